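"""Ingestion, layer merging, vetting, binning, subsetting, incidence matrices."""

import numpy as np
import pandas as pd
import pytest

from paleobeta.occurrences import (
    IntegrityError,
    SchemaError,
    TimeBinConfig,
    apply_subset,
    assign_time_bins,
    build_incidence_matrix,
    merge_contemporaneous_layers,
    read_dataset,
    vet_sites,
)
from .conftest import make_site


def _write_tables(tmp_path, occ_rows, site_rows, trait_rows):
    occ = tmp_path / "occ.csv"
    site = tmp_path / "site.csv"
    trait = tmp_path / "trait.csv"
    pd.DataFrame(occ_rows).to_csv(occ, index=False)
    pd.DataFrame(site_rows).to_csv(site, index=False)
    pd.DataFrame(trait_rows).to_csv(trait, index=False)
    return occ, site, trait


TRAITS = [
    {"species_id": "a", "order_name": "Rodentia", "mass_kg": 0.02, "extinct": 0},
    {"species_id": "b", "order_name": "Carnivora", "mass_kg": 12.0, "extinct": 0},
]
SITES = [
    {"site_id": "s1", "lon": -100.0, "lat": 40.0, "age_bp": 12000, "modern": 0},
    {"site_id": "s2", "lon": -90.0, "lat": 35.0, "age_bp": "", "modern": 1},
]


class TestReadDataset:
    def test_toy_roundtrip(self, tmp_path):
        paths = _write_tables(
            tmp_path,
            [{"site_id": "s1", "species_id": "a"}, {"site_id": "s1", "species_id": "b"},
             {"site_id": "s2", "species_id": "a"}],
            SITES,
            TRAITS,
        )
        ds = read_dataset(*paths)
        assert len(ds.sites) == 2
        assert ds.species_ids == {"a", "b"}
        s1 = next(s for s in ds.sites if s.site_id == "s1")
        assert s1.species == {"a", "b"} and s1.age_bp == 12000
        assert next(s for s in ds.sites if s.site_id == "s2").modern

    def test_unknown_site_named_in_error(self, tmp_path):
        paths = _write_tables(
            tmp_path,
            [{"site_id": "X", "species_id": "a"}],
            SITES,
            TRAITS,
        )
        with pytest.raises(IntegrityError, match="X"):
            read_dataset(*paths)

    def test_duplicate_incidence_collapses(self, tmp_path):
        paths = _write_tables(
            tmp_path,
            [{"site_id": "s1", "species_id": "a"}] * 3,
            SITES,
            TRAITS,
        )
        ds = read_dataset(*paths)
        assert next(s for s in ds.sites if s.site_id == "s1").species == {"a"}

    def test_missing_column_names_it(self, tmp_path):
        paths = _write_tables(
            tmp_path,
            [{"site_id": "s1", "species_id": "a"}],
            [{"site_id": "s1", "lon": -100.0, "lat": 40.0, "age_bp": 100}],  # no modern
            TRAITS,
        )
        with pytest.raises(SchemaError, match="modern"):
            read_dataset(*paths)


class TestLayerMerging:
    def test_within_threshold_merges_with_mean_age_and_union(self):
        layers = [
            make_site("l1", {"a", "b"}, age=10_000),
            make_site("l2", {"b", "c"}, age=10_300),
        ]
        merged = merge_contemporaneous_layers(layers)
        assert len(merged) == 1
        assert merged[0].age_bp == pytest.approx(10_150)
        assert merged[0].species == {"a", "b", "c"}

    def test_beyond_threshold_stays_separate(self):
        layers = [make_site("l1", {"a"}, age=10_000), make_site("l2", {"b"}, age=10_600)]
        assert len(merge_contemporaneous_layers(layers)) == 2

    def test_same_age_different_coords_stays_separate(self):
        layers = [
            make_site("l1", {"a"}, lon=-100.0, age=10_000),
            make_site("l2", {"b"}, lon=-101.0, age=10_000),
        ]
        assert len(merge_contemporaneous_layers(layers)) == 2

    def test_chain_merges_transitively(self):
        layers = [make_site(f"l{i}", {f"sp{i}"}, age=10_000 + 400 * i) for i in range(4)]
        merged = merge_contemporaneous_layers(layers)
        assert len(merged) == 1
        assert merged[0].species == {"sp0", "sp1", "sp2", "sp3"}

    def test_conserves_incidences_and_never_adds_sites(self, rng):
        layers = [
            make_site(f"l{i}", {f"sp{j}" for j in rng.integers(0, 20, size=5)},
                      lon=float(rng.choice([-100.0, -95.0])), age=float(rng.integers(1000, 20000)))
            for i in range(25)
        ]
        merged = merge_contemporaneous_layers(layers)
        assert len(merged) <= len(layers)
        before = sorted((sp, round(s.lon, 4)) for s in layers for sp in s.species)
        after = sorted((sp, round(s.lon, 4)) for s in merged for sp in s.species)
        assert set(after) == set(before)  # union collapses duplicates at one deposit

    def test_modern_sites_pass_through(self):
        sites = [make_site("m", {"a"}, modern=True)]
        assert merge_contemporaneous_layers(sites) == sites


class TestVetting:
    traits = pd.DataFrame(
        {
            "species_id": [f"sp{i}" for i in range(30)],
            "order_name": ["Rodentia"] * 26 + ["Artiodactyla", "Artiodactyla", "Carnivora", "Carnivora"],
            "mass_kg": 1.0,
            "extinct": False,
        }
    )

    def test_richness_floor(self):
        poor = make_site("p", {f"sp{i}" for i in range(17)} | {"sp26", "sp28"})  # 19 spp
        assert vet_sites([poor], self.traits) == []

    def test_required_orders(self):
        rodents_only = make_site("r", {f"sp{i}" for i in range(25)})
        assert vet_sites([rodents_only], self.traits) == []

    def test_boundary_site_passes(self):
        ok = make_site("ok", {f"sp{i}" for i in range(18)} | {"sp26", "sp28"})  # 20 spp, 3 orders
        assert vet_sites([ok], self.traits) == [ok]

    def test_missing_order_raises(self):
        bad_traits = self.traits.copy()
        bad_traits.loc[0, "order_name"] = np.nan
        site = make_site("s", {"sp0", "sp26", "sp28"})
        with pytest.raises(IntegrityError, match="sp0"):
            vet_sites([site], bad_traits)

    def test_idempotent(self, small_dataset):
        once = vet_sites(small_dataset.sites, small_dataset.traits)
        assert vet_sites(once, small_dataset.traits) == once


class TestTimeBins:
    config = TimeBinConfig()

    @pytest.mark.parametrize(
        "age,modern,label",
        [
            (12_345.0, False, "15000-10000"),
            (30_000.0, False, "30000-25000"),  # oldest edge closed
            (25_000.0, False, "25000-20000"),  # interior edges open on the old bin side
            (None, True, "modern"),
            (42_000.0, False, None),
            (200.0, False, None),  # in the (500, 0] gap
        ],
    )
    def test_assignment(self, age, modern, label):
        assert self.config.assign(age, modern) == label

    def test_binning_conserves_sites(self, rng):
        sites = [
            make_site(f"s{i}", {"a"}, age=float(rng.uniform(0, 40_000)))
            for i in range(60)
        ]
        traits = pd.DataFrame({"species_id": ["a"], "order_name": ["Rodentia"],
                               "mass_kg": [1.0], "extinct": [False]})
        binned = assign_time_bins(sites, self.config, traits)
        assert binned.n_dropped + sum(binned.bin_sizes.values()) == len(sites)

    def test_monotone_edges_required(self):
        with pytest.raises(ValueError):
            TimeBinConfig(edges=(10_000.0, 20_000.0))


class TestSubsets:
    @pytest.fixture
    def binned(self):
        traits = pd.DataFrame(
            {
                "species_id": ["tiny", "mid", "big", "gone"],
                "order_name": ["Rodentia", "Carnivora", "Artiodactyla", "other"],
                "mass_kg": [0.02, 2.0, 600.0, 900.0],
                "extinct": [False, False, False, True],
            }
        )
        sites = [
            make_site("north", {"tiny", "mid"}, lat=50.2, age=12_000),
            make_site("south", {"tiny", "mid", "big", "gone"}, lat=40.0, age=12_000),
            make_site("west", {"mid", "big"}, lon=-120.0, lat=40.0, age=12_000),
        ]
        return assign_time_bins(sites, TimeBinConfig(), traits)

    def test_south_of_49_drops_whole_site(self, binned):
        out = apply_subset(binned, "south_of_49")
        assert {s.site_id for s in out.all_sites} == {"south", "west"}

    def test_east_of_rockies(self, binned):
        out = apply_subset(binned, "east_of_rockies")
        assert {s.site_id for s in out.all_sites} == {"north", "south"}

    def test_exclude_extinct_drops_species_not_site(self, binned):
        out = apply_subset(binned, "exclude_extinct")
        south = next(s for s in out.all_sites if s.site_id == "south")
        assert south.species == {"tiny", "mid", "big"}
        assert len(out.all_sites) == 3

    def test_min_mass_strict_threshold(self, binned):
        out = apply_subset(binned, "min_mass", threshold_kg=1.0)
        assert all("tiny" not in s.species for s in out.all_sites)
        assert any("mid" in s.species for s in out.all_sites)

    def test_min_mass_missing_mass_raises(self, binned):
        binned.traits.loc[1, "mass_kg"] = np.nan
        with pytest.raises(ValueError, match="mid"):
            apply_subset(binned, "min_mass", threshold_kg=1.0)

    def test_traits_table_unchanged(self, binned):
        before = binned.traits.copy()
        apply_subset(binned, "exclude_extinct")
        pd.testing.assert_frame_equal(binned.traits, before)


class TestIncidenceMatrix:
    def test_two_sites(self):
        m = build_incidence_matrix([make_site("s1", {"x", "y"}), make_site("s2", {"y", "z"})])
        assert m.values.shape == (2, 3)
        assert m.values.sum(axis=1).tolist() == [2, 2]
        assert m.species_ids == ["x", "y", "z"]

    def test_single_site_all_true(self):
        m = build_incidence_matrix([make_site("s", {"a", "b", "c"})])
        assert m.values.all() and m.values.shape == (1, 3)

    def test_disjoint_block_pattern(self):
        m = build_incidence_matrix([make_site("s1", {"a"}), make_site("s2", {"b"})])
        assert m.values.sum(axis=0).tolist() == [1, 1]

    def test_round_trip(self, small_dataset):
        sites = small_dataset.sites[:20]
        m = build_incidence_matrix(sites)
        assert m.site_sets() == [s.species for s in sites]
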