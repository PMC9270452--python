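"""Occurrence-data handling: ingestion, layer merging, vetting, subsetting, time binning.

The central objects are :class:`SiteAssemblage` (one dated locality with its
species list), :class:`OccurrenceDataset` (all localities plus a species trait
table), and :class:`BinnedDataset` (localities partitioned into ordered time
bins).  All downstream similarity, null-model and geographic analyses consume
these containers, so the vetting and binning rules here define the study design:
a locality enters the analysis only if it records at least 20 species including
at least one rodent, one artiodactyl and one carnivore, and stratigraphic
layers at the same coordinates dated within 500 years of each other are pooled
into a single assemblage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_ORDERS = frozenset({"Rodentia", "Artiodactyla", "Carnivora"})

#: Default 5,000-year bin edges (years BP, oldest first) plus a modern bin.
DEFAULT_BIN_EDGES = (30_000.0, 25_000.0, 20_000.0, 15_000.0, 10_000.0, 5_000.0, 500.0)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class IntegrityError(ValueError):
    """Referential integrity between tables is violated."""


@dataclass(frozen=True)
class SiteAssemblage:
    """One vetted locality: coordinates, a median calibrated age, and its species set."""

    site_id: str
    lon: float
    lat: float
    age_bp: float | None  # None for modern survey localities
    modern: bool
    species: frozenset

    def __post_init__(self):
        if not (-180.0 <= self.lon <= 180.0) or not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"site {self.site_id!r}: coordinates out of range")
        if not self.modern:
            if self.age_bp is None or not np.isfinite(self.age_bp) or self.age_bp < 0:
                raise ValueError(f"site {self.site_id!r}: fossil site needs a non-negative age")
        if len(self.species) == 0:
            raise ValueError(f"site {self.site_id!r}: empty species set")

    @property
    def richness(self) -> int:
        return len(self.species)


@dataclass
class OccurrenceDataset:
    """Sites plus the species trait table; single source of truth after vetting.

    ``traits`` has columns ``species_id, order_name, mass_kg, extinct`` with
    ``species_id`` unique.
    """

    sites: list
    traits: pd.DataFrame

    def __post_init__(self):
        if self.traits["species_id"].duplicated().any():
            dups = self.traits.loc[self.traits["species_id"].duplicated(), "species_id"].tolist()
            raise IntegrityError(f"duplicate species in trait table: {dups}")
        mass = self.traits["mass_kg"]
        bad = self.traits.loc[mass.notna() & (mass <= 0), "species_id"].tolist()
        if bad:
            raise ValueError(f"non-positive body mass for species: {bad}")

    @property
    def species_ids(self) -> set:
        return set().union(*(s.species for s in self.sites)) if self.sites else set()

    def trait_lookup(self, column: str) -> dict:
        return dict(zip(self.traits["species_id"], self.traits[column]))


def read_dataset(occurrence_path, site_path, trait_path) -> OccurrenceDataset:
    """Read the three CSV tables and assemble a referentially checked dataset.

    Occurrence CSV: ``site_id,species_id`` (one row per incidence; duplicates
    collapse).  Site CSV: ``site_id,lon,lat,age_bp,modern``.  Trait CSV:
    ``species_id,order_name,mass_kg,extinct``.  Extra columns are tolerated.
    """
    occ = pd.read_csv(occurrence_path, dtype={"site_id": str, "species_id": str})
    sites = pd.read_csv(site_path, dtype={"site_id": str})
    traits = pd.read_csv(trait_path, dtype={"species_id": str})

    _require(occ, ["site_id", "species_id"], "occurrence")
    _require(sites, ["site_id", "lon", "lat", "age_bp", "modern"], "site")
    _require(traits, ["species_id", "order_name", "mass_kg", "extinct"], "trait")

    occ = occ.drop_duplicates(subset=["site_id", "species_id"])

    known_sites = set(sites["site_id"])
    missing_sites = sorted(set(occ["site_id"]) - known_sites)
    if missing_sites:
        raise IntegrityError(f"occurrences reference unknown sites: {missing_sites}")
    known_species = set(traits["species_id"])
    missing_sp = sorted(set(occ["species_id"]) - known_species)
    if missing_sp:
        raise IntegrityError(f"occurrences reference unknown species: {missing_sp}")

    by_site = occ.groupby("site_id")["species_id"].agg(frozenset)
    assembled = []
    for row in sites.itertuples(index=False):
        if row.site_id not in by_site.index:
            logger.warning("site %s has no occurrences; dropped", row.site_id)
            continue
        modern = bool(int(row.modern))
        age = None if modern else float(row.age_bp)
        assembled.append(
            SiteAssemblage(
                site_id=row.site_id,
                lon=float(row.lon),
                lat=float(row.lat),
                age_bp=age,
                modern=modern,
                species=by_site[row.site_id],
            )
        )
    traits = traits.copy()
    traits["extinct"] = traits["extinct"].astype(bool)
    return OccurrenceDataset(sites=assembled, traits=traits)


def write_dataset(ds: OccurrenceDataset, occurrence_path, site_path, trait_path) -> None:
    """Write the three CSV tables (inverse of :func:`read_dataset`)."""
    occ_rows = [
        {"site_id": s.site_id, "species_id": sp}
        for s in ds.sites
        for sp in sorted(s.species)
    ]
    pd.DataFrame(occ_rows).to_csv(occurrence_path, index=False)
    site_rows = [
        {
            "site_id": s.site_id,
            "lon": s.lon,
            "lat": s.lat,
            "age_bp": "" if s.modern else s.age_bp,
            "modern": int(s.modern),
        }
        for s in ds.sites
    ]
    pd.DataFrame(site_rows).to_csv(site_path, index=False)
    out = ds.traits.copy()
    out["extinct"] = out["extinct"].astype(int)
    out.to_csv(trait_path, index=False)


def _require(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{table} table is missing required column {c!r}")


# ---------------------------------------------------------------------------
# layer merging


def merge_contemporaneous_layers(sites: Iterable[SiteAssemblage], threshold_years: float = 500.0) -> list:
    """Pool stratigraphic layers at identical coordinates dated within a threshold.

    Layers share a deposit when their coordinates agree after rounding to four
    decimal places (~11 m).  Within a deposit, layers are merged by transitive
    closure on |age difference| <= ``threshold_years``: the merged assemblage is
    the species union and its age the mean of member ages.  Layers at the same
    coordinates but further apart in time, and all modern sites, pass through
    unchanged.
    """
    out: list = []
    groups: dict = {}
    for s in sites:
        if s.modern:
            out.append(s)
        else:
            groups.setdefault((round(s.lon, 4), round(s.lat, 4)), []).append(s)

    for members in groups.values():
        members = sorted(members, key=lambda s: (s.age_bp, s.site_id))
        # union-find over the chain: ages are sorted, so adjacency suffices
        # for transitive closure on |delta age| <= threshold.
        comp = [0] * len(members)
        for i in range(1, len(members)):
            if members[i].age_bp - members[i - 1].age_bp <= threshold_years:
                comp[i] = comp[i - 1]
            else:
                comp[i] = comp[i - 1] + 1
        for cid in range(comp[-1] + 1 if members else 0):
            grp = [m for m, c in zip(members, comp) if c == cid]
            if len(grp) == 1:
                out.append(grp[0])
            else:
                out.append(
                    SiteAssemblage(
                        site_id="+".join(m.site_id for m in grp),
                        lon=grp[0].lon,
                        lat=grp[0].lat,
                        age_bp=float(np.mean([m.age_bp for m in grp])),
                        modern=False,
                        species=frozenset().union(*(m.species for m in grp)),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# vetting


def vet_sites(
    sites: Iterable[SiteAssemblage],
    traits: pd.DataFrame,
    min_richness: int = 20,
    required_orders: frozenset = REQUIRED_ORDERS,
) -> list:
    """Keep sites with >= ``min_richness`` species and >= 1 species of each required order."""
    order_of = dict(zip(traits["species_id"], traits["order_name"]))
    survivors = []
    for s in sites:
        missing = [sp for sp in s.species if sp not in order_of or pd.isna(order_of[sp])]
        if missing:
            raise IntegrityError(f"species with missing taxonomic order at {s.site_id}: {sorted(missing)}")
        if s.richness < min_richness:
            continue
        present_orders = {order_of[sp] for sp in s.species}
        if not required_orders <= present_orders:
            continue
        survivors.append(s)
    return survivors


# ---------------------------------------------------------------------------
# time binning


@dataclass(frozen=True)
class TimeBinConfig:
    """Ordered bin edges in years BP (strictly decreasing, oldest first).

    ``edges = (e0, e1, ..., ek)`` defines k bins; bin i holds ages
    ``e_i >= age > e_{i+1}`` (closed at the old edge, open at the young edge),
    so an age equal to the oldest edge falls in the oldest bin and ages younger
    than ``e_k`` that are not flagged modern are dropped.
    """

    edges: tuple = DEFAULT_BIN_EDGES
    modern_bin: bool = True

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or not np.all(np.diff(e) < 0):
            raise ValueError("edges must be strictly decreasing with length >= 2")

    @property
    def labels(self) -> list:
        labs = [f"{int(a)}-{int(b)}" for a, b in zip(self.edges[:-1], self.edges[1:])]
        if self.modern_bin:
            labs.append("modern")
        return labs

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1 + int(self.modern_bin)

    def assign(self, age_bp: float | None, modern: bool) -> str | None:
        """Bin label for a site, or None if it falls outside every bin."""
        if modern:
            return "modern" if self.modern_bin else None
        if age_bp is None:
            return None
        e = self.edges
        if age_bp > e[0] or age_bp <= e[-1]:
            return None
        for i in range(len(e) - 1):
            if e[i] >= age_bp > e[i + 1]:
                return f"{int(e[i])}-{int(e[i + 1])}"
        return None  # pragma: no cover


@dataclass
class BinnedDataset:
    """Sites partitioned into ordered time bins (oldest first, modern last)."""

    bins: list  # list of (label, list[SiteAssemblage])
    traits: pd.DataFrame
    config: TimeBinConfig
    n_dropped: int = 0

    @property
    def labels(self) -> list:
        return [lab for lab, _ in self.bins]

    @property
    def sites_by_bin(self) -> dict:
        return dict(self.bins)

    @property
    def all_sites(self) -> list:
        return [s for _, members in self.bins for s in members]

    @property
    def bin_sizes(self) -> dict:
        return {lab: len(members) for lab, members in self.bins}

    def map_sites(self, fn: Callable) -> "BinnedDataset":
        """Apply ``fn`` to each bin's site list, dropping emptied bins' sites but keeping labels."""
        return BinnedDataset(
            bins=[(lab, fn(members)) for lab, members in self.bins],
            traits=self.traits,
            config=self.config,
            n_dropped=self.n_dropped,
        )


def assign_time_bins(sites: Iterable[SiteAssemblage], config: TimeBinConfig, traits: pd.DataFrame) -> BinnedDataset:
    """Place each site into its time bin by median age; out-of-range sites are dropped."""
    buckets = {lab: [] for lab in config.labels}
    dropped = 0
    for s in sites:
        lab = config.assign(s.age_bp, s.modern)
        if lab is None:
            dropped += 1
        else:
            buckets[lab].append(s)
    if dropped:
        logger.info("assign_time_bins: %d sites outside the binning scheme dropped", dropped)
    return BinnedDataset(
        bins=[(lab, buckets[lab]) for lab in config.labels],
        traits=traits,
        config=config,
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# subsets (the Table-1 style data variants)


def apply_subset(ds: BinnedDataset, name: str, **kwargs) -> BinnedDataset:
    """Apply one of the named data subsets.

    Site-level filters (``east_of_rockies``, ``south_of_49``) drop whole sites;
    species-level filters (``exclude_extinct``, ``min_mass``) drop species from
    every site without re-vetting (sites left with no species are removed).
    ``all`` returns the dataset unchanged.
    """
    if name == "all":
        return ds
    if name == "east_of_rockies":
        cutoff = kwargs.get("lon_cutoff", -105.0)
        return ds.map_sites(lambda members: [s for s in members if s.lon >= cutoff])
    if name == "south_of_49":
        cutoff = kwargs.get("lat_cutoff", 49.0)
        return ds.map_sites(lambda members: [s for s in members if s.lat <= cutoff])
    if name == "exclude_extinct":
        extinct = set(ds.traits.loc[ds.traits["extinct"].astype(bool), "species_id"])
        return _drop_species(ds, extinct)
    if name == "min_mass":
        threshold = float(kwargs["threshold_kg"])
        mass = ds.traits.set_index("species_id")["mass_kg"]
        present = set().union(*(s.species for _, m in ds.bins for s in m), set())
        missing = sorted(sp for sp in present if sp in mass.index and pd.isna(mass[sp]))
        if missing:
            raise ValueError(f"min_mass filter: species lacking body mass: {missing}")
        small = set(mass.index[mass <= threshold])  # strict > threshold retained
        return _drop_species(ds, small)
    raise ValueError(f"unknown subset {name!r}")


#: The six data variants reported in the headline effect-size table.
STANDARD_SUBSETS = (
    ("all", {}),
    ("east_of_rockies", {}),
    ("south_of_49", {}),
    ("exclude_extinct", {}),
    ("min_mass", {"threshold_kg": 1.0}),
    ("min_mass", {"threshold_kg": 5.0}),
)


def subset_label(name: str, kwargs: dict) -> str:
    if name == "min_mass":
        t = kwargs["threshold_kg"]
        return f"min_mass_{t:g}kg"
    return name


def _drop_species(ds: BinnedDataset, to_drop: set) -> BinnedDataset:
    def strip(members):
        out = []
        for s in members:
            kept = s.species - to_drop
            if kept:
                out.append(replace(s, species=frozenset(kept)))
            else:
                logger.warning("site %s lost all species under subset filter; dropped", s.site_id)
        return out

    return ds.map_sites(strip)


# ---------------------------------------------------------------------------
# incidence matrix


@dataclass
class IncidenceMatrix:
    """Boolean sites x species presence matrix; species sorted lexicographically."""

    site_ids: list
    species_ids: list
    values: np.ndarray  # bool, shape (n_sites, n_species)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueError("matrix shape does not match axis labels")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def site_sets(self) -> list:
        sp = np.asarray(self.species_ids, dtype=object)
        return [frozenset(sp[row]) for row in self.values]


def build_incidence_matrix(sites: Sequence[SiteAssemblage]) -> IncidenceMatrix:
    """Site-by-species presence matrix over the union of the sites' species."""
    if len(sites) == 0:
        raise ValueError("need at least one site")
    species = sorted(set().union(*(s.species for s in sites)))
    index = {sp: j for j, sp in enumerate(species)}
    values = np.zeros((len(sites), len(species)), dtype=bool)
    for i, s in enumerate(sites):
        for sp in s.species:
            values[i, index[sp]] = True
    return IncidenceMatrix([s.site_id for s in sites], species, values)
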