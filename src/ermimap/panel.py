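"""The 36-species ERMI panel and the published per-species result tables.

The Environmental Relative Moldiness Index (ERMI) is built from 36 mold
species quantified by mold-specific quantitative PCR in settled house dust:
26 "Group 1" species associated with water-damaged homes and 10 "Group 2"
species that occur in homes independent of water damage.

This module ships three plain-CSV fixtures:

``panel.csv``
    ``name`` (canonical species/assay label), ``group`` (1 or 2), ``aliases``
    (semicolon-separated alternative spellings; the literature uses assay
    cluster names and species names interchangeably, e.g. "Eurotium group"
    vs "Eurotium amstelodami", "Mucor group" vs "Mucor racemosus").  Note
    one naming quirk: the Group-1 assay cluster listed as "Penicillium
    crustosum" in the regression table appears as "Penicillium Group 2"
    (the P. crustosum group-2 assay) in the cluster table and figures —
    distinct from the Group-2 species "Penicillium chrysogenum 2"; both
    spellings resolve to the canonical "Penicillium crustosum" record.
``table1.csv``
    Published per-species geographic regression results: ``response``,
    ``z_lon``/``z_lat`` (Wald Z statistics for longitude/latitude),
    ``p_lon``/``p_lat`` (two-sided p-values) and ``p_*_censored`` flags.
    P-values printed as "<0.001" are stored as 0.0005 with the censored
    flag set; significance is always judged at alpha >= 0.05, so the
    imputation never changes a verdict. Contains the 36 species rows plus
    the three index rows SLG1, SLG2 and ERMI.
``table2.csv``
    Published disjoint variable clustering: ``species``, ``cluster`` (1-7),
    ``group``, ``r2_own`` and ``r2_next`` (squared correlation of the
    species with its own cluster's first principal component and with the
    next-closest cluster's).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import PanelIntegrityError

__all__ = [
    "SpeciesRecord",
    "SpeciesPanel",
    "load_panel",
    "load_table1",
    "load_table2",
    "INDEX_ROWS",
]

#: Names of the aggregate index rows appearing alongside species in table 1.
INDEX_ROWS = ("SLG1", "SLG2", "ERMI")

N_SPECIES = 36
N_GROUP1 = 26
N_GROUP2 = 10
N_CLUSTERS = 7


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("ermimap.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass(frozen=True)
class SpeciesRecord:
    """One panel member: canonical label, ERMI group, accepted aliases."""

    name: str
    group: int
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if self.group not in (1, 2):
            raise PanelIntegrityError(
                f"species {self.name!r}: group must be 1 or 2, got {self.group!r}"
            )


@dataclass(frozen=True)
class SpeciesPanel:
    """Ordered registry of the 36 ERMI species (26 Group 1 + 10 Group 2)."""

    species: tuple[SpeciesRecord, ...]
    _lookup: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise PanelIntegrityError(f"duplicate species names: {sorted(dupes)}")
        if len(self.species) != N_SPECIES:
            raise PanelIntegrityError(
                f"panel must contain {N_SPECIES} species, got {len(self.species)}"
            )
        n1 = sum(s.group == 1 for s in self.species)
        n2 = sum(s.group == 2 for s in self.species)
        if (n1, n2) != (N_GROUP1, N_GROUP2):
            raise PanelIntegrityError(
                f"panel must contain {N_GROUP1} Group 1 and {N_GROUP2} Group 2 "
                f"species, got {n1} and {n2}"
            )
        lookup = {}
        for rec in self.species:
            for key in (rec.name, *rec.aliases):
                if key in lookup:
                    raise PanelIntegrityError(f"ambiguous species label {key!r}")
                lookup[key] = rec
        object.__setattr__(self, "_lookup", lookup)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def group_names(self, group: int) -> list[str]:
        return [s.name for s in self.species if s.group == group]

    def resolve(self, label: str) -> SpeciesRecord:
        """Return the record for a canonical name or any registered alias."""
        try:
            return self._lookup[label]
        except KeyError:
            raise PanelIntegrityError(f"unknown species label {label!r}") from None

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)


def load_panel() -> SpeciesPanel:
    """Load and validate the packaged 36-species ERMI panel."""
    df = _read_fixture("panel.csv")
    if list(df.columns) != ["name", "group", "aliases"]:
        raise PanelIntegrityError(f"unexpected panel columns: {list(df.columns)}")
    records = []
    for row in df.itertuples(index=False):
        aliases = ()
        if isinstance(row.aliases, str) and row.aliases.strip():
            aliases = tuple(a.strip() for a in row.aliases.split(";"))
        records.append(SpeciesRecord(row.name, int(row.group), aliases))
    return SpeciesPanel(tuple(records))


def load_table1(panel: SpeciesPanel | None = None) -> pd.DataFrame:
    """Load the published geographic-regression table (36 species + 3 indices).

    Returns a DataFrame with columns ``response, z_lon, p_lon, p_lon_censored,
    z_lat, p_lat, p_lat_censored``; censored flags are booleans marking
    p-values printed as "<0.001" (stored as 0.0005).
    """
    panel = panel or load_panel()
    df = _read_fixture("table1.csv")
    if len(df) != N_SPECIES + len(INDEX_ROWS):
        raise PanelIntegrityError(
            f"table1 must have {N_SPECIES + len(INDEX_ROWS)} rows, got {len(df)}"
        )
    for col in ("p_lon", "p_lat"):
        if not df[col].between(0, 1).all():
            raise PanelIntegrityError(f"table1 {col} outside [0, 1]")
    for name in df["response"]:
        if name not in INDEX_ROWS:
            panel.resolve(name)
    species_rows = df[~df["response"].isin(INDEX_ROWS)]
    if len(species_rows) != N_SPECIES:
        raise PanelIntegrityError("table1 species rows incomplete")
    df = df.astype({"p_lon_censored": bool, "p_lat_censored": bool})
    return df


def load_table2(panel: SpeciesPanel | None = None) -> pd.DataFrame:
    """Load the published variable-clustering table (36 species, 7 clusters).

    Returns a DataFrame with columns ``species, cluster, group, r2_own,
    r2_next``. Validates the disjoint cover, the cluster ids spanning 1-7,
    group agreement with the panel, and the own-vs-next R-squared ordering.
    """
    panel = panel or load_panel()
    df = _read_fixture("table2.csv")
    if len(df) != N_SPECIES or df["species"].nunique() != N_SPECIES:
        raise PanelIntegrityError("table2 must assign each of the 36 species once")
    if sorted(df["cluster"].unique()) != list(range(1, N_CLUSTERS + 1)):
        raise PanelIntegrityError("table2 cluster ids must cover 1..7")
    for row in df.itertuples(index=False):
        rec = panel.resolve(row.species)
        if rec.group != row.group:
            raise PanelIntegrityError(
                f"table2 group for {row.species!r} disagrees with panel"
            )
        if not (0 <= row.r2_next <= row.r2_own <= 1):
            raise PanelIntegrityError(
                f"table2 row {row.species!r}: need 0 <= r2_next <= r2_own <= 1"
            )
    return df
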