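"""Reading and filtering of MaxQuant-style proteinGroups tables.

One SILAC pulldown replicate is a tab-delimited table with one row per
protein group, carrying a heavy/light ratio, the number of peptide-level
ratio measurements behind it (ratio count), peptide evidence counts, an
intensity, and the MaxQuant ``+`` flag columns marking decoy/contaminant
rows.  This module parses such tables into a uniform :class:`QuantTable`
and applies the standard row-level quality filters: flagged rows are
dropped, and a protein group must be supported by at least two peptides
(one of them unique) and at least two ratio counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "FilterReport",
    "QuantTable",
    "apply_quant_filters",
    "read_protein_groups",
    "require_replicate_support",
    "write_protein_groups",
]

#: Canonical field -> default proteinGroups column header.  A user
#: ``column_map`` overrides entries to bind other dialects (e.g. the
#: normalized-ratio column, or triple-label M/L / H/M channels).
DEFAULT_COLUMN_MAP = {
    "protein_group_id": "Majority protein IDs",
    "gene_name": "Gene names",
    "ratio_hl": "Ratio H/L",
    "ratio_count": "Ratio H/L count",
    "peptides": "Peptides",
    "unique_peptides": "Unique peptides",
    "intensity": "Intensity",
    "only_by_site": "Only identified by site",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    # optional RNase-effect channel (triple-label protocol only)
    "ratio_rnase": "Ratio H/M",
}

_REQUIRED = [
    "protein_group_id",
    "ratio_hl",
    "ratio_count",
    "peptides",
    "unique_peptides",
    "intensity",
]
_FLAG_FIELDS = ["only_by_site", "reverse", "contaminant"]
_NUMERIC_FIELDS = [
    "ratio_hl",
    "ratio_count",
    "peptides",
    "unique_peptides",
    "intensity",
    "ratio_rnase",
]

# columns of the canonical in-memory frame, in order
COLUMNS = [
    "protein_group_id",
    "gene_name",
    "ratio_hl",
    "ratio_count",
    "peptides",
    "unique_peptides",
    "intensity",
    "only_by_site",
    "reverse",
    "contaminant",
    "ratio_rnase",
]


class QuantIOError(ValueError):
    """Structured parsing failure (missing column or malformed cells)."""

    def __init__(self, message: str, *, missing_column: str | None = None,
                 bad_rows: list[int] | None = None):
        super().__init__(message)
        self.missing_column = missing_column
        self.bad_rows = bad_rows or []


@dataclass
class QuantTable:
    """One replicate's protein-group quantifications.

    ``data`` holds one row per protein group with the canonical columns
    (see :data:`COLUMNS`); flag columns are booleans, ``ratio_rnase`` is
    NaN when the protocol has no RNase channel.
    """

    replicate_id: str
    protocol: str = "adapted"  # "adapted" | "conventional"
    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.protocol not in ("adapted", "conventional"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if len(self.data):
            ids = self.data["protein_group_id"]
            if ids.duplicated().any():
                dup = ids[ids.duplicated()].iloc[0]
                raise ValueError(
                    f"duplicate protein_group_id {dup!r} in replicate "
                    f"{self.replicate_id}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def protein_ids(self) -> set[str]:
        return set(self.data["protein_group_id"])


@dataclass
class FilterReport:
    """Per-criterion removal tally for :func:`apply_quant_filters`.

    A row failing several criteria is counted once, under the first
    failing criterion in the fixed precedence
    flags > peptides > unique_peptides > ratio_count.
    """

    n_input: int = 0
    removed_flagged: int = 0
    removed_peptides: int = 0
    removed_unique: int = 0
    removed_ratio_count: int = 0

    @property
    def n_removed(self) -> int:
        return (self.removed_flagged + self.removed_peptides
                + self.removed_unique + self.removed_ratio_count)

    @property
    def n_survivors(self) -> int:
        return self.n_input - self.n_removed


def _parse_flag(series: pd.Series) -> pd.Series:
    # MaxQuant marks positives with "+"; anything else (empty, NaN) is False
    return series.fillna("").astype(str).str.strip().eq("+")


def read_protein_groups(path, column_map: dict | None = None, *,
                        replicate_id: str | None = None,
                        protocol: str = "adapted") -> QuantTable:
    """Parse a proteinGroups-dialect TSV into a :class:`QuantTable`.

    ``column_map`` overrides :data:`DEFAULT_COLUMN_MAP` entries
    (canonical field name -> header in the file).  Rows with a missing
    ratio are retained (the ratio-count filter removes them later);
    numbers must use dot decimals.

    Raises
    ------
    QuantIOError
        If a required column is absent (naming it) or numeric cells are
        unparsable (listing the offending 0-based row indices).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                      na_values=[""])
    for fieldname in _REQUIRED:
        if cmap[fieldname] not in raw.columns:
            raise QuantIOError(
                f"required column {cmap[fieldname]!r} (for {fieldname!r}) "
                f"not found in {path}",
                missing_column=cmap[fieldname],
            )

    out = pd.DataFrame(index=raw.index)
    out["protein_group_id"] = raw[cmap["protein_group_id"]].astype(str)
    gene_col = cmap["gene_name"]
    out["gene_name"] = (
        raw[gene_col].fillna("").astype(str) if gene_col in raw.columns else ""
    )

    bad_rows: list[int] = []
    for fieldname in _NUMERIC_FIELDS:
        col = cmap.get(fieldname)
        if col is None or col not in raw.columns:
            out[fieldname] = np.nan
            continue
        converted = pd.to_numeric(raw[col], errors="coerce")
        malformed = converted.isna() & raw[col].notna()
        bad_rows.extend(int(i) for i in raw.index[malformed])
        out[fieldname] = converted
    if bad_rows:
        bad = sorted(set(bad_rows))
        raise QuantIOError(
            f"unparsable numeric cells in {path} at row indices {bad}",
            bad_rows=bad,
        )

    for fieldname in _FLAG_FIELDS:
        col = cmap.get(fieldname)
        if col is not None and col in raw.columns:
            out[fieldname] = _parse_flag(raw[col])
        else:
            out[fieldname] = False

    for fieldname in ("ratio_count", "peptides", "unique_peptides"):
        out[fieldname] = out[fieldname].fillna(0).astype(int)

    bad_ratio = out["ratio_hl"].notna() & (out["ratio_hl"] <= 0)
    if bad_ratio.any():
        bad = [int(i) for i in out.index[bad_ratio]]
        raise QuantIOError(
            f"non-positive SILAC ratios in {path} at row indices {bad}",
            bad_rows=bad,
        )

    if replicate_id is None:
        replicate_id = str(path)
    return QuantTable(replicate_id=replicate_id, protocol=protocol,
                      data=out[COLUMNS].reset_index(drop=True))


def write_protein_groups(table: QuantTable, path,
                         column_map: dict | None = None) -> None:
    """Write a :class:`QuantTable` back to the proteinGroups dialect."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = table.data
    out = pd.DataFrame()
    for fieldname in COLUMNS:
        if fieldname in _FLAG_FIELDS:
            out[cmap[fieldname]] = np.where(df[fieldname], "+", "")
        elif fieldname == "ratio_rnase" and df[fieldname].isna().all():
            continue
        else:
            out[cmap[fieldname]] = df[fieldname]
    out.to_csv(path, sep="\t", index=False, na_rep="")


def apply_quant_filters(table: QuantTable,
                        min_peptides: int = 2,
                        min_unique: int = 1,
                        min_ratio_count: int = 2,
                        ) -> tuple[QuantTable, FilterReport]:
    """Apply the row-level quality filters to one replicate.

    Removes rows that carry any decoy/contaminant flag, have fewer than
    ``min_peptides`` peptides, fewer than ``min_unique`` unique peptides,
    or fewer than ``min_ratio_count`` SILAC ratio counts (all thresholds
    inclusive).  Missing ratios count as ratio_count failures through the
    stored ratio_count.  Idempotent; empty output is legal.
    """
    df = table.data
    report = FilterReport(n_input=len(df))
    if not len(df):
        return QuantTable(table.replicate_id, table.protocol, df.copy()), report

    flagged = df["only_by_site"] | df["reverse"] | df["contaminant"]
    few_pep = df["peptides"] < min_peptides
    few_unique = df["unique_peptides"] < min_unique
    few_rc = df["ratio_count"] < min_ratio_count

    # precedence for the tally only; survivorship is the conjunction
    report.removed_flagged = int(flagged.sum())
    report.removed_peptides = int((~flagged & few_pep).sum())
    report.removed_unique = int((~flagged & ~few_pep & few_unique).sum())
    report.removed_ratio_count = int(
        (~flagged & ~few_pep & ~few_unique & few_rc).sum())

    keep = ~(flagged | few_pep | few_unique | few_rc)
    filtered = QuantTable(table.replicate_id, table.protocol,
                          df[keep].reset_index(drop=True))
    return filtered, report


def require_replicate_support(tables: list[QuantTable],
                              min_reps: int = 2) -> set[str]:
    """IDs of protein groups detected in at least ``min_reps`` replicates.

    Tables are expected post-filter; every table must share a protocol.
    """
    if min_reps > len(tables):
        raise ValueError(
            f"min_reps={min_reps} exceeds the number of replicates "
            f"({len(tables)})")
    protocols = {t.protocol for t in tables}
    if len(protocols) > 1:
        raise ValueError(f"mixed protocols in replicate set: {protocols}")
    counts: dict[str, int] = {}
    for t in tables:
        for pid in t.protein_ids:
            counts[pid] = counts.get(pid, 0) + 1
    return {pid for pid, n in counts.items() if n >= min_reps}
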