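"""Reading, validating and summarising kinase-pair z-score tables.

The input is a table of unordered kinase pairs with one real-valued z-score
column per inhibitor treatment.  Negative z-scores mark kinase-kinase
interactions whose activity decreased under the treatment; positive ones mark
up-regulated interactions.  Missing cells mean "no measurement / no edge" and
are never imputed as zero.

Pairs are stored canonically with the two kinase names sorted
lexicographically, so the row order and the within-pair column order of the
source file are irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AliasConflictError, FormatError, ValidationError

__all__ = [
    "ZScoreTable",
    "SummaryStats",
    "load_zscore_table",
    "write_zscore_table",
    "merge_aliases",
    "summarise",
]


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ZScoreTable:
    """Unordered kinase pairs x treatments, real z-scores, NaN = missing.

    ``data`` is indexed by a two-level MultiIndex (kinase_a, kinase_b) with
    kinase_a < kinase_b; columns are treatment names.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.nlevels != 2:
            raise ValidationError("z-score table index must be (kinase_a, kinase_b) pairs")
        for a, b in idx:
            if a == b:
                raise ValidationError(f"pair with identical kinase names: ({a!r}, {b!r})")
            if a > b:
                raise ValidationError(f"pair not canonically ordered: ({a!r}, {b!r})")
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate unordered pair(s): {dups}")
        if self.data.columns.has_duplicates:
            raise ValidationError("treatment names are not unique")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.data.index)

    @property
    def treatments(self) -> list[str]:
        return list(self.data.columns)

    @property
    def kinases(self) -> list[str]:
        names: set[str] = set()
        for a, b in self.data.index:
            names.update((a, b))
        return sorted(names)

    def zscore(self, pair: tuple[str, str], treatment: str) -> float:
        """Return the z-score for an unordered pair, NaN if missing."""
        return float(self.data.loc[_canonical_pair(*pair), treatment])


def load_zscore_table(
    path: str | Path,
    pair_columns: Sequence[str] = ("kinase_a", "kinase_b"),
    treatment_columns: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> ZScoreTable:
    """Load a CSV/TSV z-score table.

    The delimiter is inferred from the extension (``.tsv``/``.txt`` -> tab,
    otherwise comma) unless given explicitly.  ``treatment_columns`` defaults
    to every column other than the two pair columns.  Empty cells are recorded
    as missing, never as zero.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = delimiter or ("\t" if path.suffix.lower() in {".tsv", ".txt"} else ",")
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if raw.empty and raw.columns.empty:
        raise FormatError(f"empty file: {path}")
    ka, kb = pair_columns
    for col in (ka, kb):
        if col not in raw.columns:
            raise FormatError(f"missing pair column {col!r} in {path}")
    if treatment_columns is None:
        treatment_columns = [c for c in raw.columns if c not in (ka, kb)]
    else:
        for col in treatment_columns:
            if col not in raw.columns:
                raise FormatError(f"missing treatment column {col!r} in {path}")
    if not treatment_columns:
        raise FormatError(f"no treatment columns found in {path}")

    z = {}
    for col in treatment_columns:
        text = raw[col].str.strip() if raw[col].dtype == object else raw[col]
        vals = pd.to_numeric(text, errors="coerce")
        bad = text.notna() & (text != "") & vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"row {row + 2} of {path}: value {raw[col].iloc[row]!r} in column "
                f"{col!r} is not a number"
            )
        z[col] = vals

    pairs = []
    for row, (a, b) in enumerate(zip(raw[ka], raw[kb])):
        if pd.isna(a) or pd.isna(b) or not str(a) or not str(b):
            raise FormatError(f"row {row + 2} of {path}: missing kinase name")
        pairs.append(_canonical_pair(str(a), str(b)))
    index = pd.MultiIndex.from_tuples(pairs, names=["kinase_a", "kinase_b"])
    data = pd.DataFrame({c: z[c].to_numpy() for c in treatment_columns}, index=index)
    data = data.astype(float)
    return ZScoreTable(data.sort_index())


def write_zscore_table(table: ZScoreTable, path: str | Path, delimiter: str | None = None) -> None:
    """Write a table back to CSV/TSV; load/write/load round-trips exactly."""
    path = Path(path)
    sep = delimiter or ("\t" if path.suffix.lower() in {".tsv", ".txt"} else ",")
    table.data.reset_index().to_csv(path, sep=sep, index=False)


def merge_aliases(
    table: ZScoreTable,
    alias_map: Mapping[str, str],
    atol: float = 1e-9,
) -> ZScoreTable:
    """Merge kinase aliases (e.g. AKT1 and AKT2 into a single AKT1/2 node).

    Pairs whose two members collapse to the same merged name are removed.
    Pairs that become duplicates are deduplicated provided their z-scores
    agree within ``atol`` per treatment; otherwise an
    :class:`~kincomm.exceptions.AliasConflictError` is raised.  Applying the
    same alias map twice is a no-op.
    """
    merged: dict[tuple[str, str], pd.Series] = {}
    for (a, b), row in table.data.iterrows():
        a2 = alias_map.get(a, a)
        b2 = alias_map.get(b, b)
        if a2 == b2:
            continue  # self-pair after merging
        key = _canonical_pair(a2, b2)
        if key not in merged:
            merged[key] = row.copy()
            continue
        prev = merged[key]
        for treatment in table.treatments:
            x, y = prev[treatment], row[treatment]
            if pd.isna(x) and pd.isna(y):
                continue
            if pd.isna(x):
                prev[treatment] = y
            elif not pd.isna(y) and not math.isclose(x, y, abs_tol=atol, rel_tol=0.0):
                raise AliasConflictError(
                    f"pair {key} has conflicting z-scores for {treatment!r}: {x} vs {y}"
                )
    index = pd.MultiIndex.from_tuples(list(merged), names=["kinase_a", "kinase_b"])
    data = pd.DataFrame(list(merged.values()), index=index, columns=table.treatments)
    return ZScoreTable(data.sort_index())


@dataclass
class SummaryStats:
    """Summary of strictly negative (or positive) z-scores for one treatment.

    ``sd`` is the sample standard deviation (ddof=1); the population value
    (ddof=0) is kept alongside because the convention behind published tables
    of this kind is not always stated.  A single retained value has sd 0
    under either reading.  ``empty`` flags the no-retained-values case, in
    which min/max/mean/sd are NaN.
    """

    treatment: str
    sign: str
    n_kinases: int
    n_values: int
    min: float = field(default=float("nan"))
    max: float = field(default=float("nan"))
    mean: float = field(default=float("nan"))
    sd: float = field(default=float("nan"))
    sd_population: float = field(default=float("nan"))

    @property
    def empty(self) -> bool:
        return self.n_values == 0

    def as_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "sign": self.sign,
            "n_kinases": self.n_kinases,
            "n_values": self.n_values,
            "min": self.min,
            "max": self.max,
            "mean": self.mean,
            "sd": self.sd,
            "sd_population": self.sd_population,
        }


def summarise(table: ZScoreTable, treatment: str, sign: str = "negative") -> SummaryStats:
    """Summary statistics over z-values strictly of the requested sign.

    Zeros are excluded from both signs.  ``n_kinases`` counts distinct
    kinases appearing in at least one retained pair.
    """
    if treatment not in table.treatments:
        raise ValidationError(f"unknown treatment {treatment!r}")
    if sign not in ("negative", "positive"):
        raise ValidationError(f"sign must be 'negative' or 'positive', got {sign!r}")
    col = table.data[treatment]
    keep = (col < 0) if sign == "negative" else (col > 0)
    vals = col[keep].to_numpy(dtype=float)
    kinases: set[str] = set()
    for a, b in col.index[keep]:
        kinases.update((a, b))
    if vals.size == 0:
        return SummaryStats(treatment, sign, n_kinases=0, n_values=0)
    sd = 0.0 if vals.size == 1 else float(np.std(vals, ddof=1))
    return SummaryStats(
        treatment,
        sign,
        n_kinases=len(kinases),
        n_values=int(vals.size),
        min=float(vals.min()),
        max=float(vals.max()),
        mean=float(vals.mean()),
        sd=sd,
        sd_population=float(np.std(vals, ddof=0)),
    )
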