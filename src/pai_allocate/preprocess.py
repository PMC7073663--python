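"""Inclusion filters and design-matrix coding for the trial table.

Three steps sit between the raw table and the per-arm regressions:

1. ``filter_completers`` — keep only patients with an observed 12-week
   outcome (the completer set on which every later analysis runs);
2. ``screen_missingness`` — drop baseline covariates whose missing
   fraction reaches the acceptability threshold (default: 50%, with
   strictly-below-50% retained);
3. ``encode`` — turn the mixed-type covariates into a numeric design
   matrix: continuous/count passed through, binary as a single 0/1
   column, each k-level nominal split into k-1 indicator columns against
   a deterministic reference level (first level in sorted order), so that
   every category is an interpretable predictor of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trial import ARM_COL, ID_COL, OUTCOME_COL, TrialTable, VariableSpec


@dataclass(frozen=True)
class ColumnMeta:
    """Provenance of one design-matrix column."""

    column: str
    source: str  # source covariate name
    category: str  # category label, or "continuous" for pass-through columns
    reference: str | None  # reference level for indicator columns, else None

    def to_dict(self) -> dict:
        return {
            "column": self.column,
            "source": self.source,
            "category": self.category,
            "reference": self.reference,
        }


@dataclass
class CodedMatrix:
    """Numeric design matrix with column provenance.

    ``X`` is indexed by patient id and contains no missing entries;
    ``column_meta`` covers every column in order.
    """

    X: pd.DataFrame
    column_meta: tuple[ColumnMeta, ...]

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def meta_for(self, column: str) -> ColumnMeta:
        for m in self.column_meta:
            if m.column == column:
                return m
        raise KeyError(column)


@dataclass(frozen=True)
class CompleterReport:
    n_input: int
    n_retained: int
    n_removed: int
    retained_per_arm: dict

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "retained_per_arm": dict(self.retained_per_arm),
        }


def filter_completers(table: TrialTable) -> tuple[TrialTable, CompleterReport]:
    """Drop patients with a missing 12-week outcome.

    Returns the completer table and a report with the removed count and
    the per-arm retained counts. Raises ``ValueError`` if either arm is
    left empty (no downstream model could be fitted).
    """
    df = table.data
    keep = df[OUTCOME_COL].notna()
    out = df.loc[keep].reset_index(drop=True)
    per_arm = out[ARM_COL].value_counts().to_dict()
    for arm in ("TAU", "BLEND"):
        if per_arm.get(arm, 0) == 0:
            raise ValueError(f"no completers left in arm {arm}; cannot fit models")
    report = CompleterReport(
        n_input=len(df),
        n_retained=len(out),
        n_removed=int((~keep).sum()),
        retained_per_arm={k: int(v) for k, v in sorted(per_arm.items())},
    )
    return TrialTable(out, table.schema), report


def screen_missingness(
    table: TrialTable, threshold: float = 0.50
) -> tuple[TrialTable, list[str]]:
    """Drop covariates whose missing fraction is >= ``threshold``.

    The fraction is computed on the table as given (run this after
    completer filtering to match the analysis set). A covariate missing
    in exactly 49% of rows is retained; one at the threshold is dropped.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    n = len(table.data)
    dropped: list[str] = []
    for s in table.schema:
        frac = float(table.data[s.name].isna().sum()) / n if n else 0.0
        if frac >= threshold:
            dropped.append(s.name)
    return table.drop_covariates(dropped), dropped


def design_columns(schema: Sequence[VariableSpec]) -> tuple[ColumnMeta, ...]:
    """Deterministic design-column layout for a covariate schema.

    Continuous/count/binary variables map to one column under their own
    name; a k-level nominal maps to k-1 ``name=level`` indicators, the
    lexicographically first level serving as reference.
    """
    meta: list[ColumnMeta] = []
    for s in schema:
        if s.kind == "nominal":
            levels = sorted(s.levels)
            ref = levels[0]
            for lev in levels[1:]:
                meta.append(ColumnMeta(f"{s.name}={lev}", s.name, lev, ref))
        else:
            meta.append(ColumnMeta(s.name, s.name, "continuous", None))
    return tuple(meta)


def encode(table: TrialTable) -> CodedMatrix:
    """Encode the covariates of ``table`` as a numeric design matrix.

    Requires fully observed covariates (run after imputation). Raises
    ``ValueError`` naming the variable and level if a nominal cell holds
    a category outside the schema.
    """
    df = table.data
    na_cols = [s.name for s in table.schema if df[s.name].isna().any()]
    if na_cols:
        raise ValueError(f"covariates contain missing values: {na_cols}; impute first")
    meta = design_columns(table.schema)
    X = pd.DataFrame(index=pd.Index(df[ID_COL].astype(str), name=ID_COL))
    for s in table.schema:
        if s.kind == "nominal":
            vals = df[s.name].to_numpy()
            unknown = set(vals) - set(s.levels)
            if unknown:
                raise ValueError(
                    f"unseen category {sorted(unknown)[0]!r} for variable {s.name!r}"
                )
            for lev in sorted(s.levels)[1:]:
                X[f"{s.name}={lev}"] = (vals == lev).astype(np.float64)
        else:
            X[s.name] = df[s.name].to_numpy(dtype=np.float64)
    assert list(X.columns) == [m.column for m in meta]
    return CodedMatrix(X, meta)


def decode_nominals(coded: CodedMatrix) -> pd.DataFrame:
    """Reconstruct category labels from indicator columns via column_meta.

    Inverse of :func:`encode` up to the reference-level convention; used
    to check that the coding is lossless.
    """
    by_source: dict[str, list[ColumnMeta]] = {}
    for m in coded.column_meta:
        if m.category != "continuous":
            by_source.setdefault(m.source, []).append(m)
    out = pd.DataFrame(index=coded.X.index)
    for source, metas in by_source.items():
        ref = metas[0].reference
        labels = np.full(len(coded.X), ref, dtype=object)
        for m in metas:
            labels[coded.X[m.column].to_numpy() == 1.0] = m.category
        out[source] = labels
    return out
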