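"""Patient-level trial table: container, validation and CSV round trip.

A :class:`TrialTable` holds one row per randomized patient: a unique id,
the treatment arm (``TAU`` for face-to-face treatment as usual, ``BLEND``
for blended treatment), a set of mixed-type baseline covariates that may
contain missing values, and the primary outcome (PHQ-9 depression total at
12 weeks, an integer on the 0–27 scale, missing for dropouts).

On disk a table is a plain CSV (missing cells written as empty strings,
never as a sentinel category) plus a JSON sidecar carrying the covariate
schema, so that the mixed typing survives the round trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ARM_TAU = "TAU"
ARM_BLEND = "BLEND"
ARMS = (ARM_TAU, ARM_BLEND)

OUTCOME_MIN = 0
OUTCOME_MAX = 27

ID_COL = "patient_id"
ARM_COL = "arm"
OUTCOME_COL = "outcome"

KINDS = ("continuous", "count", "binary", "nominal")


class TrialParseError(ValueError):
    """Raised when a trial table file or frame violates the dialect."""


@dataclass(frozen=True)
class VariableSpec:
    """Schema entry for one baseline covariate.

    Parameters
    ----------
    name
        Column name in the table.
    kind
        One of ``continuous``, ``count``, ``binary``, ``nominal``.
    levels
        Category labels; required (>= 2) for nominal variables.
    params
        Marginal distribution parameters used by the synthetic generator
        (e.g. ``{"mean": 41.0, "sd": 13.7}`` for a continuous variable);
        ignored for observed data.
    loading
        Optional Gaussian-copula loading in (-1, 1) on the generator's
        single latent severity factor; 0 means independent.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    params: Mapping[str, object] = field(default_factory=dict)
    loading: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "nominal":
            if len(self.levels) < 2:
                raise ValueError(f"nominal variable {self.name!r} needs >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels for {self.name!r}")
            for lev in self.levels:
                if "," in lev or lev == "":
                    raise ValueError(f"invalid level {lev!r} for {self.name!r}")
        elif self.levels:
            raise ValueError(f"levels given for non-nominal {self.name!r}")
        if not -1.0 < self.loading < 1.0:
            raise ValueError(f"loading for {self.name!r} must lie in (-1, 1)")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "levels": list(self.levels),
            "params": dict(self.params),
            "loading": self.loading,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableSpec":
        return cls(
            name=d["name"],
            kind=d["kind"],
            levels=tuple(d.get("levels", ())),
            params=dict(d.get("params", {})),
            loading=float(d.get("loading", 0.0)),
        )


@dataclass
class TrialTable:
    """Patient-level table plus the covariate schema.

    ``data`` columns are ``patient_id``, ``arm``, the covariates in schema
    order, then ``outcome``. Numeric covariates (continuous, count, binary)
    are float64 with NaN for missing; nominal covariates are object dtype
    with NaN for missing; the outcome is float64 (NaN = dropout).
    """

    data: pd.DataFrame
    schema: tuple[VariableSpec, ...]

    @property
    def covariate_names(self) -> list[str]:
        return [s.name for s in self.schema]

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def spec_for(self, name: str) -> VariableSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def copy(self) -> "TrialTable":
        return TrialTable(self.data.copy(), self.schema)

    def drop_covariates(self, names: Iterable[str]) -> "TrialTable":
        names = set(names)
        schema = tuple(s for s in self.schema if s.name not in names)
        data = self.data.drop(columns=[n for n in names if n in self.data.columns])
        return TrialTable(data, schema)

    def validate(self) -> None:
        df = self.data
        expected = [ID_COL, ARM_COL, *self.covariate_names, OUTCOME_COL]
        missing_cols = [c for c in expected if c not in df.columns]
        if missing_cols:
            raise TrialParseError(f"missing columns: {missing_cols}")
        if df[ID_COL].duplicated().any():
            dup = df[ID_COL][df[ID_COL].duplicated()].iloc[0]
            raise TrialParseError(f"duplicate patient_id {dup!r}")
        if df[ARM_COL].isna().any():
            row = int(df.index[df[ARM_COL].isna()][0])
            raise TrialParseError(f"missing arm label in row {row}")
        bad_arm = ~df[ARM_COL].isin(ARMS)
        if bad_arm.any():
            row = int(np.flatnonzero(bad_arm.to_numpy())[0])
            raise TrialParseError(
                f"unknown arm label {df[ARM_COL].iloc[row]!r} in row {row} "
                f"(expected one of {ARMS})"
            )
        y = df[OUTCOME_COL]
        observed = y.dropna()
        if ((observed < OUTCOME_MIN) | (observed > OUTCOME_MAX)).any():
            bad = observed[(observed < OUTCOME_MIN) | (observed > OUTCOME_MAX)].iloc[0]
            raise TrialParseError(
                f"outcome {bad} outside the {OUTCOME_MIN}-{OUTCOME_MAX} scale"
            )
        for s in self.schema:
            if s.kind == "nominal":
                vals = df[s.name].dropna()
                unknown = set(vals.unique()) - set(s.levels)
                if unknown:
                    raise TrialParseError(
                        f"unknown level(s) {sorted(unknown)} in column {s.name!r}"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        if self.schema != other.schema:
            return False
        try:
            pd.testing.assert_frame_equal(
                self.data.reset_index(drop=True),
                other.data.reset_index(drop=True),
                check_dtype=True,
            )
        except AssertionError:
            return False
        return True


def _canonical_frame(df: pd.DataFrame, schema: Sequence[VariableSpec]) -> pd.DataFrame:
    """Coerce columns to the canonical dtypes of the dialect."""
    out = pd.DataFrame(index=df.index)
    out[ID_COL] = df[ID_COL].astype(str)
    out[ARM_COL] = df[ARM_COL].astype(str)
    for s in schema:
        col = df[s.name]
        if s.kind == "nominal":
            out[s.name] = col.astype(object).where(col.notna(), np.nan)
        else:
            out[s.name] = pd.to_numeric(col, errors="raise").astype(np.float64)
    out[OUTCOME_COL] = pd.to_numeric(df[OUTCOME_COL], errors="raise").astype(np.float64)
    return out


def make_table(df: pd.DataFrame, schema: Sequence[VariableSpec]) -> TrialTable:
    """Build a validated :class:`TrialTable` from a raw frame."""
    table = TrialTable(_canonical_frame(df, schema), tuple(schema))
    table.validate()
    return table


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trial(table: TrialTable, path: str | Path, extra: Mapping | None = None) -> None:
    """Write the table CSV and its JSON schema sidecar.

    Missing cells are written as empty strings. Integer-valued numeric
    columns (counts, binaries, the outcome) are printed without a decimal
    point. ``extra`` entries (e.g. ground truth, generating config) are
    stored alongside the schema in the sidecar.
    """
    path = Path(path)
    df = table.data.copy()
    for s in table.schema:
        if s.kind in ("count", "binary"):
            df[s.name] = df[s.name].astype("Int64")
    df[OUTCOME_COL] = df[OUTCOME_COL].astype("Int64")
    df.to_csv(path, index=False, na_rep="")
    sidecar = {"schema": [s.to_dict() for s in table.schema]}
    if extra:
        sidecar.update(extra)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_trial(path: str | Path) -> TrialTable:
    """Read a trial table written by :func:`write_trial`.

    Raises :class:`TrialParseError` naming the offending row/column when
    the file violates the dialect (unknown arm label, out-of-range
    outcome, unknown nominal level, non-numeric cell).
    """
    path = Path(path)
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise TrialParseError(f"missing schema sidecar {meta_path}")
    sidecar = json.loads(meta_path.read_text())
    schema = tuple(VariableSpec.from_dict(d) for d in sidecar["schema"])
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace("", np.nan)
    for s in schema:
        if s.kind == "nominal":
            continue
        try:
            pd.to_numeric(raw[s.name], errors="raise")
        except (ValueError, KeyError) as exc:
            raise TrialParseError(f"non-numeric cell in column {s.name!r}: {exc}") from exc
    try:
        return make_table(raw, schema)
    except KeyError as exc:
        raise TrialParseError(f"column missing from {path}: {exc}") from exc


def read_sidecar(path: str | Path) -> dict:
    """Return the raw JSON sidecar for a trial CSV (schema plus extras)."""
    return json.loads(_sidecar_path(Path(path)).read_text())
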