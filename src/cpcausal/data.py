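"""Subject-by-variable tables and the measurement transforms applied to them.

A :class:`VariableTable` wraps a pandas DataFrame with a provenance flag:

``raw``
    Clinic conventions — GMFM-66 points, degrees of deviation from typically
    developing references (contractures negative, inward torsion positive),
    index/scale points.
``standardized``
    Each column z-scored on the sample mean and SD (n-1 denominator), then
    sign-oriented so a larger value always means less impairment (better
    function); age keeps its conventional direction.  All standardized
    causal-effect estimation happens in this state.

A third, unflagged convention exists for the per-unit predictive model:
:func:`to_predictive_units` re-expresses contractures as nonnegative
limitation degrees (their negated raw deviation) so per-degree coefficients
carry the sign convention of the published coefficient table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, SchemaError
from .model import ModelConfig

__all__ = [
    "VariableTable",
    "standardize_and_orient",
    "to_predictive_units",
    "apply_td_offsets",
    "read_cohort_csv",
    "COLUMN_ALIASES",
]

log = logging.getLogger(__name__)

#: Accepted CSV spellings for model variables.
COLUMN_ALIASES = {
    "Walk-DMC": "DMC",
    "WalkDMC": "DMC",
    "GMFM-66": "GMFM",
    "GMFM66": "GMFM",
}

_TOL = 1e-9


@dataclass
class VariableTable:
    """Subjects x named numeric variables, with transformation provenance."""

    data: pd.DataFrame
    state: str = "raw"  # "raw" | "standardized"

    def __post_init__(self):
        if self.state not in ("raw", "standardized"):
            raise SchemaError(f"unknown table state {self.state!r}")
        if self.state == "standardized":
            if self.data.isna().any().any():
                raise EstimationError("standardized tables must be complete cases")
            mu = self.data.mean()
            sd = self.data.std(ddof=1)
            off = [c for c in self.data.columns
                   if abs(mu[c]) > 1e-6 or abs(sd[c] - 1.0) > 1e-6]
            if off:
                raise EstimationError(
                    f"columns not standardized (mean 0, SD 1): {off}"
                )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def __getitem__(self, col: str) -> pd.Series:
        if col not in self.data.columns:
            raise SchemaError(f"no column {col!r} in table")
        return self.data[col]


def _require_complete(df: pd.DataFrame) -> None:
    na = df.isna()
    if na.any().any():
        rows = sorted(df.index[na.any(axis=1)].tolist())
        raise EstimationError(
            f"missing values are not imputed; incomplete rows: {rows[:20]}"
            + (" ..." if len(rows) > 20 else "")
        )


def standardize_and_orient(raw: VariableTable, config: ModelConfig) -> VariableTable:
    """Z-score every model variable and orient signs toward "larger = better".

    Per column: subtract the sample mean, divide by the sample SD (n-1), and
    negate where the variable's raw coding has larger meaning more impaired
    (spasticity, inward torsion).  Age is standardized but never flipped.
    Zero-variance columns and missing values are hard errors — no silent
    imputation, matching complete-case analysis.
    """
    if raw.state != "raw":
        raise SchemaError("standardize_and_orient expects a raw table")
    needed = list(config.graph.observed)
    missing = [c for c in needed if c not in raw.data.columns]
    if missing:
        raise SchemaError(f"table lacks model variables: {missing}")
    df = raw.data[needed].astype(float)
    _require_complete(df)
    out = {}
    for col in needed:
        sd = df[col].std(ddof=1)
        if not sd > 0:
            raise EstimationError(f"zero-variance column: {col!r}")
        z = (df[col] - df[col].mean()) / sd
        if config.meta(col).sign_flip:
            z = -z
        out[col] = z
    return VariableTable(pd.DataFrame(out), state="standardized")


def to_predictive_units(raw: VariableTable, config: ModelConfig) -> VariableTable:
    """Re-express a raw table in the per-unit convention of the predictive
    model: contracture deviations negated into limitation degrees, all other
    variables untouched.  Output remains a ``raw``-state table (it is not
    z-scored)."""
    if raw.state != "raw":
        raise SchemaError("to_predictive_units expects a raw table")
    df = raw.data.copy()
    for col in ("AnkleDF", "KneeExt", "Popliteal", "HipExt"):
        if col in df.columns:
            df[col] = -df[col]
    return VariableTable(df, state="raw")


#: Signed conventions turning raw goniometry/torsion readings into
#: deviation-from-typical values.  +1: deviation = reading - offset;
#: -1: deviation = offset - reading (popliteal angle grows with contracture).
_OFFSET_SIGN = {
    "AnkleDF": 1.0, "KneeExt": 1.0, "HipExt": 1.0,
    "Popliteal": -1.0, "FemRot": 1.0, "TibRot": 1.0,
}


def apply_td_offsets(measured: VariableTable, config: ModelConfig) -> VariableTable:
    """Convert unoffset goniometry/torsion readings to deviation form.

    Convenience for users whose export carries raw joint angles rather than
    deviations; cohort files matching the published supplement are already
    in deviation form and must *not* be passed through this.
    """
    if measured.state != "raw":
        raise SchemaError("apply_td_offsets expects a raw table")
    df = measured.data.copy()
    for col, sign in _OFFSET_SIGN.items():
        if col in df.columns:
            off = config.meta(col).td_offset
            df[col] = sign * (df[col] - off) if sign > 0 else (off - df[col])
    return VariableTable(df, state="raw")


def read_cohort_csv(path, config: ModelConfig) -> VariableTable:
    """Read a subject-by-variable CSV into a raw table.

    Header names are matched against the model's variables, with published
    aliases (``Walk-DMC``, ``GMFM-66``) accepted; extra columns are dropped
    with a logged warning, absent model variables raise :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={k: v for k, v in COLUMN_ALIASES.items()
                            if k in df.columns})
    needed = list(config.graph.observed)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"CSV lacks model variables: {missing}")
    extra = [c for c in df.columns if c not in needed]
    if extra:
        log.warning("ignoring %d extra columns: %s", len(extra), extra)
    return VariableTable(df[needed].astype(float), state="raw")
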