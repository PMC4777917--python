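"""Preprocessing chain: boundary-event removal, log transform, standardization.

The chain runs strictly in that order per sample.  Boundary thresholds
differ between the analog (FCS 2.0 era) and digital (FCS 3.x era)
acquisition dialects; fluorescence thresholds are expressed in log10
decades and are evaluated on the log10 of the stored raw value, even
though formal log transformation is a later step.

Events at or beyond the instrument boundaries are pile-up artifacts —
cellular debris, large non-lymphocytes, or electronic noise — and carry
no usable signal, hence the hard removal rather than any winsorizing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fcs_io import EventTable, FLUOR_ROLES, ROLES

logger = logging.getLogger(__name__)

_FLUOR_IDX = [ROLES.index(r) for r in FLUOR_ROLES]
_FSC, _SSC = ROLES.index("FSC"), ROLES.index("SSC")


class ScaleStateError(RuntimeError):
    """An operation was applied to a table in the wrong scale state."""


@dataclass(frozen=True)
class BoundaryConfig:
    """Dialect-specific boundary-removal thresholds.

    ``fsc_low``/``fsc_high``/``ssc_high`` are in raw scatter units;
    ``fluor_low``/``fluor_high`` are in log10 decades of the raw
    fluorescence value.  An event is removed iff
    FSC >= fsc_high, FSC < fsc_low, SSC >= ssc_high, or any fluorescence
    channel's log10 value is >= fluor_high or < fluor_low.
    """

    dialect: str
    fsc_low: float
    fsc_high: float
    ssc_high: float
    fluor_low: float
    fluor_high: float

    def __post_init__(self) -> None:
        if not self.fsc_low < self.fsc_high:
            raise ValueError("fsc_low must be < fsc_high")
        if not self.fluor_low < self.fluor_high:
            raise ValueError("fluor_low must be < fluor_high")

    @classmethod
    def preset(cls, dialect: str) -> "BoundaryConfig":
        if dialect == "analog":
            return cls("analog", fsc_low=100, fsc_high=1000, ssc_high=1000,
                       fluor_low=0.3, fluor_high=4.0)
        if dialect == "digital":
            return cls("digital", fsc_low=100, fsc_high=800, ssc_high=1000,
                       fluor_low=0.1, fluor_high=3.5)
        raise ValueError(f"no preset for dialect {dialect!r}")


@dataclass(frozen=True)
class ScalingParams:
    """Per-channel mean/sd used for standardization (enables inversion)."""

    mean: np.ndarray  # (6,)
    sd: np.ndarray    # (6,)

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("standardization sd must be > 0 for every channel")

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.sd + self.mean


def remove_boundary_events(
    table: EventTable, config: BoundaryConfig | None = None
) -> tuple[EventTable, np.ndarray]:
    """Drop instrument-boundary events; returns (retained table, removed mask)."""
    if not table.is_raw():
        raise ScaleStateError("boundary removal requires a raw-scale table")
    config = config or BoundaryConfig.preset(table.dialect)
    v = table.values
    if v.shape[0] == 0:
        return table.copy(), np.zeros(0, dtype=bool)

    removed = (v[:, _FSC] >= config.fsc_high) | (v[:, _FSC] < config.fsc_low)
    removed |= v[:, _SSC] >= config.ssc_high
    fluor = v[:, _FLUOR_IDX]
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.log10(np.where(fluor > 0, fluor, np.nan))
    bad = np.isnan(logf) | (logf >= config.fluor_high) | (logf < config.fluor_low)
    removed |= bad.any(axis=1)

    out = table.subset(~removed)
    out.metadata["n_boundary_removed"] = int(removed.sum())
    logger.info("boundary removal (%s): removed %d of %d events",
                config.dialect, removed.sum(), table.n_events)
    return out, removed


def log_transform(table: EventTable) -> EventTable:
    """log10-transform the four fluorescence channels in place of raw values."""
    for role in FLUOR_ROLES:
        if table.scale_state[role] != "raw":
            raise ScaleStateError(f"{role} already {table.scale_state[role]}")
    out = table.copy()
    fluor = out.values[:, _FLUOR_IDX]
    if np.any(fluor <= 0):
        raise ValueError(
            "nonpositive fluorescence after boundary removal; check that "
            "remove_boundary_events ran first with a valid config")
    out.values[:, _FLUOR_IDX] = np.log10(fluor)
    for role in FLUOR_ROLES:
        out.scale_state[role] = "logged"
    return out


def standardize(table: EventTable) -> tuple[EventTable, ScalingParams]:
    """Center/scale every channel to sample mean 0, sd 1 (per sample)."""
    for role in FLUOR_ROLES:
        if table.scale_state[role] != "logged":
            raise ScaleStateError("fluorescence must be logged before standardization")
    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0, ddof=0)
    if np.any(sd <= 0) or np.any(~np.isfinite(sd)):
        zero = [ROLES[i] for i in np.flatnonzero(~(sd > 0))]
        raise ValueError(f"zero-variance channel(s): {zero}")
    out = table.copy()
    out.values = (out.values - mean) / sd
    out.scale_state = {r: "standardized" for r in ROLES}
    return out, ScalingParams(mean=mean, sd=sd)


def preprocess(
    table: EventTable, config: BoundaryConfig | None = None
) -> tuple[EventTable, EventTable, np.ndarray, ScalingParams]:
    """Full chain.  Returns (standardized, logged, removed_mask, params).

    The intermediate logged (pre-standardization) table is kept because
    MFIs are reported on that scale, which is comparable across samples.
    """
    retained, removed = remove_boundary_events(table, config)
    logged = log_transform(retained)
    standardized, params = standardize(logged)
    return standardized, logged, removed, params
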