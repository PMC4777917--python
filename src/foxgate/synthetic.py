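"""Synthetic flow-cytometry samples and cohorts with ground-truth labels.

A sample is a Gaussian mixture over six channels in the order
(FSC, SSC, CD4, CD45RO, CD25, FOXP3).  Scatter channels are simulated in
raw instrument units; fluorescence channels are simulated as Gaussians in
log10-decade space and then exponentiated to the raw scale of the chosen
acquisition dialect, because that is the space in which cytometry
populations look Gaussian and in which boundary thresholds are stated.

The default geometry emulates PBMC staining for Treg analysis:

* a broad debris/dead-cell/non-lymphocyte smear overlapping the
  lymphocyte scatter cloud from below,
* CD4- lymphocytes and a CD4+ cloud distinct in the CD4 channel,
* within CD4+, a FOXP3- majority and three FOXP3+ subpopulations:
  CD45RO+ FOXP3^high CD25^high effector Tregs, CD45RO- FOXP3^low naive
  Tregs, and CD45RO+ FOXP3^low non-Tregs,
* a configurable fraction of instrument-boundary pile-up events, applied
  uniformly across populations.

Spillover/compensation, doublets and acquisition-time drift are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .fcs_io import EventTable, ROLES

POPULATIONS = ("debris", "lymphocyte_cd4neg", "cd4_foxp3neg",
               "effector_treg", "naive_treg", "non_treg")
FOXP3_POS = ("effector_treg", "naive_treg", "non_treg")
CD4_POS = ("cd4_foxp3neg",) + FOXP3_POS

_FLUOR_SLICE = slice(2, 6)  # CD4, CD45RO, CD25, FOXP3 columns

#: Instrument value ranges per dialect: scatter is linear on a 10-bit
#: scale; fluorescence raw limits are given as log10 decades (the analog
#: amplifier spans 4 decades; the digital converter reaches a little
#: higher and further down).
INSTRUMENT_LIMITS = {
    "analog": {"scatter": (0.0, 1023.0), "fluor_log": (0.0, 4.0)},
    "digital": {"scatter": (0.0, 1023.0), "fluor_log": (-1.0, 4.4)},
}


class SpecValidationError(ValueError):
    """A sample/cohort specification violates its invariants."""


@dataclass(frozen=True)
class PopulationSpec:
    """One mixture component.

    ``mean``/``covariance`` are in raw units for FSC/SSC and log10-decade
    units for the four fluorescence channels.
    """

    name: str
    weight: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, float))
        if self.name not in POPULATIONS:
            raise SpecValidationError(f"unknown population {self.name!r}")
        if self.mean.shape != (len(ROLES),):
            raise SpecValidationError("mean must be a 6-vector")
        if self.covariance.shape != (len(ROLES),) * 2:
            raise SpecValidationError("covariance must be 6x6")
        if not np.allclose(self.covariance, self.covariance.T):
            raise SpecValidationError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() < -1e-9:
            raise SpecValidationError("covariance must be PSD")
        if not 0 <= self.weight <= 1:
            raise SpecValidationError("weight must be in [0, 1]")

    @classmethod
    def from_sds(cls, name: str, weight: float, mean, sds) -> "PopulationSpec":
        return cls(name, weight, np.asarray(mean, float),
                   np.diag(np.square(np.asarray(sds, float))))


@dataclass(frozen=True)
class SampleSpec:
    populations: tuple[PopulationSpec, ...]
    n_events: int = 20_000
    dialect: str = "analog"
    boundary_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        if self.n_events <= 0:
            raise SpecValidationError("n_events must be > 0")
        if not 0 <= self.boundary_fraction < 1:
            raise SpecValidationError("boundary_fraction must be in [0, 1)")
        if self.dialect not in INSTRUMENT_LIMITS:
            raise SpecValidationError(f"unknown dialect {self.dialect!r}")
        total = sum(p.weight for p in self.populations)
        if abs(total - 1.0) > 1e-6:
            raise SpecValidationError(f"population weights sum to {total}, not 1")
        self._check_geometry()

    def _check_geometry(self) -> None:
        by_name = {p.name: p for p in self.populations}
        pos = [by_name[n] for n in FOXP3_POS if n in by_name and by_name[n].weight > 0]
        if len(pos) == 3:
            foxp3 = ROLES.index("FOXP3")
            ro = ROLES.index("CD45RO")
            eff, naive = by_name["effector_treg"], by_name["naive_treg"]
            if eff.mean[foxp3] < max(p.mean[foxp3] for p in pos):
                raise SpecValidationError(
                    "effector_treg must have the highest FOXP3 mean among "
                    "FOXP3+ populations")
            if naive.mean[ro] > min(p.mean[ro] for p in pos):
                raise SpecValidationError(
                    "naive_treg must have the lowest CD45RO mean among "
                    "FOXP3+ populations")

    def with_weights(self, **weights: float) -> "SampleSpec":
        """Copy with some population weights replaced; ``cd4_foxp3neg``
        absorbs the difference so the total stays 1."""
        pops = {p.name: p for p in self.populations}
        delta = 0.0
        for name, w in weights.items():
            if name not in pops:
                raise SpecValidationError(f"no population {name!r} in spec")
            delta += w - pops[name].weight
            pops[name] = replace(pops[name], weight=w)
        if "cd4_foxp3neg" not in weights:
            base = pops["cd4_foxp3neg"]
            pops["cd4_foxp3neg"] = replace(base, weight=base.weight - delta)
        return replace(self, populations=tuple(pops[n] for n in pops))


# ---------------------------------------------------------------------------
# Default geometry (versioned; see docs/methods.md for the rationale)
# ---------------------------------------------------------------------------

DEFAULT_GEOMETRY_VERSION = 1

#                      FSC   SSC   CD4   CD45RO CD25  FOXP3
_DEFAULT_MEANS = {
    "debris":            (380,  300,  0.90, 1.00, 0.90, 0.85),
    "lymphocyte_cd4neg": (480,  230,  1.00, 1.60, 1.00, 0.85),
    "cd4_foxp3neg":      (500,  240,  2.75, 1.70, 1.10, 0.90),
    "effector_treg":     (500,  240,  2.75, 2.35, 2.45, 2.60),
    "naive_treg":        (500,  240,  2.75, 1.20, 1.80, 2.00),
    "non_treg":          (500,  240,  2.75, 2.10, 1.65, 1.95),
}
_DEFAULT_SDS = {
    "debris":            (120,  150,  0.30, 0.35, 0.30, 0.28),
    "lymphocyte_cd4neg": (65,   55,   0.25, 0.45, 0.30, 0.25),
    "cd4_foxp3neg":      (65,   55,   0.18, 0.40, 0.30, 0.265),
    "effector_treg":     (65,   55,   0.18, 0.30, 0.30, 0.25),
    "naive_treg":        (65,   55,   0.18, 0.35, 0.32, 0.16),
    "non_treg":          (65,   55,   0.18, 0.35, 0.32, 0.16),
}
_DEFAULT_WEIGHTS = {
    "debris": 0.40, "lymphocyte_cd4neg": 0.29, "cd4_foxp3neg": 0.26,
    "effector_treg": 0.02, "naive_treg": 0.015, "non_treg": 0.015,
}


def default_populations() -> tuple[PopulationSpec, ...]:
    return tuple(
        PopulationSpec.from_sds(name, _DEFAULT_WEIGHTS[name],
                                _DEFAULT_MEANS[name], _DEFAULT_SDS[name])
        for name in POPULATIONS)


def default_sample_spec(n_events: int = 20_000, dialect: str = "analog",
                        seed: int = 0, boundary_fraction: float = 0.02,
                        **weights: float) -> SampleSpec:
    spec = SampleSpec(default_populations(), n_events=n_events,
                      dialect=dialect, boundary_fraction=boundary_fraction,
                      seed=seed)
    return spec.with_weights(**weights) if weights else spec


# ---------------------------------------------------------------------------
# Sample generation
# ---------------------------------------------------------------------------

def generate_sample(spec: SampleSpec) -> tuple[EventTable, np.ndarray]:
    """Draw one sample; returns (raw-scale EventTable, ground-truth labels)."""
    rng = np.random.default_rng(spec.seed)
    pops = [p for p in spec.populations if p.weight > 0]
    weights = np.array([p.weight for p in pops])
    counts = rng.multinomial(spec.n_events, weights / weights.sum())

    limits = INSTRUMENT_LIMITS[spec.dialect]
    lo_s, hi_s = limits["scatter"]
    lo_f, hi_f = limits["fluor_log"]

    def in_range(block: np.ndarray) -> np.ndarray:
        ok = (block[:, :2] > lo_s).all(axis=1) & (block[:, :2] < hi_s).all(axis=1)
        fl = block[:, _FLUOR_SLICE]
        return ok & (fl > lo_f).all(axis=1) & (fl < hi_f).all(axis=1)

    blocks, label_blocks = [], []
    for pop, count in zip(pops, counts):
        if count == 0:
            continue
        L = np.linalg.cholesky(pop.covariance + 1e-12 * np.eye(len(ROLES)))
        block = rng.standard_normal((count, len(ROLES))) @ L.T + pop.mean
        # truncate to the instrument range by rejection: only deliberate
        # pile-up (below) may sit exactly at the limits
        for _ in range(100):
            bad = ~in_range(block)
            if not bad.any():
                break
            redraw = rng.standard_normal((int(bad.sum()), len(ROLES)))
            block[bad] = redraw @ L.T + pop.mean
        else:
            raise SpecValidationError(
                f"population {pop.name!r} lies mostly outside the "
                f"{spec.dialect} instrument range")
        blocks.append(block)
        label_blocks.append(np.full(count, pop.name))
    values = np.concatenate(blocks) if blocks else np.empty((0, len(ROLES)))
    labels = np.concatenate(label_blocks) if label_blocks else np.empty(0, dtype="U20")

    order = rng.permutation(len(values))
    values, labels = values[order], labels[order]

    # fluorescence: log decades -> raw instrument units
    values[:, _FLUOR_SLICE] = 10.0 ** values[:, _FLUOR_SLICE]

    # boundary pile-up: clamp one random channel of the chosen events to a
    # random instrument limit, uniformly across populations
    n_clamp = int(round(spec.boundary_fraction * spec.n_events))
    if n_clamp:
        idx = rng.choice(spec.n_events, size=n_clamp, replace=False)
        chans = rng.integers(0, len(ROLES), size=n_clamp)
        high = rng.random(n_clamp) < 0.5
        for i, c, h in zip(idx, chans, high):
            if c < 2:
                values[i, c] = hi_s if h else lo_s
            else:
                values[i, c] = 10.0 ** (hi_f if h else lo_f)

    table = EventTable(values, spec.dialect, metadata={
        "seed": spec.seed, "generator": "foxgate.synthetic",
        "geometry_version": DEFAULT_GEOMETRY_VERSION,
        "n_clamped": n_clamp,
    })
    return table, labels


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

STATUSES = ("HC", "I-II", "III", "IV")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm: ``n_samples`` draws with the effector-Treg mixture
    weight jittered uniformly in ``center +/- jitter`` per sample."""

    status: str
    n_samples: int
    effector_center: float = 0.02
    effector_jitter: float = 0.005

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise SpecValidationError("n_samples must be >= 1")
        if self.effector_center - self.effector_jitter <= 0:
            raise SpecValidationError("effector weight range must stay positive")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    base: SampleSpec
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise SpecValidationError("cohort needs at least one group")


@dataclass
class CohortSample:
    sample_id: str
    status: str
    table: EventTable
    labels: np.ndarray
    effector_weight: float


def generate_cohort(spec: CohortSpec) -> list[CohortSample]:
    """Generate all samples of a cohort, reproducibly under ``spec.seed``."""
    out: list[CohortSample] = []
    for gi, group in enumerate(spec.groups):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, gi]))
        for si in range(group.n_samples):
            w = group.effector_center + group.effector_jitter * (2 * rng.random() - 1)
            sample_seed = int(rng.integers(0, 2**31 - 1))
            sspec = replace(spec.base, seed=sample_seed).with_weights(effector_treg=w)
            table, labels = generate_sample(sspec)
            table.metadata["status"] = group.status
            out.append(CohortSample(
                sample_id=f"{group.status}_{si + 1:02d}", status=group.status,
                table=table, labels=labels, effector_weight=w))
    return out


def default_cohort_spec(n_hc: int = 15, n_melanoma: int = 19,
                        hc_effector: float = 0.02, mel_effector: float = 0.04,
                        jitter: float = 0.005, n_events: int = 20_000,
                        dialect: str = "digital", seed: int = 0) -> CohortSpec:
    """Two-arm cohort at the scale of a typical validation data set
    (15 healthy controls vs 19 melanoma patients)."""
    base = default_sample_spec(n_events=n_events, dialect=dialect, seed=seed)
    return CohortSpec(
        groups=(GroupSpec("HC", n_hc, hc_effector, jitter),
                GroupSpec("melanoma", n_melanoma, mel_effector, jitter)),
        base=base, seed=seed)


# ---------------------------------------------------------------------------
# Config-file loading (YAML)
# ---------------------------------------------------------------------------

def sample_spec_from_dict(cfg: dict) -> SampleSpec:
    pops = []
    for name, entry in cfg.get("populations", {}).items():
        pops.append(PopulationSpec.from_sds(
            name, float(entry["weight"]), entry["mean"], entry["sd"]))
    if not pops:
        pops = list(default_populations())
    spec = SampleSpec(tuple(pops),
                      n_events=int(cfg.get("n_events", 20_000)),
                      dialect=cfg.get("dialect", "analog"),
                      boundary_fraction=float(cfg.get("boundary_fraction", 0.02)),
                      seed=int(cfg.get("seed", 0)))
    weights = {k: float(v) for k, v in cfg.get("weights", {}).items()}
    return spec.with_weights(**weights) if weights else spec


def load_sample_spec(path) -> SampleSpec:
    with open(path) as fh:
        return sample_spec_from_dict(yaml.safe_load(fh) or {})
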