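"""Automatic gating pipelines for FOXP3+ T cell subpopulations.

The established pipeline ("HKK") runs three steps on a preprocessed
sample: (1) CD4+ T cells are found by the subspace Gaussian mixture
(HDDC, k=3) on FSC/SSC/CD4 and the cluster with the highest CD4 centroid
is kept; (2) FOXP3+ cells are found by 1-D k-means (k=3) on FOXP3 within
the CD4+ cluster, keeping the cluster with the highest FOXP3 centroid;
(3) the FOXP3+ cells are subclassified by k-means (k=3) on
CD45RO/CD25/FOXP3 into effector-Treg-like (highest FOXP3 centroid),
naive-Treg-like (lowest CD45RO centroid of the remaining two) and
non-Treg-like clusters.

Competing variants swap engines: HH replaces step 2's k-means with a 1-D
Gaussian mixture; one-step-H replaces steps 1-2 with a single HDDC over
FSC/SSC/CD4/FOXP3; HKH replaces step 3's k-means with HDDC.

A manual-gating emulator (sequential rectangular gates, the historical
gold standard) and the FOXP3-high threshold calibration used by manual
gating are provided alongside.
"""

from __future__ import annotations

import logging
import math
import time
import warnings
from dataclasses import dataclass

import numpy as np

from .cluster import hddc_fit, kmeans_fit, select_cluster_by_centroid, _child_seeds
from .fcs_io import EventTable, ROLES
from .preprocess import BoundaryConfig, preprocess

logger = logging.getLogger(__name__)

IDENTIFICATION_METHODS = ("HK", "HH", "onestepH")
SUBCLASS_METHODS = ("kmeans", "hddc")

LABEL_REMOVED = "removed"
LABEL_NON_CD4 = "non_cd4"
LABEL_CD4_FOXP3NEG = "cd4_foxp3neg"
SUBSET_LABELS = ("effector_treg_like", "naive_treg_like", "non_treg_like")
ALL_LABELS = (LABEL_REMOVED, LABEL_NON_CD4, LABEL_CD4_FOXP3NEG) + SUBSET_LABELS

_CD4_CHANNELS = ("FSC", "SSC", "CD4")
_ONESTEP_CHANNELS = ("FSC", "SSC", "CD4", "FOXP3")
_SUB_CHANNELS = ("CD45RO", "CD25", "FOXP3")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Method choice plus every tunable of the gating chain.

    ``k`` values default to 3 everywhere: three scatter/CD4 clusters
    (debris, CD4-, CD4+), three FOXP3 strata (negative cloud split plus
    the positive cells) and three FOXP3+ subpopulations.
    """

    identification: str = "HK"
    subclassification: str = "kmeans"
    k_cd4: int = 3
    k_foxp3: int = 3
    k_sub: int = 3
    seed: int = 0
    kmeans_n_init: int = 10
    hddc_n_init: int = 5
    hddc_d_threshold: float = 0.2
    hddc_max_iter: int = 200
    hddc_tol: float = 1e-6
    degenerate_policy: str = "error"   # or "single_cluster"
    boundary: BoundaryConfig | None = None

    def __post_init__(self) -> None:
        if self.identification not in IDENTIFICATION_METHODS:
            raise ValueError(f"identification must be one of {IDENTIFICATION_METHODS}")
        if self.subclassification not in SUBCLASS_METHODS:
            raise ValueError(f"subclassification must be one of {SUBCLASS_METHODS}")
        if self.degenerate_policy not in ("error", "single_cluster"):
            raise ValueError("degenerate_policy must be 'error' or 'single_cluster'")

    @property
    def name(self) -> str:
        ident = {"HK": "HK", "HH": "HH", "onestepH": "one-step-H"}[self.identification]
        if self.identification == "HK":
            return "HK" + {"kmeans": "K", "hddc": "H"}[self.subclassification]
        return ident


def hkk_config(seed: int = 0, **kw) -> PipelineConfig:
    return PipelineConfig(identification="HK", subclassification="kmeans",
                          seed=seed, **kw)


def hkh_config(seed: int = 0, **kw) -> PipelineConfig:
    return PipelineConfig(identification="HK", subclassification="hddc",
                          seed=seed, **kw)


@dataclass
class GatingResult:
    """Per-event six-way labels plus derived summaries.

    ``fractions`` are percentages of the CD4+ parent set (for one-step-H,
    which never defines a CD4+ set, the selected FOXP3+ set is the
    denominator); ``mfi`` holds mean fluorescence intensities of the
    FOXP3+ subclusters on the logged, pre-standardization scale.
    """

    labels: np.ndarray
    fractions: dict[str, float]
    mfi: dict[str, dict[str, float]]
    config: PipelineConfig
    n_events: int = 0
    n_removed: int = 0
    n_cd4: int = 0
    n_foxp3: int = 0
    runtime_s: float = 0.0
    sub_centroids: np.ndarray | None = None

    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in ALL_LABELS}


def _cols(roles: tuple[str, ...]) -> list[int]:
    return [ROLES.index(r) for r in roles]


def _degenerate(values: np.ndarray) -> bool:
    return np.ptp(values, axis=0).max() <= 0


# ---------------------------------------------------------------------------
# Gating stages (all operate on the standardized table)
# ---------------------------------------------------------------------------

def gate_cd4(std_table: EventTable, config: PipelineConfig,
             seed: int) -> tuple[np.ndarray, object]:
    """CD4+ selection: HDDC (k=3) on FSC/SSC/CD4, highest-CD4 centroid.

    The defining rule of the published method names only the FOXP3 step's
    highest-centroid selection; picking the highest-CD4 centroid here is
    the analogous choice and is logged.
    """
    X = std_table.values[:, _cols(_CD4_CHANNELS)]
    model = hddc_fit(X, k=config.k_cd4, d_select_threshold=config.hddc_d_threshold,
                     max_iter=config.hddc_max_iter, tol=config.hddc_tol,
                     seed=seed, n_init=config.hddc_n_init, roles=_CD4_CHANNELS)
    chosen = select_cluster_by_centroid(model, "CD4", mode="max")
    logger.info("gate_cd4: cluster %d of %d selected (highest CD4 centroid)",
                chosen, config.k_cd4)
    return model.labels == chosen, model


def gate_foxp3(foxp3_values: np.ndarray, method: str, config: PipelineConfig,
               seed: int) -> np.ndarray:
    """FOXP3+ selection within CD4+: 1-D clustering (k=3), highest centroid."""
    if foxp3_values.shape[0] < config.k_foxp3:
        raise ValueError(f"need >= {config.k_foxp3} events for FOXP3 gating")
    X = foxp3_values.reshape(-1, 1)
    if _degenerate(X):
        if config.degenerate_policy == "single_cluster":
            warnings.warn("all FOXP3 values identical; passing through as one cluster")
            return np.ones(len(X), dtype=bool)
        raise ValueError("all FOXP3 values identical (degenerate input)")
    if method == "kmeans":
        fit = kmeans_fit(X, k=config.k_foxp3, seed=seed,
                         n_init=config.kmeans_n_init, roles=("FOXP3",))
    else:
        fit = hddc_fit(X, k=config.k_foxp3, seed=seed,
                       max_iter=config.hddc_max_iter, tol=config.hddc_tol,
                       n_init=config.hddc_n_init, roles=("FOXP3",))
    chosen = select_cluster_by_centroid(fit, "FOXP3", mode="max")
    return fit.labels == chosen


def gate_onestep(std_table: EventTable, config: PipelineConfig,
                 seed: int) -> tuple[np.ndarray, object]:
    """One-step FOXP3+CD4+ selection: a single HDDC over FSC/SSC/CD4/FOXP3.

    Among clusters whose CD4 centroid lies strictly above the median CD4
    centroid, the one with the highest FOXP3 centroid is selected.
    """
    roles = _ONESTEP_CHANNELS
    X = std_table.values[:, _cols(roles)]
    model = hddc_fit(X, k=config.k_cd4, d_select_threshold=config.hddc_d_threshold,
                     max_iter=config.hddc_max_iter, tol=config.hddc_tol,
                     seed=seed, n_init=config.hddc_n_init, roles=roles)
    cd4_idx = roles.index("CD4")
    fox_idx = roles.index("FOXP3")
    cd4_cent = model.centroids[:, cd4_idx]
    eligible = np.flatnonzero(cd4_cent > np.median(cd4_cent))
    if eligible.size == 0:       # all-tied CD4 centroids
        eligible = np.arange(model.k)
    chosen = eligible[np.argmax(model.centroids[eligible, fox_idx])]
    logger.info("gate_onestep: cluster %d selected (CD4 centroids %s)",
                chosen, np.round(cd4_cent, 3))
    return model.labels == int(chosen), model


def subclassify(sub_values: np.ndarray, method: str, config: PipelineConfig,
                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Partition FOXP3+ events into 3 clusters on CD45RO/CD25/FOXP3.

    Returns (cluster labels in 0..2, centroids (3, 3))."""
    if sub_values.shape[0] < config.k_sub:
        raise ValueError(f"need >= {config.k_sub} FOXP3+ events to subclassify")
    if _degenerate(sub_values):
        raise ValueError("degenerate FOXP3+ subset (no spread)")
    if method == "kmeans":
        fit = kmeans_fit(sub_values, k=config.k_sub, seed=seed,
                         n_init=config.kmeans_n_init, roles=_SUB_CHANNELS)
    else:
        fit = hddc_fit(sub_values, k=config.k_sub, seed=seed,
                       d_select_threshold=config.hddc_d_threshold,
                       max_iter=config.hddc_max_iter, tol=config.hddc_tol,
                       n_init=config.hddc_n_init, roles=_SUB_CHANNELS)
    return fit.labels, np.asarray(fit.centroids)


def assign_subset_labels(centroids: np.ndarray) -> dict[int, str]:
    """Map 3 subcluster centroids (CD45RO, CD25, FOXP3) to subset names.

    Highest FOXP3 centroid -> effector-Treg-like; of the remaining two the
    lower CD45RO centroid -> naive-Treg-like; the last -> non-Treg-like.
    Exact ties go to the lowest cluster index with a warning.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (3, 3):
        raise ValueError(f"expected 3 centroids with 3 coordinates, got "
                         f"{centroids.shape}")
    fox = centroids[:, 2]
    eff_hits = np.flatnonzero(fox == fox.max())
    if eff_hits.size > 1:
        warnings.warn(f"FOXP3 centroid tie between clusters {eff_hits.tolist()}; "
                      f"choosing index {eff_hits[0]}")
    eff = int(eff_hits[0])
    rest = [i for i in range(3) if i != eff]
    ro = centroids[rest, 0]
    naive_hits = np.flatnonzero(ro == ro.min())
    if naive_hits.size > 1:
        warnings.warn("CD45RO centroid tie; choosing lowest cluster index")
    naive = rest[int(naive_hits[0])]
    non = next(i for i in rest if i != naive)
    return {eff: "effector_treg_like", naive: "naive_treg_like",
            non: "non_treg_like"}


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(table: EventTable, config: PipelineConfig) -> GatingResult:
    """Preprocess -> identify FOXP3+CD4+ -> subclassify -> label.

    All stage seeds are derived from ``config.seed`` via seed-sequence
    splitting, so one integer reproduces the whole chain.
    """
    t0 = time.perf_counter()
    n = table.n_events
    seeds = _child_seeds(config.seed, 3)

    try:
        std, logged, removed_mask, _params = preprocess(table, config.boundary)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineStageError("preprocess", e) from e

    labels = np.full(n, LABEL_NON_CD4, dtype="U20")
    labels[removed_mask] = LABEL_REMOVED
    retained_idx = np.flatnonzero(~removed_mask)

    try:
        if config.identification in ("HK", "HH"):
            cd4_mask, _ = gate_cd4(std, config, seeds[0])
            cd4_idx = retained_idx[cd4_mask]
            method = "kmeans" if config.identification == "HK" else "hddc"
            fox_vals = std.values[cd4_mask, ROLES.index("FOXP3")]
            fox_mask_local = gate_foxp3(fox_vals, method, config, seeds[1])
            fox_idx = cd4_idx[fox_mask_local]
            labels[cd4_idx] = LABEL_CD4_FOXP3NEG
            parent_n = cd4_idx.size
        else:
            fox_mask, _ = gate_onestep(std, config, seeds[0])
            fox_idx = retained_idx[fox_mask]
            parent_n = fox_idx.size
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("identification", e) from e

    try:
        sub_cols = _cols(_SUB_CHANNELS)
        pos = np.isin(np.arange(n), fox_idx)
        sub_std = std.values[pos[~removed_mask]][:, sub_cols]
        sub_labels, centroids = subclassify(
            sub_std, config.subclassification, config, seeds[2])
        mapping = assign_subset_labels(centroids)
        for ci, name in mapping.items():
            labels[fox_idx[sub_labels == ci]] = name
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("subclassification", e) from e

    # summaries: percentages of the CD4+ parent, MFIs on the logged scale
    logged_full = np.full((n, len(ROLES)), np.nan)
    logged_full[~removed_mask] = logged.values
    fractions: dict[str, float] = {}
    mfi: dict[str, dict[str, float]] = {}
    denom = max(parent_n, 1)
    for name in SUBSET_LABELS:
        in_sub = labels == name
        fractions[name] = 100.0 * in_sub.sum() / denom
        mfi[name] = {r: float(np.mean(logged_full[in_sub, ROLES.index(r)]))
                     if in_sub.any() else float("nan")
                     for r in _SUB_CHANNELS}
    fractions["foxp3_total"] = float(sum(fractions[s] for s in SUBSET_LABELS))

    return GatingResult(
        labels=labels, fractions=fractions, mfi=mfi, config=config,
        n_events=n, n_removed=int(removed_mask.sum()),
        n_cd4=int(parent_n if config.identification != "onestepH" else 0),
        n_foxp3=int(fox_idx.size), runtime_s=time.perf_counter() - t0,
        sub_centroids=centroids)


# ---------------------------------------------------------------------------
# Manual-gating emulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManualGateSpec:
    """Sequential manual gates.

    The lymphocyte gate is a rectangle or polygon on raw FSC x SSC; the
    CD4 gate combines a log10-CD4 threshold with an SSC ceiling; FOXP3 and
    CD45RO thresholds are in log10-decade units.  ``foxp3_high_split``
    separates FOXP3-high (effector) from FOXP3-low cells and is the value
    the calibration routine below tunes on healthy controls.
    """

    lymph_fsc: tuple[float, float] = (250.0, 900.0)
    lymph_ssc: tuple[float, float] = (0.0, 600.0)
    lymph_polygon: tuple[tuple[float, float], ...] | None = None
    cd4_min: float = 2.3
    cd4_ssc_max: float = 600.0
    foxp3_pos: float = 1.6
    foxp3_high_split: float = 2.55
    cd45ro_pos: float = 1.7

    def __post_init__(self) -> None:
        if self.foxp3_high_split <= self.foxp3_pos:
            raise ValueError("foxp3_high_split must exceed foxp3_pos")
        if self.lymph_polygon is not None and len(self.lymph_polygon) < 3:
            raise ValueError("lymphocyte polygon needs >= 3 vertices")


def _point_in_polygon(x: np.ndarray, y: np.ndarray,
                      poly: tuple[tuple[float, float], ...]) -> np.ndarray:
    inside = np.zeros(len(x), dtype=bool)
    px, py = zip(*poly)
    n = len(poly)
    for i in range(n):
        x1, y1, x2, y2 = px[i], py[i], px[(i + 1) % n], py[(i + 1) % n]
        crosses = ((y1 > y) != (y2 > y))
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    return inside


def manual_gate(table: EventTable, spec: ManualGateSpec | None = None) -> np.ndarray:
    """Emulate sequential manual gating; returns six-way labels.

    No boundary removal happens here (a human gates the raw sample), so
    the ``removed`` label never occurs; everything failing the lymphocyte
    or CD4 gates is ``non_cd4``.
    """
    spec = spec or ManualGateSpec()
    if not table.is_raw():
        raise ValueError("manual gating expects a raw-scale table")
    v = table.values
    fsc, ssc = v[:, ROLES.index("FSC")], v[:, ROLES.index("SSC")]
    with np.errstate(divide="ignore"):
        cd4 = np.log10(np.maximum(v[:, ROLES.index("CD4")], 1e-12))
        ro = np.log10(np.maximum(v[:, ROLES.index("CD45RO")], 1e-12))
        fox = np.log10(np.maximum(v[:, ROLES.index("FOXP3")], 1e-12))

    if spec.lymph_polygon is not None:
        lymph = _point_in_polygon(fsc, ssc, spec.lymph_polygon)
    else:
        lymph = ((fsc >= spec.lymph_fsc[0]) & (fsc <= spec.lymph_fsc[1])
                 & (ssc >= spec.lymph_ssc[0]) & (ssc <= spec.lymph_ssc[1]))
    cd4_pos = lymph & (cd4 >= spec.cd4_min) & (ssc <= spec.cd4_ssc_max)
    fox_pos = cd4_pos & (fox >= spec.foxp3_pos)

    labels = np.full(table.n_events, LABEL_NON_CD4, dtype="U20")
    labels[cd4_pos] = LABEL_CD4_FOXP3NEG
    high = fox_pos & (fox >= spec.foxp3_high_split)
    low = fox_pos & ~high
    labels[high] = "effector_treg_like"
    labels[low & (ro < spec.cd45ro_pos)] = "naive_treg_like"
    labels[low & (ro >= spec.cd45ro_pos)] = "non_treg_like"
    return labels


def calibrate_foxp3_high_threshold(hc_tables: list[EventTable],
                                   spec: ManualGateSpec | None = None,
                                   cap: float = 0.002) -> float:
    """Smallest FOXP3-high split (log10 units) keeping CD45RO-FOXP3^high
    cells below ``cap`` of CD4+ lymphocytes in *every* healthy-control
    sample.

    Raising ``cap`` never raises the returned threshold.
    """
    if cap <= 0:
        raise ValueError("cap must be > 0")
    if not hc_tables:
        raise ValueError("need at least one healthy-control sample")
    spec = spec or ManualGateSpec()
    per_sample: list[float] = []
    for table in hc_tables:
        labels = manual_gate(table, spec)
        cd4_mask = labels != LABEL_NON_CD4
        n_cd4 = int(cd4_mask.sum())
        if n_cd4 == 0:
            raise ValueError("a sample has no CD4+ events under the manual gates")
        v = table.values
        with np.errstate(divide="ignore"):
            ro = np.log10(np.maximum(v[:, ROLES.index("CD45RO")], 1e-12))
            fox = np.log10(np.maximum(v[:, ROLES.index("FOXP3")], 1e-12))
        ro_neg_fox = np.sort(fox[cd4_mask & (ro < spec.cd45ro_pos)])[::-1]
        # events counted as high satisfy fox >= t; need count < cap * n_cd4
        c_max = math.ceil(cap * n_cd4 - 1e-9) - 1
        if c_max < 0:
            t = float(np.nextafter(ro_neg_fox[0], np.inf)) if ro_neg_fox.size \
                else float(fox[cd4_mask].min())
        elif ro_neg_fox.size <= c_max:
            t = float(fox[cd4_mask].min())
        else:
            t = float(np.nextafter(ro_neg_fox[c_max], np.inf))
        per_sample.append(t)
    return max(per_sample)
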