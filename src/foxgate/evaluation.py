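"""Resampling-based evaluation of the gating pipelines.

Identification methods (HK, HH, one-step-H) are compared by repeatedly
subsampling events from a source sample, running each method, and scoring
the selected FOXP3+CD4+ set against a gold standard (simulation ground
truth by default, or the manual-gating emulator).  Subclassification
stability (HKK vs HKH) is addressed with the same machinery by looking at
the spread (IQR) of subcluster percentages and MFIs across replicates.

Sensitivity is TP/(TP+FN) and accuracy (TP+TN)/N, computed over the
events retained by preprocessing.
"""

from __future__ import annotations

import logging
import warnings
from collections import namedtuple
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .fcs_io import EventTable
from .pipeline import (LABEL_REMOVED, PipelineConfig, SUBSET_LABELS,
                       ManualGateSpec, manual_gate, run_pipeline)
from .synthetic import FOXP3_POS

logger = logging.getLogger(__name__)

Confusion = namedtuple("Confusion", ["tp", "fp", "fn", "tn"])


def confusion(auto_mask: np.ndarray, gold_mask: np.ndarray) -> Confusion:
    """2x2 confusion counts for two boolean masks over the same events."""
    auto_mask = np.asarray(auto_mask, dtype=bool)
    gold_mask = np.asarray(gold_mask, dtype=bool)
    if auto_mask.shape != gold_mask.shape:
        raise ValueError(f"mask length mismatch: {auto_mask.shape} vs "
                         f"{gold_mask.shape}")
    tp = int((auto_mask & gold_mask).sum())
    fp = int((auto_mask & ~gold_mask).sum())
    fn = int((~auto_mask & gold_mask).sum())
    tn = int((~auto_mask & ~gold_mask).sum())
    return Confusion(tp, fp, fn, tn)


def sensitivity(conf: Confusion) -> float:
    """TP/(TP+FN); defined as 1.0 for an empty gold set (with a warning)."""
    pos = conf.tp + conf.fn
    if pos == 0:
        warnings.warn("empty gold-positive set; sensitivity defined as 1.0")
        return 1.0
    return conf.tp / pos


def accuracy(conf: Confusion) -> float:
    total = sum(conf)
    if total == 0:
        raise ValueError("confusion over zero events")
    return (conf.tp + conf.tn) / total


@dataclass(frozen=True)
class ResamplingPlan:
    """Conditions of a resampling experiment.

    Each (method, cell_number, seed) condition draws ``n_reps`` subsamples
    without replacement (``bootstrap=True`` switches to with-replacement)
    and runs the method on each.
    """

    cell_numbers: tuple[int, ...]
    methods: tuple[PipelineConfig, ...]
    n_reps: int = 100
    seeds: tuple[int, ...] = (0,)
    gold: str = "ground_truth"     # or "manual_gate"
    bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.gold not in ("ground_truth", "manual_gate"):
            raise ValueError("gold must be 'ground_truth' or 'manual_gate'")
        if not self.methods:
            raise ValueError("plan needs at least one method")


def _gold_mask(plan: ResamplingPlan, truth_labels: np.ndarray | None,
               table: EventTable, manual_spec: ManualGateSpec | None) -> np.ndarray:
    if plan.gold == "ground_truth":
        if truth_labels is None:
            raise ValueError("ground-truth gold requested but no labels supplied")
        return np.isin(truth_labels, FOXP3_POS)
    return np.isin(manual_gate(table, manual_spec), SUBSET_LABELS)


def resample_experiment(table: EventTable, truth_labels: np.ndarray | None,
                        plan: ResamplingPlan,
                        manual_spec: ManualGateSpec | None = None) -> pd.DataFrame:
    """Run the full resampling grid; one row per (method, condition, rep).

    Columns: method, cell_number, seed, rep, sensitivity, accuracy,
    pct_<subset> and mfi_<subset>_<channel>.
    """
    if max(plan.cell_numbers) > table.n_events:
        raise ValueError(f"cell_number {max(plan.cell_numbers)} exceeds "
                         f"sample size {table.n_events}")
    gold_all = _gold_mask(plan, truth_labels, table, manual_spec)
    rows: list[dict] = []
    for seed in plan.seeds:
        for cell_number in plan.cell_numbers:
            rng = np.random.default_rng(np.random.SeedSequence([seed, cell_number]))
            for rep in range(plan.n_reps):
                idx = rng.choice(table.n_events, size=cell_number,
                                 replace=plan.bootstrap)
                sub = table.subset(idx)
                gold_sub = gold_all[idx]
                rep_seed = int(rng.integers(0, 2**31 - 1))
                for cfg in plan.methods:
                    result = run_pipeline(sub, dc_replace(cfg, seed=rep_seed))
                    retained = result.labels != LABEL_REMOVED
                    auto = np.isin(result.labels, SUBSET_LABELS)[retained]
                    conf = confusion(auto, gold_sub[retained])
                    row = {"method": cfg.name, "cell_number": cell_number,
                           "seed": seed, "rep": rep,
                           "sensitivity": sensitivity(conf),
                           "accuracy": accuracy(conf)}
                    for sub_name in SUBSET_LABELS:
                        row[f"pct_{sub_name}"] = result.fractions[sub_name]
                        for ch, val in result.mfi[sub_name].items():
                            row[f"mfi_{sub_name}_{ch}"] = val
                    rows.append(row)
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame,
                     by: tuple[str, ...] = ("method", "cell_number")) -> pd.DataFrame:
    """Mean, SD and IQR of every metric per condition (recomputable from rows)."""
    metrics = [c for c in report.columns
               if c not in ("method", "cell_number", "seed", "rep")]
    def iqr(x):  # noqa: E306
        return np.subtract(*np.percentile(x.dropna(), [75, 25])) if x.notna().any() else np.nan
    agg = report.groupby(list(by))[metrics].agg(["mean", "std", iqr])
    agg.columns = [f"{m}_{s if s != 'iqr' else 'iqr'}" for m, s in agg.columns]
    return agg.reset_index()


def concordance(auto_results: pd.DataFrame,
                manual_results: pd.DataFrame) -> dict[str, float]:
    """Per-subpopulation Pearson r between paired per-sample percentages."""
    common = [c for c in auto_results.columns if c in manual_results.columns]
    if not common:
        raise ValueError("no shared subpopulation columns")
    out = {}
    for col in common:
        x = np.asarray(auto_results[col], float)
        y = np.asarray(manual_results[col], float)
        if len(x) != len(y):
            raise ValueError("auto and manual results must pair per sample")
        if len(x) < 3:
            raise ValueError("need >= 3 paired samples for a correlation")
        out[col] = float(pearsonr(x, y).statistic)
    return out
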