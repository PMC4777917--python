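"""Cohort-level summaries and nonparametric group comparisons.

Per-sample summaries carry the percentages of CD4+ for the three FOXP3+
subpopulations (and their total).  Two-group designs are tested with a
two-sided Mann-Whitney-Wilcoxon (MWW) test per subpopulation; staged
designs (healthy controls vs disease stages) use a Kruskal-Wallis test
per subpopulation followed by pairwise MWW tests.  All p values are
Bonferroni-adjusted: the subpopulation family has m = 3; the pairwise
family defaults to the stage-vs-control comparisons (m = number of
stages), with all-pairs as an option.

MWW p values are exact (full permutation distribution) when the combined
sample size is at most 20 and no ties are present; otherwise the normal
approximation with midranks and tie-corrected variance is used, without
continuity correction (so identical groups give p = 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import GatingResult, SUBSET_LABELS

logger = logging.getLogger(__name__)

EXACT_MWW_MAX_N = 20


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    status: str
    pct: dict[str, float]                # subset -> % of CD4+ (plus total)
    mfi: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.pct.values()):
            raise ValueError("percentages must be >= 0")


def summarize_sample(result: GatingResult, sample_id: str,
                     status: str) -> SampleSummary:
    return SampleSummary(sample_id=sample_id, status=status,
                         pct=dict(result.fractions), mfi=result.mfi)


def summaries_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"sample_id": s.sample_id, "status": s.status}
        row.update(s.pct)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def mww_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U of x, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= EXACT_MWW_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_test(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-squared p on k-1 df."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis needs >= 3 groups (use mww_test)")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    if np.unique(np.concatenate(groups)).size == 1:
        return 0.0, 1.0  # all observations tied: no evidence against the null
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) for each p."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# Cohort comparison
# ---------------------------------------------------------------------------

def compare_cohort(summaries: pd.DataFrame | list[SampleSummary],
                   design: str = "two_group",
                   control: str = "HC",
                   pairwise_family: str = "vs_control") -> pd.DataFrame:
    """Test each FOXP3+ subpopulation's percentage across status groups.

    ``design='two_group'``: one MWW test per subpopulation, Bonferroni
    m = 3 over the subpopulations.  ``design='staged'``: a Kruskal-Wallis
    test per subpopulation (Bonferroni m = 3), then pairwise MWW tests
    with Bonferroni over the pairwise family (``vs_control`` or
    ``all_pairs``).

    Returns one row per test: subpopulation, comparison, test, statistic,
    p_raw, p_adj, m.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = summaries_frame(summaries)
    if "status" not in summaries.columns:
        raise ValueError("summaries must carry a 'status' column")
    statuses = list(dict.fromkeys(summaries["status"]))
    if len(statuses) < 2:
        raise ValueError("need >= 2 status groups")
    if any((summaries["status"] == s).sum() < 2 for s in statuses):
        raise ValueError("every status group needs >= 2 samples")
    groups = {s: summaries[summaries["status"] == s] for s in statuses}

    rows: list[dict] = []
    m_sub = len(SUBSET_LABELS)
    if design == "two_group":
        if len(statuses) != 2:
            raise ValueError("two_group design requires exactly 2 statuses")
        a, b = statuses
        for sub in SUBSET_LABELS:
            u, p = mww_test(groups[a][sub], groups[b][sub])
            rows.append({"subpopulation": sub, "comparison": f"{a} vs {b}",
                         "test": "MWW", "statistic": u, "p_raw": p, "m": m_sub})
    elif design == "staged":
        for sub in SUBSET_LABELS:
            h, p = kruskal_test([groups[s][sub] for s in statuses])
            rows.append({"subpopulation": sub, "comparison": "all statuses",
                         "test": "Kruskal-Wallis", "statistic": h,
                         "p_raw": p, "m": m_sub})
        if pairwise_family == "vs_control":
            if control not in statuses:
                raise ValueError(f"control status {control!r} not present")
            pairs = [(control, s) for s in statuses if s != control]
        elif pairwise_family == "all_pairs":
            pairs = list(itertools.combinations(statuses, 2))
        else:
            raise ValueError("pairwise_family must be 'vs_control' or 'all_pairs'")
        m_pair = len(pairs)
        for sub in SUBSET_LABELS:
            for a, b in pairs:
                u, p = mww_test(groups[a][sub], groups[b][sub])
                rows.append({"subpopulation": sub, "comparison": f"{a} vs {b}",
                             "test": "MWW (pairwise)", "statistic": u,
                             "p_raw": p, "m": m_pair})
    else:
        raise ValueError("design must be 'two_group' or 'staged'")

    df = pd.DataFrame(rows)
    df["p_adj"] = [float(bonferroni([p], m=m)[0])
                   for p, m in zip(df["p_raw"], df["m"])]
    return df[["subpopulation", "comparison", "test", "statistic",
               "p_raw", "p_adj", "m"]]
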