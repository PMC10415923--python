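"""Comparative statistics between digital-twin communities.

Four downstream comparisons of DT+ vs DT- (or mutant vs wildtype):

* marker abundance — Wilcoxon rank-sum per immune marker with BH
  adjustment across markers;
* survival — Kaplan-Meier product-limit curves and the two-group log-rank
  test;
* gain/loss of function — mutant vs wildtype expression of a gene,
  direction called from the medians when the Wilcoxon test is significant;
* drug sensitivity — per-compound z-scores of ln(IC50) over all cell
  lines, compounds ranked by the median z over the case-matched lines
  (lower = more sensitive).

The rank-sum and survival machinery is delegated to scipy and lifelines;
tests verify them against enumeration and hand-computed product-limit
oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComparativeError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n_censored: int


@dataclass(frozen=True)
class GofLofCall:
    gene: str
    direction: str  # potential_gain | potential_loss | indeterminate | insufficient_samples
    p_value: float | None
    median_mutant: float | None
    median_wildtype: float | None
    n_mutant: int
    n_wildtype: int
    modality: str = "mrna"


@dataclass(frozen=True)
class SensitivityRow:
    compound: str
    n_lines: int
    median_log_ic50: float
    relative_z: float
    rank: int  # 1 = most sensitive


def wilcoxon_ranksum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    ``exact`` enumerates the null distribution over all C(nx+ny, nx) rank
    assignments and is permitted only for nx+ny <= 20 with no ties;
    ``normal`` uses the tie- and continuity-corrected normal
    approximation.  ``auto`` picks exact when permitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ComparativeError("empty sample in Wilcoxon test")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= 20 and not has_ties) else "normal"
    if mode == "exact":
        if pooled.size > 20:
            raise ComparativeError("exact mode permitted only for nx+ny <= 20")
        if has_ties:
            raise ComparativeError("exact mode permitted only without ties")
        method = "exact"
    elif mode == "normal":
        method = "asymptotic"
    else:
        raise ComparativeError(f"unknown Wilcoxon mode {mode!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    return w, float(res.pvalue)


def km_estimate(
    times: Sequence[float], events: Sequence[int]
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i).

    Subjects censored at an event time remain in the risk set for that
    event.  Returns the curve at the distinct times with >= 1 event; with
    all observations censored the curve is identically 1 (empty steps).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ComparativeError("times and events must have equal length")
    if np.any(times < 0):
        raise ComparativeError("negative survival time")
    if not np.all(np.isin(events, [0, 1])):
        raise ComparativeError("events must be 0/1")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    steps = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    event_times = [float(t) for t in steps.index]
    return SurvivalCurve(
        event_times=tuple(event_times),
        survival=tuple(float(surv.loc[t]) for t in steps.index),
        at_risk=tuple(int(v) for v in steps["at_risk"]),
        n_censored=int(events.size - events.sum()),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic df=1, p-value).

    Statistic = (sum O-E)^2 / sum V with the hypergeometric variance at
    each distinct event time.  Symmetric in group labels.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ComparativeError("both survival groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ComparativeError("no events in either group; log-rank statistic undefined")
    from lifelines.statistics import logrank_test as _ll_logrank

    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def compare_markers(
    markers: pd.DataFrame,
    dt_positive: Iterable[str],
    dt_negative: Iterable[str],
    missing_flag_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-marker DT+ vs DT- comparison.

    ``markers`` is samples (rows) x marker names (columns), abundances
    >= 0.  Returns per marker the group medians, Wilcoxon p, BH-adjusted
    p across markers, group sizes, and a flag for markers missing in more
    than ``missing_flag_fraction`` of community samples.
    """
    pos = [s for s in dt_positive if s in markers.index]
    neg = [s for s in dt_negative if s in markers.index]
    if not pos or not neg:
        raise ComparativeError("both communities need at least one sample with marker data")
    rows = []
    n_community = len(pos) + len(neg)
    for marker in markers.columns:
        a = pd.to_numeric(markers.loc[pos, marker], errors="coerce").dropna()
        b = pd.to_numeric(markers.loc[neg, marker], errors="coerce").dropna()
        if len(a) == 0 or len(b) == 0:
            logger.warning("compare_markers: marker %r has no data in one community", marker)
            continue
        _, p = wilcoxon_ranksum(a.to_numpy(), b.to_numpy(), mode="normal")
        rows.append(
            {
                "marker": marker,
                "median_positive": float(a.median()),
                "median_negative": float(b.median()),
                "n_positive": len(a),
                "n_negative": len(b),
                "p_value": p,
                "high_missingness": (len(a) + len(b)) < (1 - missing_flag_fraction) * n_community,
            }
        )
    if not rows:
        raise ComparativeError("no marker shared by both communities")
    frame = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(frame["p_value"], method="fdr_bh")
    frame["p_adjusted"] = adj
    return frame[
        ["marker", "median_positive", "median_negative", "n_positive",
         "n_negative", "p_value", "p_adjusted", "high_missingness"]
    ]


def gof_lof_call(
    expression: pd.DataFrame,
    mutant: Iterable[str],
    wildtype: Iterable[str],
    gene: str,
    alpha: float = 0.05,
    min_group: int = 3,
    modality: str = "mrna",
) -> GofLofCall:
    """Call a gene's mutations as potential gain or loss of function.

    ``expression`` is genes (rows) x samples (columns).  Mutant vs
    wildtype expression is compared by Wilcoxon rank-sum; p < alpha with a
    higher mutant median is a potential gain, with a lower mutant median a
    potential loss; otherwise indeterminate.  Either group below
    ``min_group`` yields ``insufficient_samples`` (no test).
    """
    gene = gene.upper()
    if gene not in expression.index:
        raise ComparativeError(f"gene {gene!r} absent from expression matrix")
    row = pd.to_numeric(expression.loc[gene], errors="coerce")
    mut = row[[s for s in mutant if s in row.index]].dropna()
    wt = row[[s for s in wildtype if s in row.index]].dropna()
    if len(mut) < min_group or len(wt) < min_group:
        return GofLofCall(gene, "insufficient_samples", None, None, None,
                          len(mut), len(wt), modality)
    _, p = wilcoxon_ranksum(mut.to_numpy(), wt.to_numpy(), mode="normal")
    med_m, med_w = float(mut.median()), float(wt.median())
    if p < alpha and med_m > med_w:
        direction = "potential_gain"
    elif p < alpha and med_m < med_w:
        direction = "potential_loss"
    else:
        direction = "indeterminate"
    return GofLofCall(gene, direction, p, med_m, med_w, len(mut), len(wt), modality)


def rank_drug_sensitivity(
    ic50: pd.DataFrame,
    matched_lines: Iterable[str],
    compounds: Sequence[str] | None = None,
) -> list[SensitivityRow]:
    """Rank compounds by relative sensitivity of the matched cell lines.

    ``ic50`` is compounds (rows) x cell lines (columns), raw IC50 values.
    Per compound, ln(IC50) is standardized to a z-score over *all* lines
    in the table; ``relative_z`` is the median z over the matched lines
    (missing values excluded per compound).  Rank 1 = lowest relative_z =
    most sensitive; ties broken by compound name.
    """
    if compounds is None:
        compounds = list(ic50.index)
    matched = [c for c in matched_lines if c in ic50.columns]
    rows = []
    for compound in compounds:
        if compound not in ic50.index:
            logger.warning("rank_drug_sensitivity: compound %r not in IC50 table", compound)
            continue
        vals = pd.to_numeric(ic50.loc[compound], errors="coerce")
        log_all = np.log(vals.astype(float))
        mu, sd = float(log_all.mean()), float(log_all.std(ddof=1))
        z = (log_all - mu) / sd if sd > 0 else log_all * 0.0
        z_matched = z[[c for c in matched if np.isfinite(z.get(c, np.nan))]].dropna()
        if len(z_matched) == 0:
            logger.warning(
                "rank_drug_sensitivity: no matched line has IC50 for %r", compound
            )
            continue
        rows.append(
            {
                "compound": compound,
                "n_lines": int(len(z_matched)),
                "median_log_ic50": float(np.median(np.log(vals[z_matched.index]))),
                "relative_z": float(z_matched.median()),
            }
        )
    if not rows:
        raise ComparativeError("no requested compound present with matched-line IC50 data")
    rows.sort(key=lambda r: (r["relative_z"], r["compound"]))
    return [
        SensitivityRow(r["compound"], r["n_lines"], r["median_log_ic50"],
                       r["relative_z"], i + 1)
        for i, r in enumerate(rows)
    ]


def sensitivity_frame(rows: Sequence[SensitivityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"compound": r.compound, "n_lines": r.n_lines,
             "median_log_ic50": r.median_log_ic50,
             "relative_z": r.relative_z, "rank": r.rank}
            for r in rows
        ],
        columns=["compound", "n_lines", "median_log_ic50", "relative_z", "rank"],
    )
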