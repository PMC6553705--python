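"""Structure–behavior coupling analysis.

Quantifies how weekly social-network structure co-varies with weekly wearable
behavior:

* **cohort level** — for each of the 60 pairs (5 structural metrics x 2
  network variants x 6 behavioral weekly means), the zero-lag normalized
  cross-correlation (Pearson) of the two cross-participant weekly central
  tendency series over the study weeks, with a two-sided t-based p-value;
* **person level** — the same coefficient per participant, counting how many
  participants reach |r| >= tau for each pair and, per behavior feature, for
  at least one structural feature of the participant / whole / either
  network;
* **high/low tests** — per pair, weeks are median-split on the structure
  series and the behavior values of high vs low weeks compared with a Welch
  t-test, Benjamini–Hochberg-corrected across the 60 tests.

Constant series have no defined correlation; they are flagged and never
counted as correlated.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior_features import BEHAVIOR_MEANS
from .network_builder import NETWORK_VARIANTS, STRUCTURE_METRICS

logger = logging.getLogger("netwell")

#: The 10 structure columns of the wide feature table, in fixed order.
STRUCTURE_COLUMNS = tuple(
    f"{metric}_{variant}" for variant in NETWORK_VARIANTS for metric in STRUCTURE_METRICS
)

#: All 60 (structure, behavior) pairs.
ALL_PAIRS = tuple((s, b) for s in STRUCTURE_COLUMNS for b in BEHAVIOR_MEANS)


@dataclasses.dataclass(frozen=True)
class NccResult:
    r: float
    p: float
    n: int
    defined: bool = True


@dataclasses.dataclass(frozen=True)
class HighLowTestResult:
    structure_feature: str
    behavior_feature: str
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


def ncc(x: Sequence[float], y: Sequence[float]) -> NccResult:
    """Zero-lag normalized cross-correlation of two equal-length series.

    Missing weeks are removed pairwise first.  This is the Pearson product-
    moment coefficient; the p-value is two-sided from
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  A constant series
    (or fewer than 3 usable points) has no defined coefficient and is
    returned flagged, never raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return NccResult(math.nan, math.nan, n, defined=False)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
    if denom == 0:  # spread below float resolution: no usable variance
        return NccResult(math.nan, math.nan, n, defined=False)
    r = float(np.dot(xc, yc) / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return NccResult(r, p, n)


def ncc_lag_scan(x, y, max_lag: int) -> dict[int, NccResult]:
    """Normalized cross-correlation over integer lags (y shifted by ``lag``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = {}
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            out[lag] = ncc(x[: len(x) - lag or None], y[lag:])
        else:
            out[lag] = ncc(x[-lag:], y[:lag])
    return out


def cohort_weekly_series(
    feature_table: pd.DataFrame, stat: str = "mean"
) -> pd.DataFrame:
    """Cross-participant weekly central tendency (mean or median) of every
    structure and behavior column; one row per week."""
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    cols = [c for c in (*STRUCTURE_COLUMNS, *BEHAVIOR_MEANS) if c in feature_table.columns]
    return feature_table.groupby("week")[cols].agg(stat)


def cohort_pair_matrix(
    feature_table: pd.DataFrame, stat: str = "mean"
) -> pd.DataFrame:
    """The 60-pair correlation matrix of cohort weekly series.

    Returns a frame with one row per (structure_feature, behavior_feature)
    pair: columns r, p, n, defined.
    """
    series = cohort_weekly_series(feature_table, stat=stat)
    rows = []
    for s_col, b_col in ALL_PAIRS:
        res = ncc(series[s_col].to_numpy(), series[b_col].to_numpy())
        rows.append(
            {
                "structure_feature": s_col,
                "behavior_feature": b_col,
                "r": res.r,
                "p": res.p,
                "n": res.n,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)


def count_pairs(matrix: pd.DataFrame, tau: float = 0.5) -> int:
    """Number of pairs with |r| >= tau; undefined entries never count."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    ok = matrix["defined"] & (matrix["r"].abs() >= tau)
    return int(ok.sum())


def matrix_as_table(matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pivot the pair matrix into the 10x6 report shape (structure rows,
    behavior columns) with a parallel boolean significance table."""
    r = matrix.pivot(index="structure_feature", columns="behavior_feature", values="r")
    sig = matrix.pivot(index="structure_feature", columns="behavior_feature", values="p") < alpha
    r = r.reindex(index=list(STRUCTURE_COLUMNS), columns=list(BEHAVIOR_MEANS))
    sig = sig.reindex(index=list(STRUCTURE_COLUMNS), columns=list(BEHAVIOR_MEANS))
    sig.columns = [f"{c}_significant" for c in sig.columns]
    return pd.concat([r, sig], axis=1)


# ---------------------------------------------------------------------------
# per-person counting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PersonCorrelationCounts:
    """Counts of participants with medium-to-strong per-person correlation."""

    tau: float
    denominator: int
    #: (structure_feature, behavior_feature) -> participant count
    pair_counts: dict
    #: behavior feature -> {participant, whole, either} -> count
    behavior_counts: dict
    excluded: list

    def percentages(self) -> dict:
        """Per behavior feature, round(100 * count / denominator), the integer
        percentage form used in cohort summaries."""
        return {
            b: {k: as_percent(c, self.denominator) for k, c in d.items()}
            for b, d in self.behavior_counts.items()
        }


def as_percent(count: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer, half away from zero."""
    return int(math.floor(100.0 * count / denominator + 0.5))


def per_person_counts(
    feature_table: pd.DataFrame,
    tau: float = 0.5,
    min_weeks: int = 3,
    signed: bool = False,
) -> PersonCorrelationCounts:
    """Count participants whose own weekly series reach the threshold.

    By default the comparison is |r| >= tau (inclusive); ``signed=True``
    counts r >= tau instead.  Participants with fewer than ``min_weeks``
    usable weeks are excluded from numerator and denominator (and listed).
    """
    pair_counts = {pair: 0 for pair in ALL_PAIRS}
    behavior_counts = {
        b: {"participant": 0, "whole": 0, "either": 0} for b in BEHAVIOR_MEANS
    }
    excluded: list[str] = []
    n_counted = 0
    for participant, g in feature_table.groupby("participant"):
        g = g.sort_values("week")
        if len(g) < min_weeks:
            excluded.append(str(participant))
            continue
        n_counted += 1
        hits_by_behavior: dict[str, set[str]] = {b: set() for b in BEHAVIOR_MEANS}
        for s_col, b_col in ALL_PAIRS:
            res = ncc(g[s_col].to_numpy(), g[b_col].to_numpy())
            if not res.defined:
                continue
            hit = res.r >= tau if signed else abs(res.r) >= tau
            if hit:
                pair_counts[(s_col, b_col)] += 1
                variant = "participant" if s_col.endswith("_participant") else "whole"
                hits_by_behavior[b_col].add(variant)
        for b_col, variants in hits_by_behavior.items():
            for v in variants:
                behavior_counts[b_col][v] += 1
            if variants:
                behavior_counts[b_col]["either"] += 1
    if excluded:
        logger.info("per_person_counts: excluded %d participant(s) with < %d weeks",
                    len(excluded), min_weeks)
    return PersonCorrelationCounts(
        tau=tau,
        denominator=n_counted,
        pair_counts=pair_counts,
        behavior_counts=behavior_counts,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# high/low tests
# ---------------------------------------------------------------------------

def high_low_tests(
    feature_table: pd.DataFrame,
    stat: str = "mean",
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> list[HighLowTestResult]:
    """Median-split Welch t-tests on the cohort weekly series, corrected.

    For each pair, weeks are split by the median of the structure series;
    the behavior values of high vs low weeks are compared with a Welch
    two-sample t-test.  P-values are adjusted across the 60 tests
    (Benjamini–Hochberg by default; ``method='bonferroni'`` available).
    Degenerate splits (a side with < 2 weeks) are skipped and logged.
    """
    series = cohort_weekly_series(feature_table, stat=stat)
    tested: list[tuple[str, str, float, float]] = []
    for s_col, b_col in ALL_PAIRS:
        s = series[s_col].to_numpy()
        b = series[b_col].to_numpy()
        keep = ~(np.isnan(s) | np.isnan(b))
        s, b = s[keep], b[keep]
        med = np.median(s)
        high = s > med
        low = s < med
        # weeks tied at the median join the low side so both sides stay populated
        tie = s == med
        low = low | tie
        if high.sum() < 2 or low.sum() < 2:
            logger.warning("high_low_tests: degenerate split for %s vs %s", s_col, b_col)
            continue
        t, p = stats.ttest_ind(b[high], b[low], equal_var=False)
        tested.append((s_col, b_col, float(t), float(p)))
    if not tested:
        return []
    p_raw = [p for *_, p in tested]
    reject, p_adj, *_ = multipletests(p_raw, alpha=alpha, method=method)
    return [
        HighLowTestResult(s_col, b_col, t, p, float(pa), bool(rej))
        for (s_col, b_col, t, p), pa, rej in zip(tested, p_adj, reject)
    ]


def anova_by_level(
    participant_means: pd.Series, labels: pd.Series
) -> tuple[float, float]:
    """One-way ANOVA of participant mean heart rate across ordinal levels.

    ``participant_means`` and ``labels`` are aligned by participant index;
    participants with a missing label are dropped.  Raises when fewer than
    two levels have at least two observations.
    """
    df = pd.DataFrame({"value": participant_means, "label": labels}).dropna()
    groups = [g["value"].to_numpy() for _, g in df.groupby("label") if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 levels with >= 2 observations each")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def pair_boxplot(feature_table: pd.DataFrame, structure_feature: str,
                 behavior_feature: str, path) -> None:
    """Weekly distributions of one structure/behavior pair with means and
    medians overlaid; twin y-axes since the scales differ."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    weeks = sorted(feature_table["week"].unique())
    s_data = [feature_table.loc[feature_table["week"] == w, structure_feature].dropna()
              for w in weeks]
    b_data = [feature_table.loc[feature_table["week"] == w, behavior_feature].dropna()
              for w in weeks]
    fig, ax1 = plt.subplots(figsize=(10, 4))
    ax2 = ax1.twinx()
    ax1.boxplot(b_data, positions=weeks, widths=0.55, showfliers=False)
    ax1.plot(weeks, [d.mean() for d in b_data], "-", color="tab:orange", label="behavior mean")
    ax1.plot(weeks, [d.median() for d in b_data], "^", color="darkgreen", label="behavior median")
    ax2.boxplot(s_data, positions=weeks, widths=0.3, showfliers=False,
                boxprops={"linestyle": "--", "color": "tab:blue"})
    ax2.plot(weeks, [d.mean() for d in s_data], "-", color="tab:blue", label="structure mean")
    ax1.set_xlabel("week")
    ax1.set_ylabel(behavior_feature)
    ax2.set_ylabel(structure_feature)
    ax1.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
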