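"""Group-level statistics: region split, contingency tables, Fisher's exact
tests with Woolf odds-ratio CIs, and permutation/bootstrap comparisons.

Recording sites are split into anterior and posterior parts of M1 and M2 at
AP = +1.5 mm from bregma. Response-type counts per region part form a count
table whose 2x2 collapses (responsive vs not, excitatory vs other, ...) are
compared between anterior and posterior with Fisher's exact test; effect
sizes are sample odds ratios with log-scale normal-approximation (Woolf)
95% confidence intervals. Continuous response measures (e.g. mean auROC in
+/-0.25 s) are compared with a permutation test of the median difference
plus a bootstrap percentile CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "PUBLISHED_COUNTS", "RESPONSIVE_TYPES",
    "assign_part", "fisher_exact_p", "odds_ratio_ci", "bonferroni",
    "mean_auroc_response", "permutation_median_test", "build_count_table",
    "contingency_from_counts", "region_comparisons",
]

AP_SPLIT_MM = 1.5  # boundary itself assigned posterior

RESPONSIVE_TYPES = ("E1", "E2", "I1", "I2", "I3", "I4", "O")

#: Published per-area response-type counts (rows: region x part), used as
#: the reference input for the anterior-vs-posterior contingency analyses.
PUBLISHED_COUNTS = pd.DataFrame(
    {
        "E1": [36, 18, 46, 13],
        "E2": [29, 10, 45, 3],
        "I1": [54, 14, 51, 11],
        "I2": [35, 8, 22, 2],
        "I3": [33, 4, 29, 0],
        "I4": [22, 3, 11, 1],
        "O": [62, 16, 48, 6],
        "NR": [584, 193, 485, 132],
    },
    index=pd.MultiIndex.from_tuples(
        [("M1", "A"), ("M1", "P"), ("M2", "A"), ("M2", "P")],
        names=["region", "part"],
    ),
)


def assign_part(ap: float) -> str:
    """'anterior' iff AP > 1.5 mm from bregma; the boundary is posterior."""
    return "anterior" if ap > AP_SPLIT_MM else "posterior"


def fisher_exact_p(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table (hypergeometric
    enumeration with margins fixed); degenerate margins give p = 1."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])


def odds_ratio_ci(table, level: float = 0.95):
    """Sample odds ratio with a Woolf (log-normal) confidence interval.

    OR = ad/bc; CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    Tables with a zero cell get the Haldane 0.5 continuity correction on
    every cell.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t == 0):
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    return float(orr), float(np.exp(np.log(orr) - z * se)), float(np.exp(np.log(orr) + z * se))


def bonferroni(p_values, repetitions: int):
    """Multiply p-values by the repetition count, capped at 1."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    return np.minimum(np.asarray(p_values, dtype=float) * repetitions, 1.0)


def mean_auroc_response(auroc_timecourse, window=(-0.25, 0.25),
                        bin_width: float = 0.05, t_start: float = -1.0) -> float:
    """Mean auROC over the bins covering ``window`` (must align to the grid)."""
    a = np.asarray(auroc_timecourse, dtype=float)
    i0 = (window[0] - t_start) / bin_width
    i1 = (window[1] - t_start) / bin_width
    if abs(i0 - round(i0)) > 1e-9 or abs(i1 - round(i1)) > 1e-9:
        raise ValueError("window does not align with the bin grid")
    return float(a[int(round(i0)):int(round(i1))].mean())


@dataclass
class EstimationResult:
    statistic: float  # median(A) - median(B)
    p_value: float
    ci_low: float
    ci_high: float
    n_permutations: int
    n_bootstrap: int
    seed: int
    exact: bool = False
    warning: str | None = None


def permutation_median_test(
    group_a, group_b, n_perm: int = 5000, n_boot: int = 5000,
    seed: int = 0, ci_level: float = 0.95, max_exact: int = 20000,
) -> EstimationResult:
    """Two-sided permutation test of the difference in medians with a
    bootstrap percentile CI.

    All label permutations are enumerated exhaustively when their number is
    at most ``max_exact`` (p = fraction of splits at least as extreme);
    otherwise ``n_perm`` random splits are drawn and the add-one-corrected
    p is reported.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    rng = np.random.default_rng(seed)
    obs = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    warning = None
    if comb(n, na) <= max_exact:
        stats = np.array([
            np.median(pooled[list(c)])
            - np.median(np.delete(pooled, list(c)))
            for c in combinations(range(n), na)
        ])
        p = float(np.mean(np.abs(stats) >= abs(obs) - 1e-12))
        n_used, exact = len(stats), True
    else:
        if n_perm < 100:
            warning = "n_perm < 100: p-value resolution is very coarse"
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(np.median(perm[:na]) - np.median(perm[na:])) >= abs(obs) - 1e-12:
                count += 1
        p = (count + 1.0) / (n_perm + 1.0)
        n_used, exact = n_perm, False

    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.median(rng.choice(a, len(a))) - np.median(rng.choice(b, len(b)))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return EstimationResult(obs, p, float(lo), float(hi), n_used, n_boot, seed,
                            exact=exact, warning=warning)


def build_count_table(units: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate units by (region, part) x response type.

    ``units`` needs columns region, part, type_label; every unit must carry
    a label. Adds Total, responsive and nonresponsive summary columns.
    """
    required = {"region", "part", "type_label"}
    if not required.issubset(units.columns):
        raise ValueError(f"units table needs columns {sorted(required)}")
    if units["type_label"].isna().any():
        raise ValueError("unlabeled unit in the table")
    if len(units) == 0:
        cols = list(RESPONSIVE_TYPES) + ["NR", "Total", "responsive"]
        return pd.DataFrame(
            columns=cols,
            index=pd.MultiIndex.from_arrays([[], []], names=["region", "part"]),
            dtype=int,
        )
    # keep every observed label (populations may yield E3, I5, ... subtypes)
    extra = sorted(set(units["type_label"]) - set(RESPONSIVE_TYPES) - {"NR"})
    cols = list(RESPONSIVE_TYPES) + extra + ["NR"]
    table = (
        units.pivot_table(index=["region", "part"], columns="type_label",
                          aggfunc="size", fill_value=0)
        .reindex(columns=cols, fill_value=0)
    )
    table.columns.name = None
    table["Total"] = table[cols].sum(axis=1)
    table["responsive"] = table["Total"] - table["NR"]
    return table


def contingency_from_counts(counts: pd.DataFrame, region: str, comparison: str) -> np.ndarray:
    """2x2 table (rows anterior/posterior) for one within-region comparison.

    ``comparison``: 'responsive' compares responsive vs nonresponsive among
    all recorded units; 'excitatory' (E1+E2), 'inhibitory' (I1-I4), or a
    single type name compares that class vs the other responsive units.
    """
    sub = counts.loc[region]
    type_cols = [c for c in sub.columns if c not in ("NR", "Total", "responsive")]
    resp = sub[type_cols].sum(axis=1)
    if comparison == "responsive":
        yes = resp
        no = sub["NR"]
    else:
        if comparison == "excitatory":
            members = ["E1", "E2"]
        elif comparison == "inhibitory":
            members = ["I1", "I2", "I3", "I4"]
        elif comparison in RESPONSIVE_TYPES:
            members = [comparison]
        else:
            raise ValueError(f"unknown comparison {comparison!r}")
        yes = sub[members].sum(axis=1)
        no = resp - yes
    return np.array([[yes["A"], no["A"]], [yes["P"], no["P"]]], dtype=int)


#: the anterior-vs-posterior contingency comparisons reported with odds
#: ratios: responsive fraction in M2; excitatory / inhibitory / E1 fractions
#: among responsive units in M1; E1 fraction in M2
REGION_COMPARISONS = (
    ("M2", "responsive"),
    ("M1", "excitatory"),
    ("M1", "inhibitory"),
    ("M1", "E1"),
    ("M2", "E1"),
)


def region_comparisons(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fisher p and Woolf OR CI for each standard anterior-vs-posterior
    comparison, computed from a count table (defaults to the published one)."""
    if counts is None:
        counts = PUBLISHED_COUNTS
    rows = []
    for region, comparison in REGION_COMPARISONS:
        t = contingency_from_counts(counts, region, comparison)
        orr, lo, hi = odds_ratio_ci(t)
        rows.append({
            "region": region, "comparison": comparison,
            "a": t[0, 0], "b": t[0, 1], "c": t[1, 0], "d": t[1, 1],
            "fisher_p": fisher_exact_p(t),
            "odds_ratio": orr, "ci_low": lo, "ci_high": hi,
        })
    return pd.DataFrame(rows)
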