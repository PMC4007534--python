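"""Length-variability statistics, classification and group comparisons.

For every curated ortholog set, three dispersion statistics of member lengths
(total, domain or linker) are computed separately for the OIE and nonOIE
lifestyle groups:

* ``range`` — max − min after removing box-plot outliers (Tukey fences at
  Q1 − 1.5·IQR and Q3 + 1.5·IQR, quartiles by R's default type-7 rule);
* ``sd``    — sample standard deviation (n − 1 denominator, R's ``sd()``);
* ``iqr``   — interquartile range Q3 − Q1 (type 7).

Each set is then classified per metric as no_variability, variable_in_both,
nonOIE_more_variable or OIE_more_variable, and the per-set statistics are
compared between lifestyles with a Welch t-test and a Mann–Whitney test
(exact when samples are small and tie-free, otherwise the normal
approximation with continuity and tie correction — matching R's
``wilcox.test`` defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .curation import OrthologSet
from .decomposition import LengthDecomposition

METRICS = ("range", "sd", "iqr")
METRIC_TARGETS = ("total", "domain", "linker")
CATEGORIES = (
    "no_variability",
    "variable_in_both",
    "nonOIE_more_variable",
    "OIE_more_variable",
)


@dataclass(frozen=True)
class GroupDispersion:
    """Dispersion of one set's lengths within one lifestyle group."""

    group_id: str
    lifestyle: str
    metric_target: str
    n: int
    range_excl_outliers: float
    sd: float
    iqr: float

    def metric(self, name: str) -> float:
        return {
            "range": self.range_excl_outliers,
            "sd": self.sd,
            "iqr": self.iqr,
        }[name]


@dataclass(frozen=True)
class VariabilityClassification:
    group_id: str
    metric: str
    category: str


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def sample_sd(values: Sequence[float]) -> float:
    """Sample (n−1) standard deviation; 0 for a singleton."""
    arr = np.asarray(values, dtype=float)
    return float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def quartiles(values: Sequence[float]) -> tuple[float, float]:
    """(Q1, Q3) by R's default type-7 rule (numpy's linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def iqr(values: Sequence[float]) -> float:
    q1, q3 = quartiles(values)
    return q3 - q1


def tukey_range(values: Sequence[float]) -> tuple[float, list[float]]:
    """Range after excluding box-plot outliers, plus the outliers themselves.

    Outliers lie outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with type-7 quartiles.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("tukey_range of empty input")
    q1, q3 = quartiles(arr)
    spread = q3 - q1
    lo, hi = q1 - 1.5 * spread, q3 + 1.5 * spread
    inside = arr[(arr >= lo) & (arr <= hi)]
    outliers = arr[(arr < lo) | (arr > hi)]
    return float(inside.max() - inside.min()), sorted(float(x) for x in outliers)


def dispersion(
    oset: OrthologSet,
    decomp: Mapping[str, LengthDecomposition],
    target: str = "total",
) -> dict[str, GroupDispersion]:
    """Per-lifestyle dispersion of one set's lengths for the chosen target.

    Requires ≥2 members per lifestyle (dispersion of fewer is undefined).
    """
    if target not in METRIC_TARGETS:
        raise ValueError(f"target must be one of {METRIC_TARGETS}")
    attr = {"total": "total_len", "domain": "domain_len", "linker": "linker_len"}[target]
    out: dict[str, GroupDispersion] = {}
    for lifestyle in ("OIE", "nonOIE"):
        vals = [
            getattr(decomp[p.protein_id], attr)
            for m, p in oset.members
            if m.lifestyle == lifestyle
        ]
        if len(vals) < 2:
            raise ValueError(
                f"set {oset.group_id}: lifestyle {lifestyle} has {len(vals)} "
                "member(s); need ≥2"
            )
        rng, _ = tukey_range(vals)
        out[lifestyle] = GroupDispersion(
            oset.group_id, lifestyle, target, len(vals), rng, sample_sd(vals),
            iqr(vals),
        )
    return out


def classify(
    dispersions: Mapping[str, GroupDispersion], tol: float = 0.0
) -> list[VariabilityClassification]:
    """Classify one set per metric from its OIE/nonOIE dispersion pair."""
    oie, non = dispersions["OIE"], dispersions["nonOIE"]
    out = []
    for m in METRICS:
        a, b = oie.metric(m), non.metric(m)
        if abs(a - b) <= tol:
            cat = "no_variability" if a <= tol and b <= tol else "variable_in_both"
        elif a > b:
            cat = "OIE_more_variable"
        else:
            cat = "nonOIE_more_variable"
        out.append(VariabilityClassification(oie.group_id, m, cat))
    return out


def summarize_classification(
    classifications: Sequence[VariabilityClassification],
) -> list[dict]:
    """Per-metric category counts and percentages (Table-1-style rows)."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    rows = []
    for m in METRICS:
        of_metric = [c for c in classifications if c.metric == m]
        total = len(of_metric)
        for cat in CATEGORIES:
            n = sum(1 for c in of_metric if c.category == cat)
            rows.append(
                {
                    "metric": m,
                    "category": cat,
                    "count": n,
                    "percent": 100.0 * n / total if total else float("nan"),
                }
            )
    return rows


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann–Whitney p-value, R ``wilcox.test``-compatible.

    Exact when both samples have <50 observations and there are no ties;
    otherwise the normal approximation with continuity and tie correction.
    Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and a.size < 50 and b.size < 50) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def compare_groups(
    oie_values: Sequence[float], nonoie_values: Sequence[float]
) -> dict[str, float]:
    """Welch t-test + Mann–Whitney comparison of per-set dispersion statistics.

    Returns the two two-sided p-values and the group means. With degenerate
    all-equal inputs the t-test p is NaN and the Mann–Whitney p is 1.
    """
    a = np.asarray(oie_values, dtype=float)
    b = np.asarray(nonoie_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need ≥2 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        t_p = float("nan")
    else:
        t_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return {
        "oie_mean": float(a.mean()),
        "nonoie_mean": float(b.mean()),
        "t_test_p": t_p,
        "mann_whitney_p": mann_whitney(a, b),
    }


def fit_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares y ~ x with the slope's two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of n ≥ 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    if np.ptp(y) == 0:  # constant response: flat fit, R² defined as 0
        return RegressionFit(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = stats.linregress(x, y)
    return RegressionFit(
        float(res.slope), float(res.intercept), float(res.rvalue**2),
        float(res.pvalue), int(x.size),
    )


def variance_of_averages(
    per_species_average: Mapping[str, float], meta: Sequence
) -> dict[str, float]:
    """Sample variance of species-level average ortholog lengths per lifestyle.

    A lifestyle with a single species gets NaN (sample variance undefined).
    """
    out: dict[str, float] = {}
    for lifestyle in ("OIE", "nonOIE"):
        vals = [
            per_species_average[m.species_id]
            for m in meta
            if m.lifestyle == lifestyle and m.species_id in per_species_average
        ]
        out[lifestyle] = (
            float(np.var(vals, ddof=1)) if len(vals) > 1 else float("nan")
        )
    return out


def per_species_average_lengths(sets: Sequence[OrthologSet]) -> dict[str, float]:
    """Mean member length per species over curated sets only."""
    sums: dict[str, list[int]] = {}
    for s in sets:
        for m, p in s.members:
            sums.setdefault(m.species_id, []).append(p.length)
    return {sid: float(np.mean(v)) for sid, v in sums.items()}


def bubble_table(oset: OrthologSet) -> list[dict]:
    """Per lifestyle, the proportion of proteomes at each distinct length.

    Within a lifestyle the proportions over distinct lengths sum to 1.
    """
    rows = []
    for lifestyle in ("OIE", "nonOIE"):
        lengths = oset.lengths(lifestyle)
        if not lengths:
            continue
        total = len(lengths)
        for length in sorted(set(lengths)):
            rows.append(
                {
                    "group_id": oset.group_id,
                    "lifestyle": lifestyle,
                    "length": length,
                    "proportion": lengths.count(length) / total,
                }
            )
    return rows


# ---------------------------------------------------------------------------
# whole-collection drivers


def dispersion_records(
    sets: Sequence[OrthologSet],
    decomps: Mapping[str, Mapping[str, LengthDecomposition]],
    target: str = "total",
) -> list[GroupDispersion]:
    recs: list[GroupDispersion] = []
    for s in sets:
        recs.extend(dispersion(s, decomps[s.group_id], target).values())
    return recs


def classify_sets(
    sets: Sequence[OrthologSet],
    decomps: Mapping[str, Mapping[str, LengthDecomposition]],
    target: str = "total",
    tol: float = 0.0,
) -> list[VariabilityClassification]:
    out: list[VariabilityClassification] = []
    for s in sets:
        out.extend(classify(dispersion(s, decomps[s.group_id], target), tol))
    return out


def group_comparison_table(
    dispersions: Sequence[GroupDispersion],
) -> list[dict]:
    """Table-2-style rows: per metric, group means and both test p-values.

    The inputs are per-set dispersion statistics; each metric is compared
    between the OIE and nonOIE per-set values.
    """
    rows = []
    for m in METRICS:
        oie = [d.metric(m) for d in dispersions if d.lifestyle == "OIE"]
        non = [d.metric(m) for d in dispersions if d.lifestyle == "nonOIE"]
        cmp = compare_groups(oie, non)
        rows.append(
            {
                "metric": m,
                "nonOIE_average": cmp["nonoie_mean"],
                "OIE_average": cmp["oie_mean"],
                "t_test_p": cmp["t_test_p"],
                "mann_whitney_p": cmp["mann_whitney_p"],
                "n_sets": len(oie),
            }
        )
    return rows
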