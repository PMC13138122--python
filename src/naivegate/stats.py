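"""Per-donor subset proportions, age-group tests and age-trend correlations.

Group comparisons follow the nonparametric cascade used for the aging
cohort: a one-way Kruskal–Wallis test across the five age groups, Dunn's
post hoc test for every group pair (pooled ranks, ties-corrected variance,
two-sided normal p), Holm step-down correction within one subset's family
of pairwise comparisons, and a final Bonferroni multiplication by the
number of subpopulations plotted together. Age trends are reported as a
Pearson correlation with an ordinary least-squares line and its 95%
confidence band.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import EventMatrix

__all__ = [
    "TestResult",
    "TrendResult",
    "subset_proportions",
    "kruskal_wallis",
    "dunn_posthoc",
    "bonferroni_by_subpopulations",
    "age_trend",
    "mfi_median",
    "clip_for_plot",
]


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_holm: float = np.nan
    p_final: float = np.nan


@dataclass
class TestResult:
    """Kruskal–Wallis omnibus plus Dunn pairwise results for one subset."""

    subset: str
    H: float
    df: int
    p_global: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "subset": self.subset, "H": self.H, "df": self.df,
            "p_global": self.p_global, "group_a": c.group_a,
            "group_b": c.group_b, "z": c.z, "p_raw": c.p_raw,
            "p_holm": c.p_holm, "p_final": c.p_final,
        } for c in self.pairwise]
        return pd.DataFrame(rows)


@dataclass
class TrendResult:
    r: float
    p: float
    slope: float
    intercept: float
    # 95% band parameters: t·s·sqrt(1/n + (x−x̄)²/Sxx) around the fitted line
    se_resid: float
    x_mean: float
    sxx: float
    n: int
    t_crit: float

    def band(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        yhat = self.intercept + self.slope * x
        half = self.t_crit * self.se_resid * np.sqrt(
            1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )
        return yhat - half, yhat + half


def subset_proportions(
    labels_per_donor: dict[str, np.ndarray],
    donor_meta: pd.DataFrame,
    subsets: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy per-donor × subset proportion table.

    ``labels_per_donor`` maps donor_id to that donor's per-event subset
    labels over the denominator (parent) population; proportions within a
    donor sum to 1 over the label partition. Donors with an empty
    denominator produce NA rows flagged ``empty_denominator``.
    """
    meta = donor_meta.set_index("donor_id")
    all_subsets = subsets
    if all_subsets is None:
        seen: set[str] = set()
        for v in labels_per_donor.values():
            seen.update(np.unique(v).tolist())
        all_subsets = sorted(seen)
    rows = []
    for donor_id, labels in labels_per_donor.items():
        denom = len(labels)
        for s in all_subsets:
            num = int(np.sum(labels == s)) if denom else 0
            rows.append({
                "donor_id": donor_id,
                "age": float(meta.loc[donor_id, "age"]),
                "group": meta.loc[donor_id, "group"],
                "subset": s,
                "numerator": num,
                "denominator": denom,
                "proportion": num / denom if denom else np.nan,
                "flag": "" if denom else "empty_denominator",
            })
    return pd.DataFrame(rows)


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, int, float]:
    """Ties-corrected Kruskal–Wallis H with chi-square p (df = groups − 1)."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need ≥ 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, len(arrays) - 1, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), len(arrays) - 1, float(p)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> list[PairwiseComparison]:
    """Dunn's test for all group pairs on pooled ties-corrected ranks.

    z_ab = (R̄_a − R̄_b) / sqrt[(N(N+1)/12 − ΣT/(12(N−1))) (1/n_a + 1/n_b)]
    with ΣT = Σ(t³ − t) over tie groups; two-sided p from the standard
    normal. Holm correction is applied across the pairs with
    :func:`holm_correct` (done here), Bonferroni-by-subpopulations later.
    """
    names = [k for k, v in groups.items() if len(v) > 0]
    skipped = [k for k in groups if k not in names]
    arrays = {k: np.asarray(groups[k], dtype=float) for k in names}
    pooled = np.concatenate([arrays[k] for k in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [len(arrays[k]) for k in names])
    mean_ranks = {
        k: ranks[offsets[i]: offsets[i + 1]].mean() for i, k in enumerate(names)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    out = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_term * (1.0 / len(arrays[a]) + 1.0 / len(arrays[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(PairwiseComparison(a, b, float(z), float(min(p, 1.0))))
    holm_correct(out)
    for k in skipped:
        out.append(PairwiseComparison(k, "", np.nan, np.nan))
    return out


def holm_correct(pairwise: list[PairwiseComparison]) -> None:
    """Holm step-down over the family of pairwise comparisons, in place.

    Adjusted p for the i-th smallest raw p is max over j ≤ i of
    min(1, (m−j+1)·p_(j)) — monotone nondecreasing in the step-down order.
    """
    valid = [c for c in pairwise if np.isfinite(c.p_raw)]
    if not valid:
        return
    m = len(valid)
    order = np.argsort([c.p_raw for c in valid], kind="stable")
    running = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * valid[idx].p_raw)
        running = max(running, adj)
        valid[idx].p_holm = running


def bonferroni_by_subpopulations(
    results: list[TestResult], m: int | None = None
) -> list[TestResult]:
    """Final correction: p_final = min(1, p_holm · m), with m the number of
    subpopulations compared side by side (defaults to len(results))."""
    if m is None:
        m = len(results)
    if m < 1:
        raise ValueError("m must be ≥ 1")
    for res in results:
        for c in res.pairwise:
            c.p_final = float(min(1.0, c.p_holm * m))
    return results


def subset_group_test(
    table: pd.DataFrame, subset: str, scale: float = 100.0
) -> TestResult:
    """KW + Dunn for one subset of a tidy proportion table (percent scale).

    NA proportions are dropped listwise before testing.
    """
    sub = table[(table["subset"] == subset) & table["proportion"].notna()]
    groups = {
        g: (sub.loc[sub["group"] == g, "proportion"] * scale).to_numpy()
        for g in sorted(sub["group"].unique())
    }
    H, df, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups)
    return TestResult(subset=subset, H=H, df=df, p_global=p, pairwise=pairwise)


def family_group_tests(table: pd.DataFrame, scale: float = 100.0) -> list[TestResult]:
    """KW + Dunn for every subset of a tidy table, as one comparison family.

    Equivalent to :func:`subset_group_test` per subset followed by
    :func:`bonferroni_by_subpopulations` with m = number of subsets, but
    grouping the table only once (the shape used by calibration runs).
    """
    sub = table[table["proportion"].notna()]
    grouped: dict[str, dict[str, np.ndarray]] = {}
    for (subset, group), vals in sub.groupby(["subset", "group"])["proportion"]:
        grouped.setdefault(subset, {})[group] = vals.to_numpy() * scale
    results = []
    for subset in sorted(grouped):
        groups = grouped[subset]
        H, df, p = kruskal_wallis(groups)
        results.append(TestResult(subset, H, df, p, dunn_posthoc(groups)))
    return bonferroni_by_subpopulations(results)


def age_trend(proportions: np.ndarray, ages: np.ndarray) -> TrendResult:
    """Pearson correlation and OLS age trend with 95% confidence band."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(proportions, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 donors for a trend")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    se_resid = np.sqrt(np.sum(resid**2) / (n - 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    return TrendResult(
        r=float(r), p=float(p), slope=float(fit.slope),
        intercept=float(fit.intercept), se_resid=float(se_resid),
        x_mean=float(x.mean()), sxx=sxx, n=n,
        t_crit=float(sps.t.ppf(0.975, n - 2)),
    )


def mfi_median(
    events: EventMatrix, marker: str, mask: np.ndarray | None = None
) -> float:
    """Median fluorescence intensity of a marker over a population mask.

    Returns NaN for an empty population.
    """
    col = events.column(marker)
    if mask is not None:
        col = col[np.asarray(mask, dtype=bool)]
    if col.size == 0:
        return float("nan")
    return float(np.median(col))


def clip_for_plot(values: np.ndarray, upper_quantile: float = 0.99) -> np.ndarray:
    """Plot-layer clipping: negatives to zero, values above the 99th
    percentile down to it. Never used for gating decisions."""
    v = np.asarray(values, dtype=float)
    hi = np.quantile(v, upper_quantile)
    return np.clip(v, 0.0, hi)
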