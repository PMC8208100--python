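"""Group-comparison statistics and proportion reporting.

Thin, explicit wrappers over scipy/statsmodels routines: unpaired two-tailed
t tests (pooled-variance Student's by default, Welch by flag), Pearson
chi-square on contingency tables without continuity correction, one-way
ANOVA with Tukey HSD post hoc comparisons, and count-to-percentage
arithmetic.  No multiple-testing correction is applied beyond Tukey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "unpaired_t",
    "chi_square",
    "anova_tukey",
    "proportion_from_counts",
    "build_report",
]


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: float
    p_value: float
    group_means: list[float] = field(default_factory=list)
    group_sds: list[float] = field(default_factory=list)
    n_per_group: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    pairwise: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p value outside [0, 1]")


def unpaired_t(group_a, group_b, welch: bool = False) -> ComparisonResult:
    """Two-tailed unpaired t test (pooled-variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance in both groups
        t = 0.0
        p = 1.0
    df = float(res.df) if hasattr(res, "df") else a.size + b.size - 2
    return ComparisonResult(
        test="welch_t" if welch else "student_t",
        statistic=t, df=df, p_value=p,
        group_means=[float(a.mean()), float(b.mean())],
        group_sds=[float(a.std(ddof=1)), float(b.std(ddof=1))],
        n_per_group=[int(a.size), int(b.size)],
    )


def chi_square(table) -> ComparisonResult:
    """Pearson chi-square on a contingency table of counts, without
    continuity correction; warns when any expected count is below 5."""
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    warns = []
    if np.any(expected < 5):
        warns.append("expected count below 5 in at least one cell")
    return ComparisonResult(test="chi_square", statistic=float(chi2),
                            df=float(dof), p_value=float(p),
                            n_per_group=[int(r) for r in obs.sum(axis=1)],
                            warnings=warns)


def anova_tukey(groups: list) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise post hoc comparisons."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    f, p = sps.f_oneway(*gs)
    f = 0.0 if np.isnan(f) else float(f)
    p = 1.0 if np.isnan(p) else float(p)
    k = len(gs)
    n = sum(g.size for g in gs)
    rows = []
    if k >= 3:
        hsd = sps.tukey_hsd(*gs)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append({
                    "group_a": i, "group_b": j,
                    "mean_diff": float(gs[i].mean() - gs[j].mean()),
                    "p_value": float(hsd.pvalue[i, j]),
                })
    pairwise = pd.DataFrame(rows) if rows else None
    return ComparisonResult(
        test="anova_oneway", statistic=f, df=float(k - 1), p_value=p,
        group_means=[float(g.mean()) for g in gs],
        group_sds=[float(g.std(ddof=1)) for g in gs],
        n_per_group=[int(g.size) for g in gs],
        pairwise=pairwise,
    )


def proportion_from_counts(positive: int, total: int, decimals: int = 0) -> float:
    """Percentage 100 * positive / total, rounded to the requested number
    of decimals (0 -> integer percent, 1 -> one decimal)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= positive <= total:
        raise ValueError("need 0 <= positive <= total")
    return round(100.0 * positive / total, decimals)


def build_report(
    feature_records: dict[str, dict[str, float]],
    calls: dict[str, dict[str, str]] | None = None,
    cluster_labels: dict[str, int] | None = None,
    identities: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Tabular summary of a cohort: feature means +- sd, discharge-pattern
    incidence, and cluster composition with purity."""
    if not feature_records:
        raise ValueError("empty cohort; nothing to report")
    feat = pd.DataFrame.from_dict(feature_records, orient="index")
    report: dict[str, pd.DataFrame] = {
        "features": pd.DataFrame({
            "mean": feat.mean(), "sd": feat.std(ddof=1), "n": feat.count(),
        })
    }
    if calls:
        calls_df = pd.DataFrame.from_dict(calls, orient="index")
        inc = {}
        for col in calls_df.columns:
            counts = calls_df[col].value_counts()
            inc[col] = counts
        for name, counts in inc.items():
            report[f"incidence_{name}"] = pd.DataFrame({
                "count": counts,
                "percent": (100.0 * counts / counts.sum()).round(1),
            })
    if cluster_labels:
        rows = []
        ids = sorted(cluster_labels)
        labs = np.array([cluster_labels[c] for c in ids])
        for lab in np.unique(labs):
            members = [c for c in ids if cluster_labels[c] == lab]
            row = {"cluster": int(lab), "n": len(members)}
            if identities:
                ident = pd.Series([identities[c] for c in members])
                top = ident.value_counts()
                row["dominant_identity"] = top.index[0]
                row["purity_pct"] = round(100.0 * top.iloc[0] / len(members), 1)
            rows.append(row)
        report["clusters"] = pd.DataFrame(rows)
    return report
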