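"""Profile-vs-rest association battery.

Group contrasts (Student t or Mann-Whitney, auto-selected by a Shapiro-Wilk
normality gate), Spearman rank correlations (exact permutation p for small
n), 2x2 categorical tests (Pearson chi-square without continuity correction
or Fisher's exact, selected by the expected-count-5 rule), and the HOMA-IR
insulin-resistance index.

The Student t-test uses the pooled-variance form; no multiplicity
correction is applied by default, with Benjamini-Hochberg available as an
extra column.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import Cohort

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "CategoricalTestResult",
    "homa_ir",
    "compare_profile_vs_rest",
    "compare_groups",
    "spearman",
    "categorical_test",
    "run_association_battery",
    "default_contrast_spec",
]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    method: Literal["t_test", "mann_whitney"]
    statistic: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CategoricalTestResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    method: Literal["chi2", "fisher"]
    statistic: float | None
    p_value: float
    proportions: tuple[float, float]


def homa_ir(glycemia, insulinemia):
    """HOMA-IR = fasting glucose (mM) x fasting insulin (uU/mL) / 22.5."""
    g = np.asarray(glycemia, dtype=float)
    i = np.asarray(insulinemia, dtype=float)
    if np.any(g < 0) or np.any(i < 0):
        raise ValueError("glycemia and insulinemia must be non-negative")
    return g * i / 22.5


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def compare_groups(
    a,
    b,
    variable: str = "",
    method: Literal["auto", "t_test", "mann_whitney"] = "auto",
) -> GroupComparison:
    """Two-sided two-group contrast.

    ``auto`` picks the pooled t-test when both groups pass Shapiro-Wilk at
    alpha = 0.05, otherwise Mann-Whitney. The Mann-Whitney p is the exact
    enumeration when both groups have <= 20 observations and no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "auto":
        method = "t_test" if _is_normal(a) and _is_normal(b) else "mann_whitney"
    if method == "t_test":
        res = stats.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # both groups constant and equal
            stat, p = 0.0, 1.0
    else:
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        mw_method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mw_method)
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        variable=variable,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        method=method,
        statistic=stat,
        p_value=min(p, 1.0),
    )


def compare_profile_vs_rest(
    cohort: Cohort,
    labels,
    variable: str,
    profile: int = 2,
    method: Literal["auto", "t_test", "mann_whitney"] = "auto",
) -> GroupComparison:
    """Contrast one profile's subjects against everybody else on a variable
    (marker, metabolic panel member, therapy flag, or derived ``homa`` /
    ``waist_hip_ratio``)."""
    values = np.asarray(cohort.variable(variable), dtype=float)
    labels = np.asarray(labels)
    mask = labels == profile
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError(f"profile {profile} split leaves an empty group")
    return compare_groups(values[mask], values[~mask], variable=variable, method=method)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for Spearman rho: enumerate all pairings of the
    (mid)rank vectors. Feasible for n <= 10."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    threshold = abs(rho_obs) - 1e-12

    def flush(chunk_perms: list[tuple[int, ...]]) -> int:
        perm_matrix = ryc[np.array(chunk_perms)]
        rhos = perm_matrix @ rxc / denom
        return int(np.count_nonzero(np.abs(rhos) >= threshold))

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += flush(chunk)
            total += len(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
        total += len(chunk)
    return count / total


def spearman(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Spearman rank correlation with midrank ties.

    p-value: exact permutation enumeration for n <= 10, Student-t
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 10:
        p = _exact_spearman_p(_midranks(x), _midranks(y), rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return CorrelationResult(var_x=var_x, var_y=var_y, rho=rho, p_value=p, n=n)


def categorical_test(
    table, method: Literal["auto", "chi2", "fisher"] = "auto"
) -> CategoricalTestResult:
    """2x2 test of association.

    ``auto`` applies Pearson chi-square without continuity correction when
    every expected count is >= 5, otherwise Fisher's exact test (two-sided
    by the point-probability rule). Rows are the groups; the first column
    is the event, so ``proportions`` are per-group event rates.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("a table margin is all zero")
    expected = np.outer(rows, cols) / t.sum()
    if method == "auto":
        method = "chi2" if np.all(expected >= 5) else "fisher"
    if method == "chi2":
        res = stats.chi2_contingency(t, correction=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat = None
        p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    props = (float(t[0, 0] / rows[0]), float(t[1, 0] / rows[1]))
    return CategoricalTestResult(
        table=((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
        method=method,
        statistic=stat,
        p_value=p,
        proportions=props,
    )


# --------------------------------------------------------------------------
# Battery
# --------------------------------------------------------------------------


@dataclass
class ContrastSpec:
    """Declarative list of the battery's outputs."""

    profile: int = 2
    group_variables: list[str] = field(default_factory=list)
    correlation_pairs: list[tuple[str, str]] = field(default_factory=list)
    categorical_variables: list[str] = field(default_factory=list)
    #: per-variable overrides of the auto method rule
    method_overrides: dict[str, str] = field(default_factory=dict)


def default_contrast_spec(profile: int = 2) -> ContrastSpec:
    """The study's battery: metabolic panel + HOMA + waist/hip ratio +
    gamma-GT + alcohol vs the profile; the Profile-2 marker contrasts; the
    soluble-marker and marker-vs-insulin/HOMA correlations; the three
    therapy flags."""
    return ContrastSpec(
        profile=profile,
        group_variables=[
            "insulinemia", "homa", "waist_hip_ratio", "triglycerides",
            "glycemia", "systolic", "hdl", "gamma_gt", "alcohol",
            "pct_em_cd4", "pct_exhausted_cd4", "stnfri", "scd163", "tpa", "iga",
            "pct_naive_cd4", "pct_naive_cd8", "pct_hladr_cd4", "pct_hladr_cd8",
            "pct_em_cd8", "pct_cd57_cd8",
        ],
        correlation_pairs=[
            ("scd163", "stnfri"), ("tpa", "stnfri"),
            ("scd163", "crp"), ("tpa", "crp"),
            ("pct_cd57_cd4", "insulinemia"), ("stnfri", "insulinemia"),
            ("crp", "insulinemia"), ("scd163", "insulinemia"),
            ("tpa", "insulinemia"), ("iga", "insulinemia"),
            ("stnfri", "homa"), ("scd163", "homa"),
            ("tpa", "homa"), ("iga", "homa"),
        ],
        categorical_variables=["antidiabetic", "antihyperlipidemic", "antihypertensive"],
    )


def run_association_battery(
    cohort: Cohort,
    labels,
    spec: ContrastSpec | None = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Run every configured contrast/correlation/categorical test and return
    one tidy row per result.

    Columns: kind, variable, n_a, n_b, estimate (mean difference, rho, or
    event-rate difference), statistic, p_value, method. With ``bh=True`` a
    ``p_bh`` Benjamini-Hochberg column is appended; raw p-values are always
    reported uncorrected.
    """
    if spec is None:
        spec = default_contrast_spec()
    labels = np.asarray(labels)
    rows: list[dict] = []
    for var in spec.group_variables:
        method = spec.method_overrides.get(var, "auto")
        gc = compare_profile_vs_rest(cohort, labels, var, spec.profile, method)  # type: ignore[arg-type]
        rows.append(
            dict(
                kind="group", variable=var, n_a=gc.n_a, n_b=gc.n_b,
                estimate=gc.mean_a - gc.mean_b, statistic=gc.statistic,
                p_value=gc.p_value, method=gc.method,
            )
        )
    for vx, vy in spec.correlation_pairs:
        cr = spearman(cohort.variable(vx), cohort.variable(vy), vx, vy)
        rows.append(
            dict(
                kind="correlation", variable=f"{vx}~{vy}", n_a=cr.n, n_b=cr.n,
                estimate=cr.rho, statistic=cr.rho, p_value=cr.p_value,
                method="spearman",
            )
        )
    mask = labels == spec.profile
    for var in spec.categorical_variables:
        flags = np.asarray(cohort.variable(var), dtype=bool)
        table = [
            [int(flags[mask].sum()), int((~flags[mask]).sum())],
            [int(flags[~mask].sum()), int((~flags[~mask]).sum())],
        ]
        method = spec.method_overrides.get(var, "auto")
        ct = categorical_test(table, method)  # type: ignore[arg-type]
        rows.append(
            dict(
                kind="categorical", variable=var, n_a=int(mask.sum()),
                n_b=int((~mask).sum()),
                estimate=ct.proportions[0] - ct.proportions[1],
                statistic=ct.statistic, p_value=ct.p_value, method=ct.method,
            )
        )
    report = pd.DataFrame(rows)
    if bh and len(report):
        from statsmodels.stats.multitest import multipletests

        report["p_bh"] = multipletests(report["p_value"], method="fdr_bh")[1]
    return report
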