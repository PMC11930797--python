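"""Between-group, nodewise and EEG-category statistics.

Test routing is explicit and deterministic: continuous variables use
Student's t-test when both groups pass a Shapiro-Wilk normality check at
alpha = 0.05, otherwise the Mann-Whitney U test; categorical variables use
the chi-square test without continuity correction, falling back to
Fisher's exact test when any expected cell count is below 5.  Effect sizes
are classical pooled-SD Cohen's d on unadjusted values.  Covariate
adjustment fits a logistic model of outcome on the graph measure plus
arrest-to-MRI interval, hospital indicators and the comatose flag.
Multiple comparisons are controlled by Benjamini-Hochberg FDR where the
analysis plan applies it (metric comparisons, pairwise EEG contrasts);
nodewise correlations are reported uncorrected at three significance
levels.  Outcome is coded good = 1 for nodewise correlations, so positive
r means higher connectivity with good outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "GroupComparison",
    "NodewiseResult",
    "compare_groups",
    "cohens_d",
    "adjusted_group_difference",
    "fdr_adjust",
    "nodewise_outcome_correlation",
    "eeg_category_tests",
    "metric_correlations",
    "compare_metrics_between_groups",
]

NODEWISE_ALPHA_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class GroupComparison:
    variable: str
    test: str  # "t", "mann_whitney", "chi_square", "fisher_exact"
    statistic: float
    p_raw: float
    p_fdr: float | None = None
    cohen_d: float | None = None
    adjusted_p: float | None = None


@dataclass
class NodewiseResult:
    node_index: int
    r: float  # NaN when connectivity is constant across subjects
    p: float


def compare_groups(
    group_a,
    group_b,
    variable_kind: str = "continuous",
    variable: str = "",
    normality_alpha: float = 0.05,
) -> GroupComparison:
    """Two-group test with explicit routing.

    Continuous: Shapiro-Wilk on each group at ``normality_alpha`` routes to
    Student's t (both normal) or Mann-Whitney U.  Categorical: ``group_a``
    and ``group_b`` are the two rows of a 2 x k contingency table;
    chi-square without continuity correction, Fisher exact if any expected
    count < 5 (2 x 2 only).
    """
    if variable_kind == "categorical":
        table = np.asarray([group_a, group_b], dtype=float)
        if table.min() < 0 or table.shape[0] != 2:
            raise ValueError("categorical input must be a 2 x k count table")
        expected = sps.contingency.expected_freq(table)
        if (expected < 5).any() and table.shape == (2, 2):
            stat, p = sps.fisher_exact(table)
            return GroupComparison(variable, "fisher_exact", float(stat), float(p))
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return GroupComparison(variable, "chi_square", float(stat), float(p))

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    normal = all(
        sps.shapiro(g).pvalue > normality_alpha if np.ptp(g) > 0 else False
        for g in (a, b)
    )
    if normal:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return GroupComparison(variable, "t", float(stat), float(p))
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(variable, "mann_whitney", float(stat), float(p))


def cohens_d(group_a, group_b) -> float:
    """Classical Cohen's d: mean difference over pooled (n-1) SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled variance: Cohen's d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def _design_matrix(metric: np.ndarray, covariates: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({"metric": metric}, index=covariates.index)
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[col] = s.astype(float)
    return sm.add_constant(X, has_constant="add")


def adjusted_group_difference(
    metric, outcome, covariates: pd.DataFrame
) -> tuple[float, float]:
    """Covariate-adjusted logistic contrast of a graph measure.

    Fits outcome ~ metric + covariates by maximum likelihood (hospital as
    indicator contrasts) and returns the metric coefficient and its Wald
    two-sided p.  Collinear designs and perfect separation raise explicit
    diagnostic errors.
    """
    metric = np.asarray(metric, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = _design_matrix(metric, covariates)
    if y.size < X.shape[1] + 2:
        raise ValueError("too few subjects for the covariate set")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            "collinear design: the metric coincides with a covariate "
            f"(rank {rank} < {X.shape[1]} columns)"
        )
    try:
        with warnings.catch_warnings():
            # overflow in exp() during Newton steps is benign; convergence
            # failure and separation are not
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("error", sm.tools.sm_exceptions.ConvergenceWarning)
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except PerfectSeparationError as exc:
        raise ValueError("perfect separation in adjusted logistic model") from exc
    except Warning as exc:
        raise ValueError(f"adjusted logistic model unstable: {exc}") from exc
    except Exception as exc:
        raise ValueError(f"adjusted logistic model did not converge: {exc}") from exc
    return float(fit.params["metric"]), float(fit.pvalues["metric"])


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nodewise_outcome_correlation(
    nodewise_by_subject: np.ndarray, outcomes
) -> tuple[list[NodewiseResult], dict]:
    """Point-biserial correlation of each node's connectivity with outcome.

    ``nodewise_by_subject`` is subjects x nodes; ``outcomes`` is coded
    good = 1, poor = 0 (or 'good'/'poor' strings).  Nodes with constant
    connectivity across subjects are recorded as missing (NaN) and excluded
    from the significance counts, which are reported uncorrected at
    p < 0.05, 0.01 and 0.001.
    """
    M = np.asarray(nodewise_by_subject, dtype=float)
    y = np.asarray(
        [1.0 if o in (1, 1.0, "good") else 0.0 for o in np.asarray(outcomes).ravel()]
    )
    if M.ndim != 2 or M.shape[0] != y.size:
        raise ValueError("nodewise matrix must be subjects x nodes")
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    results: list[NodewiseResult] = []
    for j in range(M.shape[1]):
        col = M[:, j]
        if np.ptp(col) == 0:
            results.append(NodewiseResult(j, float("nan"), float("nan")))
            continue
        r, p = sps.pearsonr(col, y)
        results.append(NodewiseResult(j, float(r), float(p)))
    ps = np.array([res.p for res in results])
    counts = {
        alpha: int(np.nansum(ps < alpha)) for alpha in NODEWISE_ALPHA_LEVELS
    }
    return results, counts


def eeg_category_tests(metric_by_category: dict, alpha: float = 0.05) -> dict:
    """Kruskal-Wallis omnibus across EEG categories, FDR-adjusted pairwise
    Mann-Whitney follow-up only when the omnibus rejects.

    Categories with fewer than 2 observations are excluded with a warning.
    """
    usable = {}
    for cat, vals in metric_by_category.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            warnings.warn(f"EEG category {cat!r} has n < 2; excluded", stacklevel=2)
            continue
        usable[cat] = v
    if len(usable) < 2:
        raise ValueError("need at least 2 EEG categories with n >= 2")
    h, p = sps.kruskal(*usable.values())
    out = {"kruskal_h": float(h), "kruskal_p": float(p), "pairwise": []}
    if p < alpha:
        pairs = list(combinations(sorted(usable), 2))
        raw = [
            float(sps.mannwhitneyu(usable[a], usable[b], alternative="two-sided").pvalue)
            for a, b in pairs
        ]
        adj = fdr_adjust(raw)
        out["pairwise"] = [
            {"categories": pair, "p_raw": pr, "p_fdr": float(pa)}
            for pair, pr, pa in zip(pairs, raw, adj)
        ]
    return out


def metric_correlations(metric_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and two-sided p) among whole-brain measures.

    Constant columns yield NaN entries.
    """
    if len(metric_table) < 3:
        raise ValueError("need at least 3 subjects")
    cols = list(metric_table.columns)
    n = len(cols)
    r = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    for i, j in combinations(range(n), 2):
        a = metric_table[cols[i]].to_numpy(dtype=float)
        b = metric_table[cols[j]].to_numpy(dtype=float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            rij = pij = float("nan")
        else:
            rij, pij = sps.pearsonr(a, b)
        r.iloc[i, j] = r.iloc[j, i] = rij
        p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def compare_metrics_between_groups(
    metrics: pd.DataFrame, metadata: pd.DataFrame,
    metric_cols=("whole_brain_fc", "clustering_auc", "global_efficiency_auc", "modularity_auc"),
    covariate_cols=("arrest_to_mri_hours", "hospital", "comatose_during_mri"),
) -> pd.DataFrame:
    """Full between-group analysis of the four whole-brain measures.

    Returns one row per measure with test routing, raw and FDR-adjusted p,
    Cohen's d, and the covariate-adjusted logistic p (NaN when the adjusted
    fit fails, e.g. separation in a small cohort).
    """
    df = metrics.merge(metadata, on="subject_id")
    good = df[df["outcome"] == "good"]
    poor = df[df["outcome"] == "poor"]
    rows = []
    for col in metric_cols:
        comp = compare_groups(good[col], poor[col], "continuous", variable=col)
        comp.cohen_d = cohens_d(good[col], poor[col])
        try:
            _, comp.adjusted_p = adjusted_group_difference(
                df[col].to_numpy(),
                (df["outcome"] == "good").astype(float).to_numpy(),
                df[list(covariate_cols)],
            )
        except ValueError:
            comp.adjusted_p = float("nan")
        rows.append(comp)
    adj = fdr_adjust([r.p_raw for r in rows])
    for r_, a_ in zip(rows, adj):
        r_.p_fdr = float(a_)
    return pd.DataFrame([r.__dict__ for r in rows])
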