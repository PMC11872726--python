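"""Between-group statistics and the six-feature case/control classifier.

Pairwise comparisons of gene usage use two-sided Mann-Whitney U tests with
Bonferroni correction; multi-group comparisons use Kruskal-Wallis with
Dunn's post-hoc z-tests under Holm-Sidak adjustment.  Effect sizes are
Cohen's d with pooled standard deviation.  The classifier reproduces the
published protocol: six gene-usage features, a stratified 60/40
train/test split, unregularized multivariate logistic regression, and
ROC/AUC evaluation on both splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

#: The six repertoire features used to predict case status.
DEFAULT_CLASSIFIER_FEATURES = (
    "IGHV3-30",
    "IGHV3-30-3",
    "IGHV3-49",
    "IGHV1-3",
    "IGHD1-26",
    "IGHJ6",
)


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m p)``; m defaults to the vector length."""
    p = np.asarray(list(pvalues), dtype=float)
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def holm_sidak(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    return multipletests(p, method="holm-sidak")[1]


@dataclass
class TestResult:
    feature: str
    comparison: str
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment: str
    effect_size: float | None = None


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else
    normal approximation with tie and continuity correction."""
    pooled = np.concatenate([a, b])
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    result = sps.mannwhitneyu(a, b, alternative="two-sided",
                              method="exact" if exact else "asymptotic",
                              use_continuity=True)
    return float(result.statistic), float(result.pvalue)


def mannwhitney_usage(
    usage: pd.DataFrame,
    groups: pd.Series,
    comparisons: Sequence[tuple[str, str]],
    genes: Sequence[str] | None = None,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Mann-Whitney U + Bonferroni for each (gene, group-pair).

    ``m_tests`` is the Bonferroni family size; it defaults to the number of
    (gene, comparison) pairs tested in this call.  The replication preset
    for the targeted six-gene analysis passes ``m_tests=2`` (two disease
    groups against controls per gene, as in the published figure).
    """
    genes = list(usage.columns) if genes is None else list(genes)
    missing = [g for g in genes if g not in usage.columns]
    if missing:
        raise ValueError(f"genes not in usage matrix: {missing}")
    family = m_tests if m_tests is not None else len(genes) * len(comparisons)
    rows = []
    for gene in genes:
        for group_a, group_b in comparisons:
            a = usage.loc[groups[groups == group_a].index, gene].to_numpy()
            b = usage.loc[groups[groups == group_b].index, gene].to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"comparison {group_a} vs {group_b} has a group with < 2 subjects")
            statistic, p_raw = _mannwhitney(a, b)
            rows.append(
                TestResult(
                    feature=gene,
                    comparison=f"{group_a}_vs_{group_b}",
                    statistic=statistic,
                    p_raw=p_raw,
                    p_adjusted=float(bonferroni([p_raw], family)[0]),
                    adjustment=f"bonferroni(m={family})",
                    effect_size=cohens_d(a, b) if np.std(np.concatenate([a, b])) > 0 else None,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def kruskal_dunn(values_by_group: Mapping[str, Sequence[float]]) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis omnibus plus Dunn's pairwise post-hoc tests.

    Dunn's z for groups i, j uses mean pooled ranks with tie correction:
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` where
    ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups.  Pairwise p-values
    are reported raw and Holm-Sidak adjusted.
    """
    names = list(values_by_group)
    if len(names) < 3:
        raise ValueError("need >= 3 groups; use mannwhitney_usage for two groups")
    samples = [np.asarray(values_by_group[name], dtype=float) for name in names]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >= 2 observations")
    h_statistic, omnibus_p = sps.kruskal(*samples)
    omnibus = TestResult(
        feature="omnibus",
        comparison="+".join(names),
        statistic=float(h_statistic),
        p_raw=float(omnibus_p),
        p_adjusted=float(omnibus_p),
        adjustment="none",
    )

    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    mean_ranks, sizes = [], []
    offset = 0
    for sample in samples:
        mean_ranks.append(ranks[offset : offset + len(sample)].mean())
        sizes.append(len(sample))
        offset += len(sample)

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"comparison": f"{names[i]}_vs_{names[j]}", "statistic": z, "p_raw": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adjusted"] = multipletests(pairwise["p_raw"], method="holm-sidak")[1]
    pairwise["adjustment"] = "holm-sidak"
    return omnibus, pairwise


def cohens_d(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Standardized mean difference with pooled (n-1) standard deviation."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 values")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def median_usage_correlation(
    usage: pd.DataFrame, groups: pd.Series, group_a: str, group_b: str
) -> float:
    """R^2 between per-gene median usages of two groups.

    Medians are taken within each group for every shared gene and the
    squared Pearson correlation of the two median vectors is returned.
    """
    med_a = usage.loc[groups[groups == group_a].index].median()
    med_b = usage.loc[groups[groups == group_b].index].median()
    if len(med_a) < 3:
        raise ValueError("need >= 3 shared genes")
    if med_a.std(ddof=0) < 1e-12 or med_b.std(ddof=0) < 1e-12:
        raise ValueError("zero variance in a median-usage vector")
    fit = sps.linregress(med_b.to_numpy(), med_a.to_numpy())
    return float(fit.rvalue**2)


def pca_features(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of standardized features: (scores, explained variance, loadings).

    Features are centred and scaled to unit variance first; constant
    features are dropped with a warning.  Component signs follow a fixed
    convention (the largest-magnitude loading of each component is
    positive) so results are reproducible across library versions.
    """
    X = features.astype(float)
    constant = X.columns[X.std(ddof=0) == 0]
    if len(constant):
        import warnings

        warnings.warn(f"dropping constant features: {list(constant)}", stacklevel=2)
        X = X.drop(columns=constant)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 non-constant features")
    Z = (X - X.mean()) / X.std(ddof=0)
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_
    for k in range(loadings.shape[0]):
        pivot = np.argmax(np.abs(loadings[k]))
        if loadings[k, pivot] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    names = [f"PC{k + 1}" for k in range(loadings.shape[0])]
    return (
        pd.DataFrame(scores, index=X.index, columns=names),
        pca.explained_variance_ratio_,
        pd.DataFrame(loadings, index=names, columns=X.columns),
    )


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def stratified_split(
    subjects: Sequence[str],
    labels: Sequence[str],
    train_frac: float = 0.6,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[str]]:
    """Stratified train/test partition of subjects.

    Per label the train allocation is round-half-even of
    ``count * train_frac``, then repaired toward the overall target
    (round-half-even of ``N * train_frac``) by adjusting the labels whose
    allocation is furthest from exact, keeping at least one subject per
    label on each side.  Membership within a label is a seeded shuffle.
    """
    rng = np.random.default_rng() if rng is None else rng
    subjects = list(subjects)
    labels = pd.Series(list(labels), index=subjects)
    counts = labels.value_counts().sort_index()
    if (counts < 2).any():
        raise ValueError("every label needs >= 2 subjects")
    target = {lab: _round_half_even(n * train_frac) for lab, n in counts.items()}
    for lab, n in counts.items():
        target[lab] = min(max(target[lab], 1), n - 1)
    overall = _round_half_even(len(subjects) * train_frac)
    # repair: move single subjects between splits, preferring the label whose
    # allocation deviates most from the exact fraction, until totals match
    while sum(target.values()) != overall:
        direction = 1 if sum(target.values()) < overall else -1
        candidates = [
            lab
            for lab, n in counts.items()
            if 1 <= target[lab] + direction <= n - 1
        ]
        if not candidates:
            break
        deviation = {lab: (target[lab] - counts[lab] * train_frac) * direction for lab in candidates}
        lab = min(sorted(candidates), key=lambda l: deviation[l])
        target[lab] += direction
    train, test = [], []
    for lab in counts.index:
        members = sorted(labels.index[labels == lab])
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        train.extend(shuffled[: target[lab]])
        test.extend(shuffled[target[lab] :])
    if not train or not test:
        raise ValueError("degenerate split: one side is empty")
    return train, test


def fit_logistic(
    features: pd.DataFrame,
    labels: Sequence[int],
    ridge: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood logistic regression (intercept first).

    Unregularized by default; if the fit fails to converge or the data are
    perfectly separable (diverging coefficients), a small-ridge L2 fit is
    substituted and flagged.  Returns ``(coefficients, used_ridge)`` with
    the intercept in position 0.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more training subjects than features")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant feature in design matrix")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, max_iter=5000, tol=1e-10)
        model.fit(X, y)
    coef = np.concatenate([model.intercept_, model.coef_.ravel()])
    if np.abs(coef).max() > 1e4 or not np.isfinite(coef).all():
        ridge_model = LogisticRegression(penalty="l2", C=1.0 / ridge, max_iter=5000)
        ridge_model.fit(X, y)
        coef = np.concatenate([ridge_model.intercept_, ridge_model.coef_.ravel()])
        return coef, True
    return coef, False


def logistic_scores(features: pd.DataFrame, coefficients: np.ndarray) -> np.ndarray:
    """Predicted case probabilities under fitted coefficients."""
    eta = coefficients[0] + features.to_numpy(dtype=float) @ coefficients[1:]
    return 1.0 / (1.0 + np.exp(-eta))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, pd.DataFrame]:
    """AUC (ties counted 1/2) and the (FPR, TPR) curve points."""
    y = np.asarray(list(labels), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


@dataclass
class ClassifierReport:
    features: tuple[str, ...]
    case_group: str
    control_group: str
    coefficients: np.ndarray
    used_ridge: bool
    train_subjects: list[str]
    test_subjects: list[str]
    auc_train: float
    auc_test: float
    roc_train: pd.DataFrame = field(repr=False)
    roc_test: pd.DataFrame = field(repr=False)
    seed: int | None = None


def run_classifier_experiment(
    usage: pd.DataFrame,
    groups: pd.Series,
    case_group: str,
    control_group: str,
    features: Sequence[str] = DEFAULT_CLASSIFIER_FEATURES,
    train_frac: float = 0.6,
    seed: int | None = None,
) -> ClassifierReport:
    """Six-feature case/control classification experiment.

    Assembles the gene-usage features (genes absent from the matrix enter as
    zero usage), splits subjects 60/40 stratified by group, fits logistic
    regression on the training split, and reports AUC on both splits.
    Features enter the model unscaled: they are all usage proportions on a
    common scale.
    """
    rng = np.random.default_rng(seed)
    members = groups[groups.isin([case_group, control_group])]
    design = pd.DataFrame(index=members.index)
    for gene in features:
        design[gene] = usage[gene] if gene in usage.columns else 0.0
    labels = (members == case_group).astype(int)
    train_ids, test_ids = stratified_split(members.index, members.to_numpy(), train_frac, rng)
    coef, used_ridge = fit_logistic(design.loc[train_ids], labels.loc[train_ids])
    score_train = logistic_scores(design.loc[train_ids], coef)
    score_test = logistic_scores(design.loc[test_ids], coef)
    auc_train, roc_train = roc_auc(score_train, labels.loc[train_ids])
    auc_test, roc_test = roc_auc(score_test, labels.loc[test_ids])
    return ClassifierReport(
        features=tuple(features),
        case_group=case_group,
        control_group=control_group,
        coefficients=coef,
        used_ridge=used_ridge,
        train_subjects=list(train_ids),
        test_subjects=list(test_ids),
        auc_train=auc_train,
        auc_test=auc_test,
        roc_train=roc_train,
        roc_test=roc_test,
        seed=seed,
    )
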