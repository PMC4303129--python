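"""Per-CpG supervised differential-methylation testing.

Two routes mirror the analysis design: non-parametric rank tests
(Wilcoxon rank-sum for two groups, Kruskal-Wallis for more) on raw β, and
covariate-adjusted ordinary-least-squares models on logit-transformed β.
Benjamini-Hochberg controls the FDR within each comparison; significant
probes are split by direction (hyper- vs hypomethylated in the index
group), overlapped across comparisons, tested against external probe
signatures with Fisher's exact test, and correlated with gene expression
overall and within subtype strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .preprocess import logit_transform

__all__ = [
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "CovariateSpec",
    "default_covariate_spec",
    "fit_probe_model",
    "run_comparison",
    "DifferentialMethylation",
    "bh_fdr",
    "direction_summary",
    "overlap_sets",
    "signature_overlap_test",
    "methylation_expression_correlation",
]

logger = logging.getLogger(__name__)

#: Combined sample size at or below which the exact rank-sum null is enumerated.
EXACT_RANKSUM_N = 12


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact enumeration null when the combined sample size is at
    most 12 and there are no ties; otherwise the normal approximation with
    tie and continuity corrections.  Returns (U statistic of the first
    group, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == combined.size
    if combined.size <= EXACT_RANKSUM_N and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on (g-1) df.

    All-identical observations give H = 0, p = 1 (the tie-corrected
    statistic is degenerate there).
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(
        groups[0][0]
    ):
        groups = tuple(groups[0])
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    allvals = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(allvals == allvals[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class CovariateSpec:
    """Adjustment sets per comparison, with covariate typing and references.

    ``adjustments`` maps a comparison name to the covariate columns entered
    into its probe models.  ``categorical`` covariates enter as indicator
    contrasts against ``reference_levels`` (or their first sorted level);
    everything else enters numerically.
    """

    adjustments: dict[str, list[str]]
    categorical: set = field(default_factory=set)
    reference_levels: dict[str, object] = field(default_factory=dict)

    def for_comparison(self, comparison: str) -> list[str]:
        if comparison not in self.adjustments:
            raise KeyError(f"no adjustment set for comparison {comparison!r}")
        return list(self.adjustments[comparison])


def default_covariate_spec() -> CovariateSpec:
    """Standard adjustment sets: age/race/menopause/stage, with the stated
    exceptions (stage models drop stage; tumor-size and node models swap in
    each other instead of stage)."""
    standard = ["age", "race", "menopause", "stage"]
    return CovariateSpec(
        adjustments={
            "hr_status": standard,
            "subtype": standard,
            "p53": standard,
            "p53_subtype_adjusted": standard + ["subtype"],
            "cluster3_vs_rest": standard,
            "grade": standard,
            "stage": ["age", "race", "menopause"],
            "tumor_size": ["age", "race", "menopause", "node_status"],
            "node_status": ["age", "race", "menopause", "tumor_size"],
        },
        categorical={"race", "menopause", "stage", "subtype", "node_status", "tumor_size"},
    )


def _encode_design(
    annotation: pd.DataFrame,
    covariates: list[str],
    spec: CovariateSpec,
) -> pd.DataFrame:
    """Dummy-encode the adjustment covariates (complete cases assumed)."""
    cols = {}
    for cov in covariates:
        series = annotation[cov]
        if cov in spec.categorical:
            levels = sorted(series.dropna().unique(), key=str)
            ref = spec.reference_levels.get(cov, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{cov}[{lev}]"] = (series == lev).astype(float)
        else:
            cols[cov] = series.astype(float)
    return pd.DataFrame(cols, index=annotation.index)


def fit_probe_model(
    logit_beta: pd.Series,
    factor: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """OLS of logit β on a factor contrast plus adjustment covariates.

    ``factor`` must be numeric: a 0/1 indicator for two-group contrasts or
    an ordinal score (e.g. stage 1-4).  Rows with any missing value are
    dropped.  Returns (factor coefficient, two-sided t-test p).  Raises
    ``np.linalg.LinAlgError`` on a rank-deficient design so callers can
    skip and log the probe.
    """
    df = pd.DataFrame({"y": logit_beta.astype(float), "factor": factor.astype(float)})
    if covariates is not None:
        df = df.join(covariates.astype(float))
    df = df.dropna()
    X = sm.add_constant(df.drop(columns="y"), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    fit = sm.OLS(df["y"], X).fit()
    return float(fit.params["factor"]), float(fit.pvalues["factor"])


def _ols_matrix(Y: np.ndarray, X: np.ndarray, coef_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS of many responses (rows of Y) on one shared design matrix.

    Returns per-probe (coefficient, two-sided p) for column ``coef_idx``.
    Algebraically identical to probe-wise statsmodels OLS; used for speed.
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv.T  # probes x p
    resid = Y - B @ X.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(sigma2 * xtx_inv[coef_idx, coef_idx])
    coef = B[:, coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    return coef, pvals


def run_comparison(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    comparison: str,
    factor_col: str,
    *,
    spec: CovariateSpec | None = None,
    contrast: tuple | None = None,
    ordinal: bool = False,
    eps: float = 1e-3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted differential methylation for every probe.

    Parameters
    ----------
    beta : DataFrame, probes x tumors
    contrast : (reference_level, index_level) or None
        Two-group contrast on ``factor_col``; tumors at other levels are
        excluded.  ``ordinal=True`` instead scores the factor numerically
        (the across-stages trend analysis).
    Returns a frame with estimate (logit-scale coefficient of the index
    level), raw_p, q (BH within this comparison) and direction
    (hyper/hypo in the index group).
    """
    if spec is None:
        spec = default_covariate_spec()
    covs = spec.for_comparison(comparison)
    if factor_col in covs:
        raise ValueError(f"comparison {comparison!r} adjusts for its own factor")
    ann = annotation.loc[annotation.index.intersection(beta.columns)]

    factor = ann[factor_col]
    if ordinal:
        fvals = pd.to_numeric(factor, errors="coerce")
    else:
        if contrast is None:
            levels = sorted(factor.dropna().unique(), key=str)
            if len(levels) != 2:
                raise ValueError("contrast required for factors with != 2 levels")
            contrast = (levels[0], levels[1])
        ref, alt = contrast
        fvals = pd.Series(np.nan, index=ann.index)
        fvals[factor == ref] = 0.0
        fvals[factor == alt] = 1.0
    design = _encode_design(ann, covs, spec)
    keep = fvals.notna() & design.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: %d tumors dropped (missing factor/covariates)", comparison, n_dropped)
    tumors = ann.index[keep]
    X = np.column_stack(
        [np.ones(len(tumors)), fvals[tumors].to_numpy(), design.loc[tumors].to_numpy()]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(f"rank-deficient design for comparison {comparison!r}")
    Y = logit_transform(beta.loc[:, tumors], eps=eps).to_numpy()
    coef, raw_p = _ols_matrix(Y, X, coef_idx=1)
    q = bh_fdr(raw_p)
    out = pd.DataFrame(
        {
            "comparison": comparison,
            "estimate": coef,
            "raw_p": raw_p,
            "q": q,
            "direction": np.where(coef > 0, "hyper", "hypo"),
        },
        index=beta.index,
    )
    out.attrs["n_used"] = len(tumors)
    out.attrs["n_dropped"] = n_dropped
    out.attrs["alpha"] = alpha
    return out


class DifferentialMethylation(BaseEstimator):
    """Estimator wrapper around :func:`run_comparison`.

    ``fit(beta, annotation)`` runs the configured comparison over all
    probes; results land in ``results_`` and the FDR-significant probe set
    in ``significant_``.
    """

    def __init__(
        self,
        comparison: str = "hr_status",
        factor_col: str | None = None,
        contrast: tuple | None = None,
        ordinal: bool = False,
        eps: float = 1e-3,
        alpha: float = 0.05,
    ):
        self.comparison = comparison
        self.factor_col = factor_col
        self.contrast = contrast
        self.ordinal = ordinal
        self.eps = eps
        self.alpha = alpha

    def fit(self, beta: pd.DataFrame, annotation: pd.DataFrame):
        self.results_ = run_comparison(
            beta,
            annotation,
            self.comparison,
            self.factor_col or self.comparison,
            contrast=self.contrast,
            ordinal=self.ordinal,
            eps=self.eps,
            alpha=self.alpha,
        )
        self.significant_ = set(self.results_.index[self.results_["q"] < self.alpha])
        return self


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def direction_summary(results: pd.DataFrame, alpha: float = 0.05) -> tuple[int, int]:
    """(n_hyper, n_hypo) among probes significant at q < alpha."""
    sig = results[results["q"] < alpha]
    return int((sig["direction"] == "hyper").sum()), int((sig["direction"] == "hypo").sum())


def overlap_sets(named_sets: dict[str, set]) -> dict[frozenset, int]:
    """Exclusive Venn-region counts for 2+ named sets.

    Keys are frozensets of the names whose sets contain the region's
    elements (and no others); values sum to the union size.
    """
    names = list(named_sets)
    universe = set().union(*named_sets.values())
    regions: dict[frozenset, int] = {}
    for el in universe:
        key = frozenset(n for n in names if el in named_sets[n])
        regions[key] = regions.get(key, 0) + 1
    return regions


def signature_overlap_test(sig_probes, external_signature, background) -> float:
    """One-sided (enrichment) Fisher exact p for signature overlap.

    All three are probe-ID collections with sig and external subsets of the
    background universe.
    """
    background = set(background)
    a = set(sig_probes)
    b = set(external_signature)
    if not a <= background or not b <= background:
        raise ValueError("signatures must be subsets of the background")
    overlap = len(a & b)
    table = [
        [overlap, len(a - b)],
        [len(b - a), len(background - a - b)],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def methylation_expression_correlation(
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    probe_gene: pd.Series,
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation between probe β and its gene's expression.

    Computed over all samples and within each stratum (e.g. intrinsic
    subtype); strata with fewer than 3 paired observations are skipped.
    Returns rows (probe_id, gene, stratum, n, r, p).
    """
    shared = beta.columns.intersection(expression.columns)
    rows = []
    strata_values = [("all", shared)]
    if strata is not None:
        for level in pd.unique(strata.dropna()):
            members = strata.index[strata == level].intersection(shared)
            strata_values.append((level, members))
    for probe, gene in probe_gene.items():
        if probe not in beta.index or gene not in expression.index:
            continue
        for level, members in strata_values:
            b = beta.loc[probe, members].astype(float)
            e = expression.loc[gene, members].astype(float)
            ok = b.notna() & e.notna()
            if ok.sum() < 3:
                continue
            r, p = stats.pearsonr(b[ok], e[ok])
            rows.append(
                {
                    "probe_id": probe,
                    "gene": gene,
                    "stratum": level,
                    "n": int(ok.sum()),
                    "r": float(r),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)
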