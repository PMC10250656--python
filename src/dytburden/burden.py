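"""Gene-level rare-variant association: SKAT, burden, and SKAT-O.

The null model is a logistic regression of case status on age, sex, and five
principal components.  For a gene cell with genotype matrix ``G`` (samples x
variants), per-variant score statistics are ``S_j = sum_i G_ij (y_i - mu_i)``
and the family of test statistics is

    Q(rho) = (1 - rho) * sum_j (w_j S_j)^2  +  rho * (sum_j w_j S_j)^2,

which interpolates between the variance-component kernel statistic (SKAT,
rho = 0) and the squared weighted burden score (rho = 1).  Each Q(rho) is a
quadratic form in the projected, variance-weighted genotypes under the null,
so its p-value follows from the eigenvalues of the corresponding kernel.
SKAT-O takes the minimum p-value over a grid of rho and evaluates the null
distribution of that minimum by one-dimensional numerical integration over
the shared burden component (Lee-style optimal test).  A label-permutation
evaluation is available as an independent oracle.

Default variant weights are Beta(1, 25) density evaluated at the cohort
alternate-allele frequency — the convention that upweights the rarest
variants.  Missing dosages are mean-imputed per variant within the analyzed
sample set; carrier counts use the raw (non-imputed) dosages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .classify import MAF_THRESHOLDS, SUBGROUP_CLASSES, classify, subgroup_membership
from .exceptions import ConvergenceError, NoTestError, ValidationError
from .io import CohortData, Status, Subgroup
from .panel import GenePanel

logger = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "BurdenResult",
    "BurdenConfig",
    "DEFAULT_RHO_GRID",
    "fit_null",
    "impute_mean",
    "score_statistic",
    "pvalue_quadform",
    "skat_o",
    "skat_o_permutation",
    "run_burden_scan",
    "run_burden_scans",
    "significance_flags",
    "beta_maf_weights",
]

from .quadform import liu_params, pvalue_quadform  # re-exported as module surface

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass
class NullModel:
    """Fitted logistic null model and the pieces score tests need."""

    X: np.ndarray  # n x (p+1) design including intercept
    y: np.ndarray  # n, 0/1
    mu: np.ndarray  # fitted probabilities
    params: np.ndarray

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.mu

    @property
    def variance(self) -> np.ndarray:
        return self.mu * (1.0 - self.mu)


def fit_null(y, X=None, *, tol: float = 1e-8, maxiter: int = 25) -> NullModel:
    """Fit the logistic null model by iteratively reweighted least squares.

    ``X`` holds the covariate columns (no intercept; one is added).  Raises
    :class:`ConvergenceError` on non-convergence or separation, and
    :class:`ValidationError` when ``y`` has a single class or covariates are
    missing.
    """
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("y must be a 0/1 case indicator")
    if len(np.unique(y)) < 2:
        raise ValidationError("y must contain both cases and controls")
    if X is None:
        X = np.empty((y.size, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any():
        raise ValidationError(
            "covariate matrix contains missing values; drop those samples first"
        )
    design = sm.add_constant(X, has_constant="add")
    try:
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=tol
        )
    except PerfectSeparationError:
        raise ConvergenceError(
            "logistic null model separated; review covariates"
        ) from None
    mu = np.asarray(res.fittedvalues, dtype=float)
    eps = 1e-8
    if (mu < eps).any() or (mu > 1 - eps).any():
        raise ConvergenceError(
            "fitted probabilities at the 0/1 boundary indicate separation; "
            "review covariates"
        )
    if not res.converged:
        raise ConvergenceError("logistic null model did not converge")
    if abs(float((y - mu).sum())) > 1e-6:
        raise ConvergenceError("score equation not satisfied at the optimum")
    return NullModel(X=design, y=y, mu=mu, params=np.asarray(res.params, dtype=float))


def impute_mean(G: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean of observed dosages."""
    G = np.array(G, dtype=float)
    for j in range(G.shape[1]):
        col = G[:, j]
        nan = np.isnan(col)
        if nan.any():
            fill = col[~nan].mean() if (~nan).any() else 0.0
            col[nan] = fill
    return G


def beta_maf_weights(af: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a, b) density weights at the observed allele frequencies."""
    af = np.clip(np.asarray(af, dtype=float), 0.0, 1.0)
    return beta_dist.pdf(af, a, b)


def score_statistic(G, null: NullModel, weights, rho: float) -> float:
    """Q(rho) for one gene cell; missing dosages must be imputed already."""
    if not (0.0 <= rho <= 1.0):
        raise ValidationError(f"rho must lie in [0, 1], got {rho}")
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise NoTestError("no variants in cell")
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != G.shape[1] or (w <= 0).any():
        raise ValidationError("weights must be positive, one per variant")
    S = G.T @ null.residuals
    U = w * S
    return float((1.0 - rho) * np.sum(U**2) + rho * np.sum(U) ** 2)


def _projected_weighted_genotypes(G: np.ndarray, null: NullModel, w: np.ndarray):
    """Z1 = V^{1/2} (I - H) G W with Cov(weighted scores) = Z1' Z1."""
    v = null.variance
    X = null.X
    XtVX = X.T @ (X * v[:, None])
    # lstsq tolerates rank-deficient designs (e.g. constant covariates)
    coef = np.linalg.lstsq(XtVX, X.T @ (G * v[:, None]), rcond=None)[0]
    G_tilde = G - X @ coef
    return np.sqrt(v)[:, None] * G_tilde * w[None, :]


def _rho_eigenvalues(sigma: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of R_rho^{1/2} Sigma R_rho^{1/2}, R_rho = (1-rho)I + rho J."""
    m = sigma.shape[0]
    a = math.sqrt(1.0 - rho)
    total = 1.0 - rho + m * rho
    b = (math.sqrt(total) - a) / m
    ones = np.ones((m, m))
    r_half = a * np.eye(m) + b * ones
    mat = r_half @ sigma @ r_half
    lam = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    return lam


@dataclass
class SkatOResult:
    p_value: float
    rho_opt: float
    p_per_rho: dict[float, float]
    q_per_rho: dict[float, float]


def _single_variant_p(U: float, var: float) -> float:
    if var <= 0:
        raise NoTestError("zero score variance for single-variant cell")
    return float(chi2.sf(U**2 / var, df=1))


def skat_o(
    G,
    null: NullModel,
    weights=None,
    rho_grid=DEFAULT_RHO_GRID,
    *,
    outer_method: str = "auto",
) -> SkatOResult:
    """Optimal-rho kernel association test for one gene cell.

    Returns the combined p-value and the grid point attaining the minimum
    per-rho p-value.  ``outer_method`` selects the tail evaluator inside the
    min-p integral: ``'imhof'`` (accurate), ``'liu'`` (fast moment matching),
    or ``'auto'`` (Imhof when the minimum per-rho p-value is small enough to
    matter, below 0.2; Liu otherwise).
    """
    G = impute_mean(np.asarray(G, dtype=float))
    n, m = G.shape
    if m == 0:
        raise NoTestError("no variants in cell")
    rho_grid = tuple(float(r) for r in rho_grid)
    if not rho_grid or any(not 0 <= r <= 1 for r in rho_grid):
        raise ValidationError("rho grid must be non-empty within [0, 1]")
    w = (
        np.ones(m)
        if weights is None
        else np.asarray(weights, dtype=float).ravel()
    )
    S = G.T @ null.residuals
    U = w * S
    Z1 = _projected_weighted_genotypes(G, null, w)
    sigma = Z1.T @ Z1

    if m == 1:
        p = _single_variant_p(float(U[0]), float(sigma[0, 0]))
        q = float(U[0] ** 2)
        return SkatOResult(
            p_value=p,
            rho_opt=rho_grid[0],
            p_per_rho={r: p for r in rho_grid},
            q_per_rho={r: q for r in rho_grid},
        )

    q_per_rho: dict[float, float] = {}
    p_per_rho: dict[float, float] = {}
    for rho in rho_grid:
        q = float((1.0 - rho) * np.sum(U**2) + rho * np.sum(U) ** 2)
        lam = _rho_eigenvalues(sigma, rho)
        q_per_rho[rho] = q
        p_per_rho[rho] = pvalue_quadform(q, lam)
    t_min = min(p_per_rho.values())
    rho_opt = min(rho_grid, key=lambda r: (p_per_rho[r], r))
    if len(rho_grid) == 1:
        return SkatOResult(p_value=t_min, rho_opt=rho_opt, p_per_rho=p_per_rho, q_per_rho=q_per_rho)

    p_value = _minp_null_pvalue(Z1, rho_grid, t_min, outer_method)
    # the combined p can never undercut the per-rho minimum, nor exceed its
    # Bonferroni bound over the grid
    p_value = min(max(p_value, t_min), t_min * len(rho_grid), 1.0)
    return SkatOResult(
        p_value=float(p_value), rho_opt=rho_opt, p_per_rho=p_per_rho, q_per_rho=q_per_rho
    )


def _minp_null_pvalue(Z1: np.ndarray, rho_grid, t_min: float, outer_method: str) -> float:
    """P(min_rho p_rho <= t_min) under the null, via the shared-component
    decomposition of the Q(rho) family."""
    n, m = Z1.shape
    z_mean = Z1.mean(axis=1)
    zbar2 = float(z_mean @ z_mean)
    if zbar2 <= 0:
        return min(1.0, t_min * len(rho_grid))
    cof1 = (z_mean @ Z1) / zbar2  # m-vector
    z_item1 = np.outer(z_mean, cof1)  # burden-direction component
    z_item2 = Z1 - z_item1  # orthogonal remainder
    mat2 = z_item2.T @ z_item2
    lam = np.linalg.eigvalsh((mat2 + mat2.T) / 2.0)
    lam = lam[lam > max(1e-12, lam.max() * 1e-10)] if lam.size else lam
    if lam.size == 0:
        return min(1.0, t_min * len(rho_grid))
    mu_q = float(lam.sum())
    var_remain = 4.0 * float(np.sum((z_item1.T @ z_item1) * mat2))
    var_q = 2.0 * float((lam**2).sum()) + var_remain
    sd_ratio = math.sqrt(2.0 * float((lam**2).sum())) / math.sqrt(var_q)

    rall = np.minimum(np.asarray(rho_grid, dtype=float), 0.999)
    tau = zbar2 * (m**2 * rall + (1.0 - rall) * float(cof1 @ cof1))

    # per-rho quantiles of Q(rho) at upper-tail level t_min
    sigma = Z1.T @ Z1
    q_min = np.empty(rall.size)
    for i, rho in enumerate(rho_grid):
        lam_r = _rho_eigenvalues(sigma, min(rho, 0.999))
        lam_r = lam_r[lam_r > max(1e-12, lam_r.max() * 1e-10)]
        q_min[i] = liu_params(lam_r).isf(min(max(t_min, 1e-300), 1.0 - 1e-12))

    use_imhof = outer_method == "imhof" or (outer_method == "auto" and t_min < 0.2)

    # integrate over the chi^2_1 burden component; substitution x = t^2 makes
    # the integrand smooth at the origin
    nodes, weights_gl = np.polynomial.legendre.leggauss(80)
    t_hi = math.sqrt(40.0)
    t = 0.5 * t_hi * (nodes + 1.0)
    wq = 0.5 * t_hi * weights_gl
    x = t**2
    kappa_q = (q_min[None, :] - tau[None, :] * x[:, None]) / (1.0 - rall[None, :])
    kappa_min = kappa_q.min(axis=1)
    adj = (kappa_min - mu_q) * sd_ratio + mu_q

    tails = np.empty_like(adj)
    if use_imhof:
        for k, qv in enumerate(adj):
            if qv > mu_q * 1e4:
                tails[k] = 0.0
            elif qv <= 0:
                tails[k] = 1.0
            else:
                tails[k] = pvalue_quadform(qv, lam)
    else:
        lp = liu_params(lam)
        for k, qv in enumerate(adj):
            tails[k] = 1.0 if qv <= 0 else (0.0 if qv > mu_q * 1e4 else lp.sf(qv))
    density = 2.0 * np.exp(-x / 2.0) / math.sqrt(2.0 * math.pi)
    prob_all_below = float(np.sum((1.0 - tails) * density * wq))
    return 1.0 - prob_all_below


def skat_o_permutation(
    G,
    null: NullModel,
    weights=None,
    rho_grid=DEFAULT_RHO_GRID,
    *,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation evaluation of the SKAT-O min-p statistic.

    Case/control labels are permuted (exchangeable under an intercept-only
    null); per-rho p-values are ranked empirically across permutations and
    the final p-value is the rank of the observed minimum.  Serves as the
    independent oracle for :func:`skat_o` on small cohorts.
    """
    rng = rng if rng is not None else np.random.default_rng()
    G = impute_mean(np.asarray(G, dtype=float))
    n, m = G.shape
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float).ravel()
    rhos = np.asarray(rho_grid, dtype=float)

    Gw = G * w[None, :]
    resid_obs = null.residuals
    resid_perm = np.empty((n, n_perm))
    y = null.y
    for b in range(n_perm):
        resid_perm[:, b] = y[rng.permutation(n)] - null.mu
    M_obs = Gw.T @ resid_obs  # m
    M_perm = Gw.T @ resid_perm  # m x B

    def q_all(M):  # M: m x B
        return (1.0 - rhos[:, None]) * np.sum(M**2, axis=0)[None, :] + rhos[
            :, None
        ] * (np.sum(M, axis=0) ** 2)[None, :]

    Q_perm = q_all(M_perm)  # R x B
    Q_obs = q_all(M_obs[:, None])[:, 0]  # R

    # empirical per-rho upper-tail p for observed and each permutation
    T_obs = np.inf
    T_perm = np.full(n_perm, np.inf)
    for r in range(rhos.size):
        row = Q_perm[r]
        order = np.argsort(row, kind="mergesort")
        # p(perm b) = (# perms with Q >= Q_b) / B  computed via ranks
        ranks = np.empty(n_perm)
        ranks[order] = np.arange(n_perm)
        p_perm = (n_perm - ranks) / n_perm
        T_perm = np.minimum(T_perm, p_perm)
        p_obs = float(np.count_nonzero(row >= Q_obs[r])) / n_perm
        T_obs = min(T_obs, p_obs)
    return float((1 + np.count_nonzero(T_perm <= T_obs)) / (n_perm + 1))


# ---------------------------------------------------------------------------
# cohort-level scan
# ---------------------------------------------------------------------------


@dataclass
class BurdenConfig:
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    weights: str = "beta"  # "beta" (Beta(1,25) at cohort AF) or "flat"
    beta_a: float = 1.0
    beta_b: float = 25.0
    classes: tuple[str, ...] = SUBGROUP_CLASSES
    maf_thresholds: tuple[float, ...] = MAF_THRESHOLDS
    cohort_label: str | None = None
    outer_method: str = "auto"


@dataclass
class BurdenResult:
    gene: str
    cohort: str
    patient_subgroup: str
    variant_subgroup: str
    maf_threshold: float
    n_variants: int
    case_carriers: int
    control_carriers: int
    statistic: float | None = None
    rho_opt: float | None = None
    p_value: float | None = None
    tested: bool = False
    suggestive: bool = False
    significant: bool = False

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value must lie in (0, 1], got {self.p_value}")


_COHORT_LABELS = {Subgroup.SEOPD: "Cohort 1", Subgroup.SLOPD: "Cohort 2"}


def _covariate_matrix(cohort: CohortData) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """(y, X, kept sample indices); samples missing age or sex are dropped."""
    kept, rows, ys = [], [], []
    dropped = 0
    for i, s in enumerate(cohort.samples):
        if s.age is None or s.sex is None:
            dropped += 1
            continue
        sex01 = 1.0 if s.sex == "male" else 0.0
        rows.append([s.age, sex01, *s.pcs])
        ys.append(1.0 if s.status is Status.CASE else 0.0)
        kept.append(i)
    if dropped:
        logger.info("dropped %d sample(s) with missing age/sex from burden scan", dropped)
    return np.asarray(ys), np.asarray(rows, dtype=float), kept


def run_burden_scan(
    cohort: CohortData, panel: GenePanel, config: BurdenConfig | None = None
) -> list[BurdenResult]:
    """SKAT-O over every panel gene and variant-subgroup cell.

    The cohort must contain exactly one case subgroup with its matched
    control group.  Rarity for cell membership is judged on the annotation's
    population (gnomAD-EAS effective) frequency; the cohort-internal allele
    frequency enters only through the variant weights.
    """
    cfg = config or BurdenConfig()
    case_subs = {s.subgroup for s in cohort.samples if s.status is Status.CASE}
    if len(case_subs) != 1:
        raise ValidationError(
            f"burden scan expects exactly one case subgroup, found {sorted(x.value for x in case_subs)}"
        )
    sub = case_subs.pop()
    if not cohort.control_indices().size:
        raise ValidationError("burden scan requires a control group")
    label = cfg.cohort_label or _COHORT_LABELS.get(sub, "cohort")

    y, X, kept = _covariate_matrix(cohort)
    try:
        null = fit_null(y, X)
    except ConvergenceError:
        # tiny or degenerate cohorts can quasi-separate on covariates; an
        # unadjusted score test is still valid, so fall back with a warning
        logger.warning(
            "covariate null model separated; falling back to an intercept-only "
            "(unadjusted) null model"
        )
        null = fit_null(y, None)
    D = cohort.dosages[kept, :]
    case_rows = np.array([k for k, i in enumerate(kept) if cohort.samples[i].status is Status.CASE])
    ctrl_rows = np.array([k for k, i in enumerate(kept) if cohort.samples[i].status is Status.CONTROL])

    cells: dict[tuple[str, str, float], list[int]] = {}
    for j in cohort.annotated_variant_indices():
        ann = cohort.annotations[cohort.variants[j].id]
        vc = classify(ann)
        for cls, thr in subgroup_membership(vc):
            if cls in cfg.classes and thr in cfg.maf_thresholds:
                cells.setdefault((ann.gene, cls, thr), []).append(j)

    results: list[BurdenResult] = []
    for gene in panel.symbols:
        for cls in cfg.classes:
            for thr in cfg.maf_thresholds:
                cols = cells.get((gene, cls, thr), [])
                base = dict(
                    gene=gene,
                    cohort=label,
                    patient_subgroup=sub.value,
                    variant_subgroup=cls,
                    maf_threshold=thr,
                    n_variants=len(cols),
                )
                if not cols:
                    results.append(
                        BurdenResult(**base, case_carriers=0, control_carriers=0)
                    )
                    continue
                raw = D[:, cols]
                carrier = np.nan_to_num(raw, nan=0.0) >= 1.0
                any_carrier = carrier.any(axis=1)
                base["case_carriers"] = int(any_carrier[case_rows].sum())
                base["control_carriers"] = int(any_carrier[ctrl_rows].sum())
                G = impute_mean(raw)
                if cfg.weights == "beta":
                    af = G.mean(axis=0) / 2.0
                    w = beta_maf_weights(af, cfg.beta_a, cfg.beta_b)
                else:
                    w = np.ones(len(cols))
                try:
                    res = skat_o(
                        G, null, w, cfg.rho_grid, outer_method=cfg.outer_method
                    )
                except NoTestError:
                    results.append(BurdenResult(**base))
                    continue
                results.append(
                    BurdenResult(
                        **base,
                        statistic=res.q_per_rho[res.rho_opt],
                        rho_opt=res.rho_opt,
                        p_value=res.p_value,
                        tested=True,
                    )
                )
    return significance_flags(results, n_genes=len(panel))


_MATCHED_CONTROLS = {Subgroup.SEOPD: Subgroup.CONTROL1, Subgroup.SLOPD: Subgroup.CONTROL2}


def run_burden_scans(
    cohort: CohortData, panel: GenePanel, config: BurdenConfig | None = None
) -> list[BurdenResult]:
    """Scan every sporadic case subgroup against its matched control group.

    Early-onset cases pair with control group 1 and late-onset cases with
    control group 2 (falling back to all controls when the matched group is
    absent); familial probands do not enter the burden analysis.  Each pair
    is passed to :func:`run_burden_scan` and the results concatenated.
    """
    subs = {s.subgroup for s in cohort.samples if s.status is Status.CASE}
    results: list[BurdenResult] = []
    for sub in (Subgroup.SEOPD, Subgroup.SLOPD):
        if sub not in subs:
            continue
        matched = _MATCHED_CONTROLS[sub]
        ctrl_subs = {s.subgroup for s in cohort.samples if s.status is Status.CONTROL}
        use_ctrl = {matched} if matched in ctrl_subs else ctrl_subs
        idx = [
            i
            for i, s in enumerate(cohort.samples)
            if s.subgroup == sub or s.subgroup in use_ctrl
        ]
        if not idx:
            continue
        results.extend(run_burden_scan(cohort.subset_samples(idx), panel, config))
    return results


def significance_flags(results: list[BurdenResult], n_genes: int) -> list[BurdenResult]:
    """Bonferroni over genes: significant iff p < 0.05/n_genes (strict);
    suggestive iff p < 0.05 and not significant."""
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    threshold = 0.05 / n_genes
    for r in results:
        if r.p_value is None:
            r.suggestive = r.significant = False
            continue
        r.significant = r.p_value < threshold
        r.suggestive = (r.p_value < 0.05) and not r.significant
    return results
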