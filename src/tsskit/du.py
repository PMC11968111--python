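"""Differential TSS usage testing.

The primary test is a binomial generalized linear mixed model: for one TSS
cluster at a time, the cluster count x is Binomial(y, theta) given the gene
total y, with

    logit(theta_j) = beta0 + z_j' beta + phi_j,      phi_j ~ N(0, sigma^2)

where z_j codes the biological condition (and optional covariates) of sample
j and phi_j is a per-sample random intercept absorbing donor-level
heterogeneity.  Significance of the condition effect is assessed by a
likelihood-ratio test of the full model against the null without the
condition coefficients (chi-square, K-1 df).

The model can be fit at the single-cell level (one binomial observation per
cell) or at the pseudo-bulk level (per-sample aggregated counts).  Because
binomial observations sharing theta_j aggregate exactly — the product of the
cell-level pmfs equals the pseudo-bulk pmf times a data-only combinatorial
constant — the two fits have identical parameter estimates and LRT p-values;
only the reported log-likelihood differs by that constant.

The random-effect integral is handled by a Laplace approximation (the same
strategy lme4's glmer uses by default); the marginal likelihood is maximized
by L-BFGS-B over (beta, log sigma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

_BETA_BOUND = 30.0
_LOG_SIGMA_BOUNDS = (-6.0, 3.0)
_REL_TOL = 1e-10
_MAX_ITER = 200


@dataclass
class DuDesign:
    """Condition labels (1..K) and optional covariates per sample."""

    condition_of_sample: Mapping[str, int]
    covariates: Mapping[str, Sequence[float]] | None = None
    baseline: int = 1

    @property
    def n_conditions(self) -> int:
        return len(set(self.condition_of_sample.values()))

    def condition_matrix(self, samples: Sequence[str]) -> np.ndarray:
        """K-1 dummy columns (baseline condition = all zeros)."""
        levels = sorted(set(self.condition_of_sample.values()))
        if self.baseline not in levels:
            raise ValueError(f"baseline condition {self.baseline} not present")
        non_base = [k for k in levels if k != self.baseline]
        Z = np.zeros((len(samples), len(non_base)))
        for i, s in enumerate(samples):
            k = self.condition_of_sample[s]
            if k != self.baseline:
                Z[i, non_base.index(k)] = 1.0
        return Z

    def covariate_matrix(self, samples: Sequence[str]) -> np.ndarray:
        if not self.covariates:
            return np.zeros((len(samples), 0))
        return np.array([np.atleast_1d(self.covariates[s]) for s in samples], float)


@dataclass
class DuTestResult:
    """Fitted coefficients and LRT p-value for one TSS cluster."""

    cluster_id: str | None
    gene_id: str | None
    beta0: float
    beta: np.ndarray
    sigma2: float
    loglik_full: float
    loglik_null: float
    lrt_stat: float
    df: int
    p_value: float
    p_adjusted: float | None = None
    converged: bool = True
    level: str = "bulk"


# ---------------------------------------------------------------------------
# Laplace-approximated binomial GLMM on per-sample sufficient statistics
# ---------------------------------------------------------------------------


def _softplus(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def _mode_phi(eta0: np.ndarray, x: np.ndarray, y: np.ndarray,
              sigma2: float) -> np.ndarray:
    """Per-sample mode of the random-effect posterior (damped Newton).

    The objective x*eta - y*softplus(eta) - phi^2/(2 sigma^2) is strictly
    concave in phi, so Newton from 0 with step halving always converges.
    """
    phi = np.zeros_like(eta0)
    obj = x * (eta0 + phi) - y * _softplus(eta0 + phi) - phi**2 / (2 * sigma2)
    for _ in range(100):
        eta = eta0 + phi
        mu = expit(eta)
        grad = x - y * mu - phi / sigma2
        hess = -(y * mu * (1 - mu) + 1.0 / sigma2)
        step = -grad / hess
        new_phi = phi + step
        new_obj = (x * (eta0 + new_phi) - y * _softplus(eta0 + new_phi)
                   - new_phi**2 / (2 * sigma2))
        # damp any sample that overshot
        bad = new_obj < obj - 1e-12
        halvings = 0
        while bad.any() and halvings < 40:
            step = np.where(bad, step / 2, step)
            new_phi = phi + step
            new_obj = (x * (eta0 + new_phi) - y * _softplus(eta0 + new_phi)
                       - new_phi**2 / (2 * sigma2))
            bad = new_obj < obj - 1e-12
            halvings += 1
        phi, obj = new_phi, new_obj
        if np.max(np.abs(grad)) < 1e-9 * (1 + np.max(y)):
            break
    return phi


def _laplace_loglik(beta: np.ndarray, log_sigma: float | None,
                    x: np.ndarray, y: np.ndarray, Z1: np.ndarray,
                    fixed_sigma2: float | None = None) -> float:
    """Marginal log-likelihood (without binomial coefficients)."""
    eta0 = Z1 @ beta
    if fixed_sigma2 is not None and fixed_sigma2 == 0.0:
        return float(np.sum(x * eta0 - y * _softplus(eta0)))
    sigma2 = np.exp(2 * log_sigma) if fixed_sigma2 is None else fixed_sigma2
    phi = _mode_phi(eta0, x, y, sigma2)
    eta = eta0 + phi
    mu = expit(eta)
    ll = np.sum(x * eta - y * _softplus(eta)) - np.sum(phi**2) / (2 * sigma2)
    ll -= 0.5 * np.sum(np.log1p(sigma2 * y * mu * (1 - mu)))
    return float(ll)


def _fit_glmm(x: np.ndarray, y: np.ndarray, Z: np.ndarray,
              fixed_sigma2: float | None = None,
              start: np.ndarray | None = None):
    """Fit the GLMM on per-sample totals; Z excludes the intercept.

    Returns (beta_with_intercept, sigma2, loglik, converged).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = y > 0
    x, y = x[keep], y[keep]
    Z1 = np.column_stack([np.ones(len(x)), np.asarray(Z, float)[keep]])
    p = Z1.shape[1]

    if start is None:
        b0 = np.log((x.sum() + 0.5) / (y.sum() - x.sum() + 0.5))
        start_beta = np.r_[b0, np.zeros(p - 1)]
        start_s = np.log(0.5)
    else:
        start_beta, start_s = start[:p], start[p] if len(start) > p else np.log(0.5)

    if fixed_sigma2 is not None:
        def nll(params):
            return -_laplace_loglik(params, None, x, y, Z1,
                                    fixed_sigma2=fixed_sigma2)
        theta0 = start_beta
        bounds = [(-_BETA_BOUND, _BETA_BOUND)] * p
    else:
        def nll(params):
            return -_laplace_loglik(params[:p], params[p], x, y, Z1)
        theta0 = np.r_[start_beta, start_s]
        bounds = [(-_BETA_BOUND, _BETA_BOUND)] * p + [_LOG_SIGMA_BOUNDS]

    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": _MAX_ITER, "ftol": _REL_TOL},
    )
    beta = res.x[:p]
    sigma2 = (np.exp(2 * res.x[p]) if fixed_sigma2 is None else fixed_sigma2)
    return beta, float(sigma2), float(-res.fun), bool(res.success)


def _binom_coef_sum(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = y > 0
    x, y = x[keep], y[keep]
    return float(np.sum(gammaln(y + 1) - gammaln(x + 1) - gammaln(y - x + 1)))


def _lrt_result(x, y, Z_full, Z_null, df, const, level,
                cluster_id=None, gene_id=None,
                fixed_sigma2=None) -> DuTestResult:
    beta_f, sig_f, ll_f, ok_f = _fit_glmm(x, y, Z_full, fixed_sigma2)
    # warm-start the null at the full fit's intercept/covariates and sigma
    p_null = Z_null.shape[1] + 1
    start_null = np.r_[beta_f[0], np.zeros(p_null - 1), 0.5 * np.log(max(sig_f, 1e-8))]
    beta_n, sig_n, ll_n, ok_n = _fit_glmm(x, y, Z_null, fixed_sigma2, start=start_null)
    if ll_n > ll_f:  # null is nested: refit full starting from the null optimum
        start_full = np.r_[beta_n, np.zeros(Z_full.shape[1] - Z_null.shape[1]),
                           0.5 * np.log(max(sig_n, 1e-8))]
        beta_f2, sig_f2, ll_f2, ok_f2 = _fit_glmm(x, y, Z_full, fixed_sigma2,
                                                  start=start_full)
        if ll_f2 > ll_f:
            beta_f, sig_f, ll_f, ok_f = beta_f2, sig_f2, ll_f2, ok_f2
    lrt = max(0.0, 2.0 * (ll_f - ll_n))
    converged = ok_f and ok_n
    p = float(stats.chi2.sf(lrt, df)) if converged else float("nan")
    return DuTestResult(
        cluster_id=cluster_id, gene_id=gene_id,
        beta0=float(beta_f[0]), beta=beta_f[1:1 + df], sigma2=sig_f,
        loglik_full=ll_f + const, loglik_null=ll_n + const,
        lrt_stat=lrt, df=df, p_value=p, converged=converged, level=level,
    )


def fit_du_bulk(
    x: Sequence[float], y: Sequence[float], samples: Sequence[str],
    design: DuDesign, cluster_id: str | None = None,
    gene_id: str | None = None, fixed_sigma2: float | None = None,
) -> DuTestResult:
    """Pseudo-bulk GLMM: one aggregated binomial observation per sample.

    ``x`` and ``y`` are the per-sample cluster and gene totals aligned with
    ``samples``.  Samples with y = 0 are dropped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x > y):
        raise ValueError("cluster counts exceed gene totals")
    _check_conditions(samples, y, design)
    Z_cond = design.condition_matrix(samples)
    Z_cov = design.covariate_matrix(samples)
    Z_full = np.column_stack([Z_cond, Z_cov])
    df = Z_cond.shape[1]
    const = _binom_coef_sum(x, y)
    return _lrt_result(x, y, Z_full, Z_cov, df, const, "bulk",
                       cluster_id, gene_id, fixed_sigma2)


def fit_du_cell(
    x_cells: Sequence[float], y_cells: Sequence[float],
    cell_sample: Sequence[str], design: DuDesign,
    cluster_id: str | None = None, gene_id: str | None = None,
    fixed_sigma2: float | None = None,
) -> DuTestResult:
    """Single-cell-level GLMM: one binomial observation per cell.

    Cells with y = 0 carry no likelihood information and are dropped.
    Within a sample all cells share theta_j, so the likelihood depends on the
    data only through per-sample totals; estimation runs on those sufficient
    statistics while the reported log-likelihood includes the per-cell
    binomial coefficients.
    """
    x_cells = np.asarray(x_cells, float)
    y_cells = np.asarray(y_cells, float)
    if np.any(x_cells > y_cells):
        raise ValueError("cluster counts exceed gene totals")
    cell_sample = np.asarray(cell_sample)
    keep = y_cells > 0
    x_cells, y_cells, cell_sample = x_cells[keep], y_cells[keep], cell_sample[keep]
    samples = sorted(set(cell_sample.tolist()))
    x = np.array([x_cells[cell_sample == s].sum() for s in samples])
    y = np.array([y_cells[cell_sample == s].sum() for s in samples])
    _check_conditions(samples, y, design)
    Z_cond = design.condition_matrix(samples)
    Z_cov = design.covariate_matrix(samples)
    Z_full = np.column_stack([Z_cond, Z_cov])
    df = Z_cond.shape[1]
    const = _binom_coef_sum(x_cells, y_cells)
    res = _lrt_result(x, y, Z_full, Z_cov, df, const, "cell",
                      cluster_id, gene_id, fixed_sigma2)
    return res


def _check_conditions(samples, y, design):
    present = {design.condition_of_sample[s]
               for s, yy in zip(samples, np.atleast_1d(y)) if yy > 0}
    if len(present) < 2:
        raise ValueError("need data in at least 2 conditions for DU testing")


# ---------------------------------------------------------------------------
# Gene filters
# ---------------------------------------------------------------------------


def filter_genes(
    matrices, design: DuDesign | None = None,
    min_detection_fraction: float = 0.1,
    require_multicluster: bool = True,
) -> set[str]:
    """Genes kept for DU testing.

    A gene is kept iff, in *every* sample, the fraction of cells (pooling
    the compared groups) with a positive gene total is >= the threshold
    (>= semantics, so a gene at exactly 10% is kept), and — when
    ``require_multicluster`` — it has at least two TSS clusters.
    """
    from .quantification import gene_totals

    kept: set[str] | None = None
    n_clusters_of_gene: dict[str, int] = {}
    for m in matrices:
        genes, totals = gene_totals(m)
        det = np.asarray((totals > 0).sum(axis=1)).ravel() / totals.shape[1]
        sample_kept = {g for g, d in zip(genes, det)
                       if d >= min_detection_fraction}
        kept = sample_kept if kept is None else kept & sample_kept
        counts: dict[str, int] = {}
        for g in m.gene_of_cluster.values():
            if g is not None:
                counts[g] = counts.get(g, 0) + 1
        for g, n in counts.items():
            n_clusters_of_gene[g] = max(n_clusters_of_gene.get(g, 0), n)
    if kept is None:
        return set()
    if require_multicluster:
        kept = {g for g in kept if n_clusters_of_gene.get(g, 0) >= 2}
    return kept


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-aware).

    Missing values are excluded from the number of tests m and returned as
    NaN; adjusted values are monotone and capped at 1.
    """
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    from statsmodels.stats.multitest import multipletests

    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Comparator tests
# ---------------------------------------------------------------------------


def wilcoxon_du(
    x_cells: Sequence[float], y_cells: Sequence[float],
    cell_sample: Sequence[str], design: DuDesign, level: str = "bulk",
) -> float:
    """Two-sided Wilcoxon rank-sum test on TSS cluster usage.

    ``level='cell'`` compares per-cell usages x/y (cells with y = 0
    dropped) between the two conditions; ``level='bulk'`` compares per-sample
    aggregated usages.  Returns NaN if a group has no usable values.
    """
    if level not in ("cell", "bulk"):
        raise ValueError("level must be 'cell' or 'bulk'")
    levels = sorted(set(design.condition_of_sample.values()))
    if len(levels) != 2:
        raise ValueError("wilcoxon_du supports exactly 2 conditions")
    x_cells = np.asarray(x_cells, float)
    y_cells = np.asarray(y_cells, float)
    cell_sample = np.asarray(cell_sample)
    groups: list[np.ndarray] = []
    for k in levels:
        members = {s for s, kk in design.condition_of_sample.items() if kk == k}
        in_grp = np.isin(cell_sample, list(members))
        if level == "cell":
            xs, ys = x_cells[in_grp], y_cells[in_grp]
            ok = ys > 0
            groups.append(xs[ok] / ys[ok])
        else:
            vals = []
            for s in sorted(members):
                sel = cell_sample == s
                ytot = y_cells[sel].sum()
                if ytot > 0:
                    vals.append(x_cells[sel].sum() / ytot)
            groups.append(np.array(vals))
    if any(len(g) == 0 for g in groups):
        return float("nan")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(groups[0], groups[1],
                                    alternative="two-sided").pvalue)


def ideas_modified_du(
    usages_by_sample: Mapping[str, Sequence[float]],
    design: DuDesign, n_perm: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Distance-permutation comparator on per-sample usage distributions.

    The statistic is the mean Wasserstein-1 distance between the empirical
    usage CDFs of samples in different conditions minus the mean distance
    between samples in the same condition; the p-value is a permutation tail
    probability over random reassignments of sample condition labels,
    p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    rng = rng or np.random.default_rng()
    samples = [s for s, u in usages_by_sample.items() if len(u) > 0]
    if len(samples) < 4:
        logger.warning("ideas_modified_du: too few samples for permutation")
        return float("nan")
    labels = np.array([design.condition_of_sample[s] for s in samples])
    if len(set(labels.tolist())) < 2:
        return float("nan")
    n = len(samples)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = stats.wasserstein_distance(
                np.asarray(usages_by_sample[samples[i]], float),
                np.asarray(usages_by_sample[samples[j]], float),
            )
            dmat[i, j] = dmat[j, i] = d

    def statistic(lab):
        same = lab[:, None] == lab[None, :]
        iu = np.triu_indices(n, 1)
        within = dmat[iu][same[iu]]
        between = dmat[iu][~same[iu]]
        if len(within) == 0 or len(between) == 0:
            return np.nan
        return between.mean() - within.mean()

    observed = statistic(labels)
    if np.isnan(observed):
        return float("nan")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        s = statistic(perm)
        if not np.isnan(s) and s >= observed - 1e-15:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def results_to_frame(results: Sequence[DuTestResult]):
    """Tabulate DU results (one row per cluster) with BH adjustment."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "cluster": [r.cluster_id for r in results],
            "gene": [r.gene_id for r in results],
            "beta0": [r.beta0 for r in results],
            "beta": [r.beta[0] if len(r.beta) else np.nan for r in results],
            "sigma2": [r.sigma2 for r in results],
            "lrt": [r.lrt_stat for r in results],
            "p": [r.p_value for r in results],
            "converged": [r.converged for r in results],
            "level": [r.level for r in results],
        }
    )
    df["p_bh"] = bh_adjust(df["p"].to_numpy())
    return df
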