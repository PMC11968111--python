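"""Synthetic TSS-cluster count data with known usage structure, and the
type-I-error / power benchmark for differential-usage tests.

Design (two conditions, J samples each, I cells per sample, two TSS clusters
per gene):

* gene totals y are independent negative-binomial counts per cell, with
  per-gene mean/dispersion drawn from log-normal hyperpriors (optionally
  moment-fit to a user matrix); a fraction of genes gets condition-specific
  means to emulate confounding differential gene expression;
* the expected usage mu_jk of cluster 1 in sample j, condition k is a
  baseline plus a sample-level offset tau_jk from a uniform/outlier mixture
  (outlier probability pi, deviation bounds c1 < c2), clipped to [0, 1]:
    - null genes share one baseline a ~ U(0.1, 0.9) across conditions, with
      tau ~ (1-pi) U(-0.1,0.1) + pi/2 U(c1,c2) + pi/2 U(-c2,-c1);
    - alternative genes have a1 ~ U(0.1, 0.4) and a2 = a1 + d with
      d ~ U(0.1, 0.5), and a one-sided outlier component
      tau ~ (1-pi) U(-0.1,0.1) + pi U(c1,c2) in both conditions (a
      symmetric variant is available behind ``symmetric_alt_outliers``);
* per-cell usage gamma ~ Beta(alpha_jk, 5) with alpha_jk chosen so
  E[gamma] = mu_jk (alpha = 5 mu / (1-mu); mu in {0,1} degenerates to a
  point mass), and the cluster-1 count is Binomial(y, gamma); cluster 2 is
  the complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .du import (
    DuDesign,
    bh_adjust,
    fit_du_bulk,
    fit_du_cell,
    ideas_modified_du,
    wilcoxon_du,
)

METHODS = ("glmm_bulk", "glmm_cell", "wilcoxon_bulk", "wilcoxon_cell", "ideas")


@dataclass
class SimScenario:
    """All knobs for one benchmark cell."""

    J: int = 10                # samples per condition
    I: int = 100               # cells per sample
    n_null: int = 500
    n_alt: int = 500
    pi: float = 0.1            # outlier probability
    c1: float = 0.1            # outlier deviation bounds
    c2: float = 0.2
    beta_shape: float = 5.0    # second Beta shape parameter
    d_range: tuple[float, float] = (0.1, 0.5)
    symmetric_alt_outliers: bool = False
    fraction_de: float = 0.2   # genes with condition-specific expression
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pi <= 1:
            raise ValueError("pi must be in [0, 1]")
        if not 0 < self.c1 < self.c2:
            raise ValueError("require 0 < c1 < c2")
        if min(self.J, self.I, self.n_null, self.n_alt) < 1:
            raise ValueError("J, I, n_null, n_alt must all be >= 1")


@dataclass
class NbParams:
    """Per-gene negative-binomial parameters, possibly condition-specific.

    ``mean`` has shape (n_genes, K); ``dispersion`` (the NB size r, with
    variance m + m^2/r) has shape (n_genes,).
    """

    mean: np.ndarray
    dispersion: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersion must be > 0")
        self.mean = np.atleast_2d(np.asarray(self.mean, float).T).T


def default_nb_params(
    n_genes: int, rng: np.random.Generator,
    fraction_de: float = 0.2, n_conditions: int = 2,
    mean_log_mu: float = 0.0, mean_log_sd: float = 1.0,
    disp_log_mu: float = 0.0, disp_log_sd: float = 0.5,
) -> NbParams:
    """Log-normal hyperpriors emulating a detection-filtered 10x gene pool.

    Base means ~ LogNormal(0, 1) truncated below at 0.2 UMI/cell (so expected
    detection stays above the 1%-of-cells pre-filter), dispersions
    ~ LogNormal(0, 0.5).  A ``fraction_de`` subset of genes receives a
    condition-2 fold change 2**N(0, 1) to emulate confounding differential
    expression.
    """
    base = np.exp(rng.normal(mean_log_mu, mean_log_sd, n_genes))
    base = np.clip(base, 0.2, 50.0)
    disp = np.exp(rng.normal(disp_log_mu, disp_log_sd, n_genes))
    mean = np.tile(base[:, None], (1, n_conditions)).astype(float)
    is_de = rng.random(n_genes) < fraction_de
    lfc = rng.normal(0.0, 1.0, n_genes)
    for k in range(1, n_conditions):
        mean[is_de, k] = base[is_de] * 2.0 ** lfc[is_de]
    return NbParams(mean, disp)


def nb_params_from_matrix(counts: np.ndarray) -> NbParams:
    """Method-of-moments NB fit to a genes x cells count matrix."""
    counts = np.asarray(counts, float)
    m = counts.mean(axis=1)
    v = counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = m**2 / (v - m)
    r = np.where((v > m) & np.isfinite(r), r, 1e6)  # ~Poisson when var <= mean
    m = np.maximum(m, 1e-6)
    return NbParams(m[:, None], r)


def simulate_gene_counts(
    n_genes: int, J: int, I: int, condition: int,
    nb_params: NbParams, rng: np.random.Generator,
) -> np.ndarray:
    """Independent NB gene counts, shape (n_genes, J*I), for one condition."""
    m = nb_params.mean[:, min(condition - 1, nb_params.mean.shape[1] - 1)]
    r = nb_params.dispersion
    p = r / (r + m)
    return rng.negative_binomial(r[:, None], p[:, None], size=(n_genes, J * I))


def _draw_tau_null(shape, pi, c1, c2, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(3, size=shape, p=[1 - pi, pi / 2, pi / 2])
    tau = rng.uniform(-0.1, 0.1, size=shape)
    out_pos = rng.uniform(c1, c2, size=shape)
    out_neg = rng.uniform(-c2, -c1, size=shape)
    return np.where(comp == 0, tau, np.where(comp == 1, out_pos, out_neg))


def _draw_tau_alt(shape, pi, c1, c2, rng: np.random.Generator,
                  symmetric: bool = False) -> np.ndarray:
    if symmetric:
        return _draw_tau_null(shape, pi, c1, c2, rng)
    comp = rng.choice(2, size=shape, p=[1 - pi, pi])
    tau = rng.uniform(-0.1, 0.1, size=shape)
    out = rng.uniform(c1, c2, size=shape)
    return np.where(comp == 0, tau, out)


def _clip_usage(a: np.ndarray, tau: np.ndarray) -> np.ndarray:
    return np.clip(a + tau, 0.0, 1.0)


def draw_null_usage(scenario: SimScenario, rng: np.random.Generator,
                    n_genes: int | None = None) -> dict:
    """Baselines, sample offsets and expected usages for null genes.

    Returns ``a`` (n,), ``tau`` and ``mu`` (n, J, 2): the baseline is shared
    by both conditions and mu = clip(a + tau).
    """
    n = n_genes if n_genes is not None else scenario.n_null
    a = rng.uniform(0.1, 0.9, n)
    tau = _draw_tau_null((n, scenario.J, 2), scenario.pi,
                         scenario.c1, scenario.c2, rng)
    mu = _clip_usage(a[:, None, None], tau)
    return {"a": a, "tau": tau, "mu": mu}


def draw_alt_usage(scenario: SimScenario, rng: np.random.Generator,
                   n_genes: int | None = None) -> dict:
    """Baselines a1, a2 = a1 + d and expected usages for alternative genes."""
    n = n_genes if n_genes is not None else scenario.n_alt
    a1 = rng.uniform(0.1, 0.4, n)
    d = rng.uniform(*scenario.d_range, n)
    a = np.stack([a1, a1 + d], axis=1)  # (n, 2)
    tau = _draw_tau_alt((n, scenario.J, 2), scenario.pi,
                        scenario.c1, scenario.c2, rng,
                        scenario.symmetric_alt_outliers)
    mu = _clip_usage(a[:, None, :], tau)
    return {"a1": a1, "d": d, "tau": tau, "mu": mu}


def simulate_tss_counts(
    gene_counts: np.ndarray, mu: np.ndarray, beta_shape: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cluster-1 counts per cell: gamma ~ Beta(alpha, beta_shape), x ~ Bin(y, gamma).

    ``gene_counts`` is (n_genes, n_cells) for one sample/condition; ``mu``
    is (n_genes,) expected usage.  alpha = beta_shape * mu / (1 - mu) gives
    E[gamma] = mu; mu in {0, 1} degenerates to the point mass at mu.
    Cluster 2 is ``gene_counts - result``.
    """
    mu = np.asarray(mu, float)
    n_genes, n_cells = gene_counts.shape
    gamma = np.empty((n_genes, n_cells))
    interior = (mu > 0) & (mu < 1)
    if interior.any():
        alpha = beta_shape * mu[interior] / (1 - mu[interior])
        gamma[interior] = rng.beta(
            alpha[:, None], beta_shape, size=(int(interior.sum()), n_cells)
        )
    gamma[~interior] = mu[~interior, None]
    return rng.binomial(gene_counts, gamma)


@dataclass
class SimData:
    """One simulated dataset: cluster-1 counts x, gene totals y, design, truth."""

    x: np.ndarray                 # (n_genes, n_cells)
    y: np.ndarray                 # (n_genes, n_cells)
    cell_sample: np.ndarray       # (n_cells,) sample ids
    design: DuDesign
    truth: pd.DataFrame           # gene, hypothesis, baseline(s), d
    scenario: SimScenario

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.cell_sample.tolist()))

    def bulk_totals(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        samples = self.samples
        S = np.stack([(self.cell_sample == s) for s in samples]).astype(float)
        return self.x @ S.T, self.y @ S.T, samples


def simulate_dataset(scenario: SimScenario,
                     nb_params: NbParams | None = None) -> SimData:
    """Generate a full benchmark dataset for one scenario (deterministic in seed)."""
    rng = np.random.default_rng(scenario.seed)
    n_genes = scenario.n_null + scenario.n_alt
    if nb_params is None:
        nb_params = default_nb_params(n_genes, rng, scenario.fraction_de)

    null = draw_null_usage(scenario, rng)
    alt = draw_alt_usage(scenario, rng)
    mu = np.concatenate([null["mu"], alt["mu"]], axis=0)  # (n_genes, J, 2)

    xs, ys, cell_sample = [], [], []
    for k in (1, 2):
        y_k = simulate_gene_counts(n_genes, scenario.J, scenario.I, k,
                                   nb_params, rng)
        for j in range(scenario.J):
            sl = slice(j * scenario.I, (j + 1) * scenario.I)
            y_sj = y_k[:, sl]
            x_sj = simulate_tss_counts(y_sj, mu[:, j, k - 1],
                                       scenario.beta_shape, rng)
            xs.append(x_sj)
            ys.append(y_sj)
            cell_sample.extend([f"c{k}_s{j + 1}"] * scenario.I)

    truth = pd.DataFrame({
        "gene": [f"gene_{i}" for i in range(n_genes)],
        "hypothesis": ["null"] * scenario.n_null + ["alt"] * scenario.n_alt,
        "baseline": np.concatenate([null["a"], alt["a1"]]),
        "d": np.concatenate([np.zeros(scenario.n_null), alt["d"]]),
    })
    design = DuDesign({
        f"c{k}_s{j + 1}": k for k in (1, 2) for j in range(scenario.J)
    })
    return SimData(
        x=np.concatenate(xs, axis=1), y=np.concatenate(ys, axis=1),
        cell_sample=np.array(cell_sample), design=design,
        truth=truth, scenario=scenario,
    )


# ---------------------------------------------------------------------------
# Benchmark evaluation
# ---------------------------------------------------------------------------


def _pvalues_glmm_bulk(data: SimData) -> np.ndarray:
    xb, yb, samples = data.bulk_totals()
    out = np.full(data.x.shape[0], np.nan)
    for g in range(data.x.shape[0]):
        try:
            out[g] = fit_du_bulk(xb[g], yb[g], samples, data.design).p_value
        except ValueError:
            pass
    return out


def _pvalues_glmm_cell(data: SimData) -> np.ndarray:
    out = np.full(data.x.shape[0], np.nan)
    for g in range(data.x.shape[0]):
        try:
            out[g] = fit_du_cell(data.x[g], data.y[g], data.cell_sample,
                                 data.design).p_value
        except ValueError:
            pass
    return out


def _pvalues_wilcoxon(data: SimData, level: str) -> np.ndarray:
    out = np.full(data.x.shape[0], np.nan)
    for g in range(data.x.shape[0]):
        out[g] = wilcoxon_du(data.x[g], data.y[g], data.cell_sample,
                             data.design, level=level)
    return out


def _pvalues_ideas(data: SimData, n_perm: int = 2000,
                   seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    samples = data.samples
    sel = {s: data.cell_sample == s for s in samples}
    out = np.full(data.x.shape[0], np.nan)
    for g in range(data.x.shape[0]):
        usages = {}
        for s in samples:
            ys = data.y[g][sel[s]]
            xs = data.x[g][sel[s]]
            ok = ys > 0
            usages[s] = xs[ok] / ys[ok]
        out[g] = ideas_modified_du(usages, data.design, n_perm=n_perm, rng=rng)
    return out


def method_pvalues(data: SimData, method: str, n_perm: int = 2000) -> np.ndarray:
    if method == "glmm_bulk":
        return _pvalues_glmm_bulk(data)
    if method == "glmm_cell":
        return _pvalues_glmm_cell(data)
    if method == "wilcoxon_bulk":
        return _pvalues_wilcoxon(data, "bulk")
    if method == "wilcoxon_cell":
        return _pvalues_wilcoxon(data, "cell")
    if method == "ideas":
        return _pvalues_ideas(data, n_perm=n_perm, seed=data.scenario.seed + 1)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def evaluate_du_methods(
    scenarios: Sequence[SimScenario],
    methods: Sequence[str] = ("glmm_bulk",),
    alpha: float = 0.05,
    n_perm: int = 2000,
    pvalue_fn: Callable[[SimData, str], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Type-I error and power per scenario x method.

    Each method is applied to the first cluster of every gene (cluster 2 is
    the complement), p-values are BH-adjusted across all genes jointly, and
    type-I error (power) is the fraction of null (alternative) genes with
    adjusted p < alpha.  Method failures count as non-rejections and are
    tallied in ``n_failed``.
    """
    rows = []
    for scenario in scenarios:
        data = simulate_dataset(scenario)
        is_null = (data.truth["hypothesis"] == "null").to_numpy()
        for method in methods:
            if pvalue_fn is not None:
                p = pvalue_fn(data, method)
            else:
                p = method_pvalues(data, method, n_perm=n_perm)
            adj = bh_adjust(p)
            reject = np.nan_to_num(adj, nan=1.0) < alpha
            rows.append({
                "J": scenario.J, "I": scenario.I, "pi": scenario.pi,
                "c1": scenario.c1, "c2": scenario.c2,
                "seed": scenario.seed, "method": method,
                "type1_error": float(reject[is_null].mean()) if is_null.any() else np.nan,
                "power": float(reject[~is_null].mean()) if (~is_null).any() else np.nan,
                "n_failed": int(np.isnan(p).sum()),
            })
    return pd.DataFrame(rows)
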