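"""ICM inference of DE/EE states, initializers, logFC and call filtering.

Per gene, iterated conditional modes alternates three steps until the state
vector stops changing (or an iteration cap is hit):

1. refit the Poisson-Gamma parameters (alpha, beta) at the current states;
2. refit the MRF parameters (gamma, beta_mrf) from the current states by
   pseudolikelihood;
3. one ICM sweep: visit cell types in ascending order and set each state to
   the value maximizing  log f(y_k | x_k; theta) + log p(x_k | rest; phi).

Final DE calls additionally require |logFC| above a threshold, and in
real-data mode a minimum-expression filter (mean CPM above a percentile of
the pooled gene x cell-type means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from . import mrf, poisson_gamma as pg
from .data_model import (CALL_COLUMNS, CellTypeNetwork, InputValidationError,
                         PseudobulkDataset, StateMatrix)


@dataclass
class ICMConfig:
    """Knobs for ICM inference and DE calling.

    ``logfc_threshold`` is on the log2 scale (benchmarks use tau/2);
    ``expression_percentile`` enables the real-data minimum-expression
    filter when set (e.g. 40.0) and is disabled when None.
    ``fix_phi`` freezes the MRF parameters instead of refitting per gene
    (setting it to MRFParams(0, 0) decouples the cell types entirely).
    """

    max_outer_iters: int = 20
    phi_bounds: tuple = mrf.PHI_BOUNDS
    theta_bounds: tuple = pg.THETA_BOUNDS
    logfc_pseudocount: float = 1.0
    logfc_threshold: float = 1.0
    expression_percentile: float | None = None
    init_p_threshold: float = 0.05
    fix_phi: mrf.MRFParams | None = None

    def __post_init__(self):
        if self.max_outer_iters < 1:
            raise ValueError("max_outer_iters must be >= 1")
        if self.logfc_threshold < 0 or self.logfc_pseudocount <= 0:
            raise ValueError("logFC threshold must be >= 0 and pseudocount > 0")


@dataclass
class ICMResult:
    states: StateMatrix
    theta_alpha: np.ndarray
    theta_beta: np.ndarray
    phi_gamma: np.ndarray
    phi_beta: np.ndarray
    n_iters: np.ndarray
    converged: np.ndarray
    degenerate: np.ndarray


def _state_log_densities(pb_gene: np.ndarray, m: int, n: int, theta: pg.PGParams):
    """(ll0, ll1) per cell type: log density under EE (pooled) and DE (split)."""
    K = pb_gene.shape[0]
    ll0 = np.array([pg.log_group_marginal(pb_gene[k], theta) for k in range(K)])
    ll1 = np.array([pg.log_group_marginal(pb_gene[k, :m], theta)
                    + pg.log_group_marginal(pb_gene[k, m:], theta) for k in range(K)])
    return ll0, ll1


def gene_objective(pb_gene, x, m, n, theta: pg.PGParams, phi: mrf.MRFParams, net) -> float:
    """ICM objective: Poisson-Gamma log likelihood plus MRF log joint energy."""
    return (pg.gene_log_likelihood(pb_gene, x, m, n, theta)
            + float(mrf.mrf_log_joint_unnormalized(np.asarray(x), phi, net)))


def icm_sweep(pb_gene, x, theta: pg.PGParams, phi: mrf.MRFParams, net, m: int, n: int,
              record_objective: bool = False):
    """One full ICM sweep at fixed (theta, phi); ties broken toward EE.

    Returns the updated state vector, or ``(x, trajectory)`` of the
    objective after each coordinate update when ``record_objective`` is set.
    """
    A = mrf._as_adj(net)
    x = np.asarray(x, dtype=np.int8).copy()
    pb_gene = np.atleast_2d(np.asarray(pb_gene))
    ll0, ll1 = _state_log_densities(pb_gene, m, n, theta)
    traj = []
    for k in range(len(x)):
        F = phi.gamma + phi.beta * float((2.0 * x - 1.0) @ A[:, k])
        # log-odds of x_k = 1 vs 0 under likelihood x conditional prior
        x[k] = 1 if (ll1[k] - ll0[k]) + F > 0 else 0
        if record_objective:
            traj.append(gene_objective(pb_gene, x, m, n, theta, phi, A))
    return (x, traj) if record_objective else x


def run_icm(pb: PseudobulkDataset, net: CellTypeNetwork, init: StateMatrix,
            cfg: ICMConfig | None = None) -> ICMResult:
    """Run per-gene ICM over a pseudobulk dataset.

    Genes with all-zero pseudobulk are degenerate: they are forced all-EE
    with sentinel parameters and skipped by inference.  Deterministic given
    its inputs; genes are independent.
    """
    cfg = cfg or ICMConfig()
    if init.states.shape != (pb.n_genes, pb.n_cell_types):
        raise InputValidationError(
            f"init states shape {init.states.shape} != {(pb.n_genes, pb.n_cell_types)}")
    if list(init.cell_type_labels) != list(pb.cell_type_labels):
        raise InputValidationError("init cell-type order does not match pseudobulk")
    if set(net.nodes) != set(pb.cell_type_labels):
        raise InputValidationError("network nodes do not match pseudobulk cell types")
    A = net.adjacency(order=pb.cell_type_labels)
    m, n = pb.m, pb.n
    G, K = pb.n_genes, pb.n_cell_types

    states = np.zeros((G, K), dtype=np.int8)
    alpha = np.ones(G)
    beta = np.ones(G)
    gamma = np.zeros(G)
    beta_m = np.zeros(G)
    iters = np.zeros(G, dtype=int)
    converged = np.zeros(G, dtype=bool)
    degenerate = np.zeros(G, dtype=bool)

    for g in range(G):
        y = pb.tensor[g]
        if not y.any():
            degenerate[g] = True
            converged[g] = True
            continue
        x = init.states[g].copy()
        for it in range(1, cfg.max_outer_iters + 1):
            theta, _ = pg.fit_theta(y, x, m, n, bounds=cfg.theta_bounds)
            if cfg.fix_phi is not None:
                phi = cfg.fix_phi
            else:
                phi, _ = mrf.fit_phi(x, A, bounds=cfg.phi_bounds)
            x_new = icm_sweep(y, x, theta, phi, A, m, n)
            changed = (x_new != x).any()
            x = x_new
            if not changed:
                converged[g] = True
                break
        states[g] = x
        alpha[g], beta[g] = theta.alpha, theta.beta
        gamma[g], beta_m[g] = phi.gamma, phi.beta
        iters[g] = it
    return ICMResult(StateMatrix(states, pb.gene_ids, pb.cell_type_labels),
                     alpha, beta, gamma, beta_m, iters, converged, degenerate)


# ---------------------------------------------------------------------------
# initializers


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def init_from_table(table: pd.DataFrame, gene_ids, cell_type_labels,
                    p_threshold: float = 0.05, logfc_threshold: float = 1.0,
                    preadjusted: bool = False) -> StateMatrix:
    """Build initial states from an external DE result table.

    Expects columns gene, cell_type, p_value (or adj_p_value when
    ``preadjusted``), logFC.  BH adjustment is applied per cell type across
    genes ("locally"); state is 1 iff adjusted p < ``p_threshold`` and
    |logFC| > ``logfc_threshold``.  Missing (gene, cell type) pairs get 0.
    """
    pcol = "adj_p_value" if preadjusted else "p_value"
    need = {"gene", "cell_type", pcol, "logFC"}
    if not need <= set(table.columns):
        raise InputValidationError(f"initialization table missing columns {sorted(need - set(table.columns))}")
    gi = {g: i for i, g in enumerate(gene_ids)}
    ki = {k: i for i, k in enumerate(cell_type_labels)}
    states = np.zeros((len(gene_ids), len(cell_type_labels)), dtype=np.int8)
    for ct, sub in table.groupby("cell_type"):
        if ct not in ki:
            raise InputValidationError(f"initialization table has unknown cell type {ct!r}")
        padj = sub[pcol].to_numpy(dtype=float) if preadjusted else bh_adjust(sub[pcol])
        hit = (padj < p_threshold) & (np.abs(sub["logFC"].to_numpy(dtype=float)) > logfc_threshold)
        for g, h in zip(sub["gene"], hit):
            if g in gi and h:
                states[gi[g], ki[ct]] = 1
    return StateMatrix(states, list(gene_ids), list(cell_type_labels))


def binomial_pvalues(pb: PseudobulkDataset) -> np.ndarray:
    """Exact two-sided binomial p-values per (gene, cell type).

    Conditioning on the total count of a (gene, cell type) across all
    samples, the condition-1 share is Binomial(total, m/(m+n)) under the
    null of equal per-sample means; an all-zero total gives p = 1.
    """
    m, n = pb.m, pb.n
    p0 = m / (m + n)
    s1 = pb.tensor[:, :, :m].sum(axis=2)
    tot = pb.tensor.sum(axis=2)
    pvals = np.ones_like(s1, dtype=float)
    for g in range(pb.n_genes):
        for k in range(pb.n_cell_types):
            if tot[g, k] > 0:
                pvals[g, k] = binomtest(int(s1[g, k]), int(tot[g, k]), p0).pvalue
    return pvals


def builtin_initializer(pb: PseudobulkDataset, mode: str = "binomial",
                        p_threshold: float = 0.05, logfc_threshold: float = 1.0,
                        logfc_pseudocount: float = 1.0, seed=None,
                        rng: np.random.Generator | None = None) -> StateMatrix:
    """Built-in state initializer.

    ``binomial``: exact conditional binomial test on condition-1 count
    share, BH-adjusted per cell type, thresholded on adjusted p and |logFC|.
    ``random``: iid Bernoulli(0.5) states (seeded).
    """
    if mode == "random":
        if rng is None:
            rng = np.random.default_rng(seed)
        states = (rng.random((pb.n_genes, pb.n_cell_types)) < 0.5).astype(np.int8)
        return StateMatrix(states, pb.gene_ids, pb.cell_type_labels)
    if mode != "binomial":
        raise ValueError(f"unknown initializer mode {mode!r}")
    pvals = binomial_pvalues(pb)
    padj = np.column_stack([bh_adjust(pvals[:, k]) for k in range(pb.n_cell_types)])
    lfc = compute_logfc(pb, pseudocount=logfc_pseudocount)
    states = ((padj < p_threshold) & (np.abs(lfc) > logfc_threshold)).astype(np.int8)
    return StateMatrix(states, pb.gene_ids, pb.cell_type_labels)


# ---------------------------------------------------------------------------
# logFC and call filtering


def cpm(pb: PseudobulkDataset) -> np.ndarray:
    """Counts-per-million within each (cell type, sample) column."""
    tensor = pb.tensor.astype(float)
    totals = tensor.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(totals > 0, tensor / totals * 1e6, 0.0)
    return out


def compute_logfc(pb: PseudobulkDataset, pseudocount: float = 1.0) -> np.ndarray:
    """log2 fold change (condition 2 vs condition 1) of mean CPM, per
    (gene, cell type), with a pseudocount on both means."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    m = pb.m
    x = cpm(pb)
    mean1 = x[:, :, :m].mean(axis=2)
    mean2 = x[:, :, m:].mean(axis=2)
    return np.log2((mean2 + pseudocount) / (mean1 + pseudocount))


def apply_filters(states: StateMatrix, logfc: np.ndarray, pb: PseudobulkDataset,
                  cfg: ICMConfig) -> pd.DataFrame:
    """Turn inferred states into final DE calls.

    call = (state == 1) AND |logFC| > threshold AND expression filter.
    The expression filter (real-data mode) requires the (gene, cell type)
    mean CPM across samples to exceed the configured percentile of all
    pooled gene x cell-type mean-CPM values; it is a pass-through when
    ``cfg.expression_percentile`` is None (simulation mode).
    """
    G, K = states.states.shape
    if logfc.shape != (G, K) or pb.tensor.shape[:2] != (G, K):
        raise InputValidationError("states / logFC / pseudobulk shapes disagree")
    logfc_pass = np.abs(logfc) > cfg.logfc_threshold
    if cfg.expression_percentile is None:
        expr_pass = np.ones((G, K), dtype=bool)
    else:
        mean_expr = cpm(pb).mean(axis=2)
        cut = np.percentile(mean_expr, cfg.expression_percentile)
        expr_pass = mean_expr > cut
    call = (states.states == 1) & logfc_pass & expr_pass
    df = pd.DataFrame({
        "gene": np.repeat(states.gene_ids, K),
        "cell_type": np.tile(states.cell_type_labels, G),
        "state": states.states.reshape(-1).astype(np.int64),
        "logFC": logfc.reshape(-1),
        "expression_pass": expr_pass.reshape(-1),
        "logfc_pass": logfc_pass.reshape(-1),
        "call": call.reshape(-1),
    })
    return df.loc[:, CALL_COLUMNS]
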