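"""Network-aware negative-binomial simulation and benchmarking.

The generator mirrors a multi-sample, multi-cell-type scRNA-seq design:

* a random cell-type network (exactly ``round(connectivity * K(K-1)/2)``
  pairs connected, chosen uniformly);
* per-gene latent DE/EE states sampled by a few Gibbs sweeps from the MRF
  on that network (default Phi_true = (-10, 11), sweeps = 5, Bernoulli(0.5)
  start), so DE appears in network-coherent clusters against a mostly-EE
  background;
* counts from a negative binomial whose mean combines a log-normal gene
  baseline, a per-(gene, cell type) effect, and per-sample biological and
  library-size factors; DE (gene, cell type) pairs draw a log2 fold-change
  magnitude from Gamma(shape 4, rate 4/tau) (mean tau), an up/down sign,
  and a uniformly chosen condition whose mean is multiplied by 2^(+-delta).

``fast`` mode draws pseudobulk directly (a sum of n_c iid NB(mu, 1/disp)
cells is NB(n_c * mu, n_c / disp)); ``cells`` mode emits the full
cell-level matrix plus annotations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import icm, mrf
from .data_model import (CellAnnotations, CellCounts, CellTypeNetwork,
                         PseudobulkDataset, StateMatrix)


@dataclass(frozen=True)
class NBReference:
    """Synthetic stand-in for a reference-data NB parameter fit.

    All scales are on the natural-log scale of multiplicative factors.
    Defaults give per-cell gene means with median ~0.22 and a long right
    tail, moderate cell-type structure, ~15% sample-to-sample biological
    variation, and per-cell NB dispersions centred at 1.
    """

    gene_mean_loc: float = -1.5
    gene_mean_scale: float = 1.0
    cell_type_effect_scale: float = 0.5
    sample_effect_scale: float = 0.15
    dispersion_loc: float = 0.0
    dispersion_scale: float = 0.5
    library_size_loc: float = 0.0
    library_size_scale: float = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    K: int = 6
    connectivity: float = 0.5
    n_genes: int = 1000
    n_cells: int = 150          # cells per cell type per sample (n_c)
    n_samples: int = 4          # samples per condition (n_s)
    tau: float = 2.0            # average |log2 FC| of DE pairs
    phi_true: mrf.MRFParams = field(default_factory=lambda: mrf.MRFParams(-10.0, 11.0))
    gibbs_sweeps: int = 5
    init_prob: float = 0.5
    logfc_shape: float = 4.0    # Gamma shape for |log2 FC|
    nb_reference: NBReference = field(default_factory=NBReference)
    mode: str = "fast"          # "fast" (pseudobulk NB) or "cells"
    seed: int = 0

    def __post_init__(self):
        if self.K < 2 or not (0.0 <= self.connectivity <= 1.0):
            raise ValueError("need K >= 2 and connectivity in [0, 1]")
        if self.tau <= 0 or self.n_cells < 1 or self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("tau > 0 and n_cells, n_samples, n_genes >= 1 required")
        if self.mode not in ("fast", "cells"):
            raise ValueError(f"mode must be 'fast' or 'cells', got {self.mode!r}")


@dataclass
class SimulatedDataset:
    pseudobulk: PseudobulkDataset
    truth_states: StateMatrix
    truth_logfc: np.ndarray     # signed log2 FC (condition 2 vs 1); 0 where EE
    network: CellTypeNetwork
    counts: CellCounts | None = None
    annotations: CellAnnotations | None = None


@dataclass
class BenchmarkMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def fdr(self) -> float:
        return self.fp / max(1, self.tp + self.fp)


def random_network(K: int, connectivity: float, seed=None,
                   rng: np.random.Generator | None = None) -> CellTypeNetwork:
    """Uniformly choose exactly round(connectivity * K(K-1)/2) node pairs."""
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes = [f"CT{i + 1}" for i in range(K)]
    pairs = list(itertools.combinations(nodes, 2))
    n_edges = int(round(connectivity * len(pairs)))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False) if n_edges else []
    return CellTypeNetwork(nodes, {pairs[i] for i in chosen})


def simulate_truth(net: CellTypeNetwork, cfg: SimulationConfig,
                   rng: np.random.Generator | None = None) -> StateMatrix:
    """Latent states from a few Gibbs sweeps of the MRF (not run to
    stationarity on purpose: a short chain from a Bernoulli(0.5) start
    leaves network-coherent DE clusters over a mostly-EE background)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    states = mrf.gibbs_sample_states(net.adjacency(), cfg.phi_true, cfg.n_genes,
                                     cfg.gibbs_sweeps, init_prob=cfg.init_prob, rng=rng)
    genes = [f"gene{i + 1}" for i in range(cfg.n_genes)]
    return StateMatrix(states, genes, net.nodes)


def draw_logfc(n: int, tau: float, shape: float = 4.0,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Signed log2 fold changes: magnitude ~ Gamma(shape, rate shape/tau)
    (mean tau), sign uniform."""
    if rng is None:
        rng = np.random.default_rng()
    mag = rng.gamma(shape, scale=tau / shape, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * mag


def build_mean_tensor(truth: StateMatrix, cfg: SimulationConfig,
                      rng: np.random.Generator):
    """Per-cell NB mean tensor (G x K x S) plus per-gene dispersions and the
    effective condition-2-vs-1 log2 FC.  Sample ordering: the n_s
    condition-1 samples first."""
    ref = cfg.nb_reference
    G, K = truth.states.shape
    S = 2 * cfg.n_samples
    gene_eff = rng.normal(ref.gene_mean_loc, ref.gene_mean_scale, size=G)
    ct_eff = rng.normal(0.0, ref.cell_type_effect_scale, size=(G, K))
    base = np.exp(gene_eff[:, None] + ct_eff)                       # per-cell mean
    samp = np.exp(rng.normal(0.0, ref.sample_effect_scale, size=S)
                  + rng.normal(ref.library_size_loc, ref.library_size_scale, size=S))
    disp = np.exp(rng.normal(ref.dispersion_loc, ref.dispersion_scale, size=G))

    de = truth.states == 1
    delta = np.zeros((G, K))
    delta[de] = rng.gamma(cfg.logfc_shape, scale=cfg.tau / cfg.logfc_shape, size=de.sum())
    sign = np.where(rng.random((G, K)) < 0.5, 1.0, -1.0)
    hit_cond2 = rng.random((G, K)) < 0.5    # which condition's mean is scaled
    fold = np.exp2(np.clip(sign * delta, -30, 30))
    factor = np.ones((G, K, S))
    factor[:, :, cfg.n_samples:] = np.where((de & hit_cond2)[:, :, None], fold[:, :, None], 1.0)
    factor[:, :, :cfg.n_samples] = np.where((de & ~hit_cond2)[:, :, None], fold[:, :, None], 1.0)
    mean = base[:, :, None] * samp[None, None, :] * factor
    # effective condition-2-vs-1 log2 FC
    truth_logfc = np.where(de, np.where(hit_cond2, sign * delta, -sign * delta), 0.0)
    return mean, disp, truth_logfc


def simulate_counts(truth: StateMatrix, net: CellTypeNetwork, cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw counts given the latent truth (fast pseudobulk or full cells)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    G, K = truth.states.shape
    S = 2 * cfg.n_samples
    mean, disp, truth_logfc = build_mean_tensor(truth, cfg, rng)
    samples = [f"s{c}_{i + 1}" for c in (1, 2) for i in range(cfg.n_samples)]
    conditions = ["cond1"] * cfg.n_samples + ["cond2"] * cfg.n_samples

    def nb_draw(mu, size_r):
        p = size_r / (size_r + mu)
        return rng.negative_binomial(size_r, np.clip(p, 1e-12, 1.0))

    if cfg.mode == "fast":
        mu_pb = cfg.n_cells * mean
        r_pb = (cfg.n_cells / disp)[:, None, None] * np.ones((1, K, S))
        tensor = nb_draw(mu_pb, r_pb).astype(np.int64)
        pb = PseudobulkDataset(tensor, truth.gene_ids, net.nodes, samples, conditions)
        return SimulatedDataset(pb, truth, truth_logfc, net)

    # full cell-level simulation
    n_c = cfg.n_cells
    cell_ids, rows = [], []
    blocks = []
    lib = cfg.nb_reference
    for k, ct in enumerate(net.nodes):
        for s, (sid, cond) in enumerate(zip(samples, conditions)):
            cell_lib = np.exp(rng.normal(0.0, lib.library_size_scale, size=n_c))
            cell_lib /= cell_lib.mean()     # sample-level factor already in `mean`
            mu = mean[:, k, s][:, None] * cell_lib[None, :]
            r = (1.0 / disp)[:, None] * np.ones((1, n_c))
            blocks.append(nb_draw(mu, r))
            ids = [f"{sid}.{ct}.c{i + 1}" for i in range(n_c)]
            cell_ids += ids
            rows += [(cid, sid, ct, cond) for cid in ids]
    matrix = np.concatenate(blocks, axis=1).astype(np.int64)
    counts = CellCounts(matrix, truth.gene_ids, cell_ids)
    ann = CellAnnotations(pd.DataFrame(rows, columns=["cell_id", "sample_id", "cell_type", "condition"]))
    tensor = np.zeros((G, K, S), dtype=np.int64)
    col = 0
    for k in range(K):
        for s in range(S):
            tensor[:, k, s] = matrix[:, col:col + n_c].sum(axis=1)
            col += n_c
    pb = PseudobulkDataset(tensor, truth.gene_ids, net.nodes, samples, conditions)
    return SimulatedDataset(pb, truth, truth_logfc, net, counts=counts, annotations=ann)


def simulate(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Network -> latent truth -> counts, from one seeded generator."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    net = random_network(cfg.K, cfg.connectivity, rng=rng)
    truth = simulate_truth(net, cfg, rng=rng)
    return simulate_counts(truth, net, cfg, rng=rng)


# ---------------------------------------------------------------------------
# scenarios and benchmarking

SCENARIO_REPLICATES = {"full": 50, "reduced": 5}


def scenario_grid(scenario: int, reduced: bool = False) -> list[SimulationConfig]:
    """Benchmark grids: scenario 1 varies cells per type (n_c), scenario 2
    samples per condition (n_s), scenario 3 the mean logFC (tau)."""
    base = SimulationConfig(n_genes=300 if reduced else 1000)
    if scenario == 1:
        vals = [100, 150, 300] if reduced else list(range(100, 1001, 100))
        return [replace(base, n_cells=v, tau=2.0, n_samples=4) for v in vals]
    if scenario == 2:
        vals = [3, 6, 12] if reduced else list(range(3, 13))
        return [replace(base, n_samples=v, n_cells=150, tau=2.0) for v in vals]
    if scenario == 3:
        vals = [1.2, 2.0, 3.8] if reduced else [round(v, 2) for v in np.linspace(1.2, 3.8, 10)]
        return [replace(base, tau=v, n_cells=150, n_samples=4) for v in vals]
    raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")


def evaluate_calls(calls: pd.DataFrame, truth: StateMatrix,
                   exclude_genes=()) -> BenchmarkMetrics:
    """Confusion counts of boolean calls against truth at (gene, cell type)
    resolution; ``exclude_genes`` (e.g. degenerate all-zero genes) are
    dropped from both arms."""
    excl = set(exclude_genes)
    tr = pd.DataFrame(truth.states.astype(bool), index=truth.gene_ids,
                      columns=truth.cell_type_labels).stack()
    tr.index.names = ["gene", "cell_type"]
    ca = calls.set_index(["gene", "cell_type"])["call"].astype(bool)
    joined = pd.concat([tr.rename("truth"), ca.rename("call")], axis=1)
    if joined.isna().any().any():
        raise ValueError("calls and truth cover different (gene, cell type) sets")
    if excl:
        joined = joined[~joined.index.get_level_values("gene").isin(excl)]
    t, c = joined["truth"].to_numpy(), joined["call"].to_numpy()
    return BenchmarkMetrics(tp=int((t & c).sum()), fp=int((~t & c).sum()),
                            tn=int((~t & ~c).sum()), fn=int((t & ~c).sum()))


METHODS = ("initializer", "mrf_builtin", "mrf_random")


def _run_methods(sim: SimulatedDataset, cfg: SimulationConfig, methods,
                 init_rng: np.random.Generator):
    """Run each benchmark arm on one simulated replicate; yields rows."""
    pb, net = sim.pseudobulk, sim.network
    thr = cfg.tau / 2.0
    icm_cfg = icm.ICMConfig(logfc_threshold=thr)
    lfc = icm.compute_logfc(pb, pseudocount=icm_cfg.logfc_pseudocount)
    degenerate = [g for g, row in zip(pb.gene_ids, pb.tensor) if not row.any()]
    init_binom = icm.builtin_initializer(pb, mode="binomial", p_threshold=0.05,
                                         logfc_threshold=thr)
    for method in methods:
        if method == "initializer":
            # initializer alone: BH p < 0.05 and |logFC| > tau/2 (its states
            # already encode both thresholds)
            states = init_binom
        elif method == "mrf_builtin":
            states = icm.run_icm(pb, net, init_binom, icm_cfg).states
        elif method == "mrf_random":
            init_rand = icm.builtin_initializer(pb, mode="random", rng=init_rng)
            states = icm.run_icm(pb, net, init_rand, icm_cfg).states
        else:
            raise ValueError(f"unknown method {method!r}")
        calls = icm.apply_filters(states, lfc, pb, icm_cfg)
        met = evaluate_calls(calls, sim.truth_states, exclude_genes=degenerate)
        yield method, met


def run_benchmark(scenario: int, reduced: bool = False, seed: int = 0,
                  methods=METHODS, replicates: int | None = None,
                  grid: list[SimulationConfig] | None = None) -> pd.DataFrame:
    """Simulate -> initialize -> infer -> call -> score over a scenario grid.

    Returns a tidy table with one row per (grid point, replicate, method).
    Deterministic given ``seed``; all arms within a replicate share the
    simulated data.
    """
    if grid is None:
        grid = scenario_grid(scenario, reduced=reduced)
    if replicates is None:
        replicates = SCENARIO_REPLICATES["reduced" if reduced else "full"]
    param = {1: "n_cells", 2: "n_samples", 3: "tau"}[scenario]
    rows = []
    for cfg in grid:
        for rep in range(replicates):
            sim_seq, init_seq = np.random.SeedSequence((seed, scenario, hash(getattr(cfg, param)) % (2**31), rep)).spawn(2)
            sim = simulate(cfg, rng=np.random.default_rng(sim_seq))
            for method, met in _run_methods(sim, cfg, methods, np.random.default_rng(init_seq)):
                rows.append({
                    "scenario": scenario, "param": param,
                    "value": getattr(cfg, param), "replicate": rep, "method": method,
                    "sensitivity": met.sensitivity, "specificity": met.specificity,
                    "fdr": met.fdr, "tp": met.tp, "fp": met.fp, "tn": met.tn, "fn": met.fn,
                })
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean sensitivity/specificity/FDR per (grid value, method)."""
    return (table.groupby(["scenario", "param", "value", "method"], as_index=False)
            [["sensitivity", "specificity", "fdr"]].mean())
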