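"""Core data containers, file I/O and pseudobulk aggregation.

The containers here are deliberately thin: validated numpy arrays plus label
vectors, with pandas used for all tabular I/O and :mod:`scipy.io` for
Matrix-Market files.  Pseudobulk counts for a gene in cell type *k* are the
sums of that gene's counts over all cells of type *k* within one sample,
arranged condition-1 samples first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["gene", "cell_type", "state", "logFC", "expression_pass", "logfc_pass", "call"]


class DataFormatError(ValueError):
    """A file could not be parsed as the expected format."""


class InputValidationError(ValueError):
    """Inputs are structurally inconsistent (labels, shapes, conditions)."""


def _check_counts(matrix: np.ndarray) -> np.ndarray:
    arr = np.asarray(matrix)
    if arr.ndim != 2:
        raise InputValidationError(f"count matrix must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise InputValidationError("counts must be integers (normalized inputs are rejected)")
    if (arr < 0).any():
        raise InputValidationError("counts must be non-negative")
    return arr.astype(np.int64, copy=False)


def _check_unique(labels, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise InputValidationError(f"duplicate {what} identifiers")
    return labels


@dataclass
class CellCounts:
    """Gene x cell integer count matrix with identifiers."""

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.matrix = _check_counts(self.matrix)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if self.matrix.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise InputValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )


@dataclass
class CellAnnotations:
    """Per-cell metadata: sample of origin, cell type, condition.

    Each sample must belong to exactly one condition, and exactly two
    condition labels must be present for a two-group comparison.
    """

    table: pd.DataFrame

    REQUIRED = ("cell_id", "sample_id", "cell_type", "condition")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InputValidationError(f"annotation table missing columns: {missing}")
        tab = self.table.loc[:, list(self.REQUIRED)].astype(str)
        if tab.isna().any().any():
            raise InputValidationError("annotation table contains missing values")
        if tab["cell_id"].duplicated().any():
            raise InputValidationError("duplicate cell_id in annotations")
        per_sample = tab.groupby("sample_id")["condition"].nunique()
        if (per_sample > 1).any():
            bad = per_sample[per_sample > 1].index.tolist()
            raise InputValidationError(f"samples mapped to multiple conditions: {bad}")
        self.table = tab.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())


@dataclass
class PseudobulkDataset:
    """Gene x cell-type x sample pseudobulk counts with condition labels.

    ``tensor[g, k, s]`` is the summed count of gene ``g`` over all cells of
    cell type ``k`` in sample ``s``.  Samples are ordered with the ``m``
    condition-1 samples first, then the ``n`` condition-2 samples.
    """

    tensor: np.ndarray
    gene_ids: list[str]
    cell_type_labels: list[str]
    sample_ids: list[str]
    sample_conditions: list[str]

    def __post_init__(self):
        arr = np.asarray(self.tensor)
        if arr.ndim != 3:
            raise InputValidationError(f"pseudobulk tensor must be 3-D, got shape {arr.shape}")
        flat = _check_counts(arr.reshape(arr.shape[0], -1))
        self.tensor = flat.reshape(arr.shape)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_type_labels = _check_unique(self.cell_type_labels, "cell type")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.sample_conditions = [str(c) for c in self.sample_conditions]
        g, k, s = self.tensor.shape
        if (g, k, s) != (len(self.gene_ids), len(self.cell_type_labels), len(self.sample_ids)):
            raise InputValidationError("tensor dimensions do not match label vectors")
        conds = list(dict.fromkeys(self.sample_conditions))
        if len(conds) != 2:
            raise InputValidationError(f"exactly two conditions required, got {conds}")
        # condition-1 block first, contiguous
        n1 = self.sample_conditions.count(conds[0])
        if self.sample_conditions != [conds[0]] * n1 + [conds[1]] * (s - n1):
            raise InputValidationError("samples must be ordered condition-1 block then condition-2 block")
        if n1 < 1 or s - n1 < 1:
            raise InputValidationError("each condition needs at least one sample")

    @property
    def condition_labels(self) -> tuple[str, str]:
        conds = list(dict.fromkeys(self.sample_conditions))
        return conds[0], conds[1]

    @property
    def m(self) -> int:
        return self.sample_conditions.count(self.condition_labels[0])

    @property
    def n(self) -> int:
        return len(self.sample_ids) - self.m

    @property
    def n_genes(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.tensor.shape[1]


@dataclass
class CellTypeNetwork:
    """Undirected graph on cell-type labels (no self-loops, no multi-edges)."""

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self.nodes = _check_unique(self.nodes, "node")
        node_set = set(self.nodes)
        norm = set()
        for e in self.edges:
            a, b = str(e[0]), str(e[1])
            if a == b:
                raise InputValidationError(f"self-loop on node {a!r}")
            if a not in node_set or b not in node_set:
                raise InputValidationError(f"edge ({a!r}, {b!r}) references unknown node")
            norm.add((min(a, b), max(a, b)))
        self.edges = norm

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def neighbors(self, node: str) -> set[str]:
        return {b if a == node else a for a, b in self.edges if node in (a, b)}

    def adjacency(self, order: list[str] | None = None) -> np.ndarray:
        """Boolean adjacency matrix in the given node order (default: self.nodes)."""
        order = list(order) if order is not None else self.nodes
        if set(order) != set(self.nodes):
            raise InputValidationError("adjacency order must be a permutation of the node set")
        idx = {v: i for i, v in enumerate(order)}
        A = np.zeros((len(order), len(order)), dtype=bool)
        for a, b in self.edges:
            A[idx[a], idx[b]] = A[idx[b], idx[a]] = True
        return A


@dataclass
class StateMatrix:
    """Binary DE/EE states, genes x cell types (1 = DE)."""

    states: np.ndarray
    gene_ids: list[str]
    cell_type_labels: list[str]

    def __post_init__(self):
        arr = np.asarray(self.states)
        if not np.isin(arr, [0, 1]).all():
            raise InputValidationError("states must be binary")
        self.states = arr.astype(np.int8)
        if self.states.shape != (len(self.gene_ids), len(self.cell_type_labels)):
            raise InputValidationError("state matrix shape does not match labels")


def aggregate_pseudobulk(counts: CellCounts, ann: CellAnnotations,
                         condition_order: tuple[str, str] | None = None,
                         network: CellTypeNetwork | None = None) -> PseudobulkDataset:
    """Sum cell-level counts into gene x cell-type x sample pseudobulk.

    Samples are ordered condition-1 first (lexicographic within condition);
    by default condition labels are taken in sorted order.  (cell type,
    sample) groups with no cells yield all-zero columns and are logged.

    Parameters
    ----------
    condition_order
        Which condition label is "condition 1"; default sorted order.
    network
        If given, its node set defines (and validates) the cell-type labels.
    """
    tab = ann.table
    missing = set(tab["cell_id"]) - set(counts.cell_ids)
    if missing:
        raise InputValidationError(f"annotated cells absent from count matrix: {sorted(missing)[:5]}")
    conds = ann.conditions
    if len(conds) != 2:
        raise InputValidationError(f"exactly two conditions required, got {conds}")
    if condition_order is not None:
        if sorted(condition_order) != sorted(conds):
            raise InputValidationError("condition_order does not match annotated conditions")
        conds = list(condition_order)

    if network is not None:
        unknown = set(tab["cell_type"]) - set(network.nodes)
        if unknown:
            raise InputValidationError(f"cell types absent from network: {sorted(unknown)}")
        cell_types = list(network.nodes)
    else:
        cell_types = ann.cell_types

    samp_cond = tab.drop_duplicates("sample_id").set_index("sample_id")["condition"]
    sample_ids = [s for c in conds for s in sorted(samp_cond[samp_cond == c].index)]
    sample_conditions = [samp_cond[s] for s in sample_ids]

    cell_pos = {c: i for i, c in enumerate(counts.cell_ids)}
    G = len(counts.gene_ids)
    tensor = np.zeros((G, len(cell_types), len(sample_ids)), dtype=np.int64)
    grouped = tab.groupby(["cell_type", "sample_id"], sort=False).groups
    ct_idx = {c: i for i, c in enumerate(cell_types)}
    s_idx = {s: i for i, s in enumerate(sample_ids)}
    for k in cell_types:
        for s in sample_ids:
            rows = grouped.get((k, s))
            if rows is None or len(rows) == 0:
                logger.warning("empty pseudobulk group: cell type %r, sample %r", k, s)
                continue
            cols = [cell_pos[c] for c in tab.loc[rows, "cell_id"]]
            tensor[:, ct_idx[k], s_idx[s]] = counts.matrix[:, cols].sum(axis=1)
    return PseudobulkDataset(tensor, counts.gene_ids, cell_types, sample_ids, sample_conditions)


def equalize_depth(pb: PseudobulkDataset) -> PseudobulkDataset:
    """Rescale every (cell type, sample) column to the mean column total,
    rounding back to integers.

    The count model assumes a common mean per condition group and carries no
    library-size offset, so this optional pre-scaling is the escape hatch
    when sequencing depth differs sharply between samples.  Off by default
    everywhere.
    """
    tensor = pb.tensor.astype(float)
    totals = tensor.sum(axis=0)
    target = totals[totals > 0].mean() if (totals > 0).any() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, tensor * (target / totals), 0.0)
    return PseudobulkDataset(np.rint(scaled).astype(np.int64), pb.gene_ids,
                             pb.cell_type_labels, pb.sample_ids, pb.sample_conditions)


# ---------------------------------------------------------------------------
# file I/O


def read_counts(path, format: str = "auto") -> CellCounts:
    """Read a count matrix: dense TSV (genes x cells, first column gene ids)
    or a 10x-style Matrix-Market prefix/directory with ``matrix.mtx``,
    ``features.tsv`` and ``barcodes.tsv``."""
    import os

    if format == "auto":
        format = "mtx" if os.path.isdir(path) or str(path).endswith(".mtx") else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise DataFormatError(f"cannot parse dense TSV {path}: {exc}") from exc
        try:
            mat = _check_counts(df.to_numpy())
        except InputValidationError as exc:
            raise DataFormatError(f"{path}: {exc}") from exc
        return CellCounts(mat, list(df.index.astype(str)), list(df.columns.astype(str)))
    if format == "mtx":
        import os

        base = path if os.path.isdir(path) else os.path.dirname(path) or "."
        mtx = path if str(path).endswith(".mtx") else os.path.join(base, "matrix.mtx")
        try:
            mat = np.asarray(mmread(mtx).todense())
        except Exception as exc:
            raise DataFormatError(f"cannot parse Matrix-Market file {mtx}: {exc}") from exc
        genes = pd.read_csv(os.path.join(base, "features.tsv"), sep="\t", header=None)[0]
        cells = pd.read_csv(os.path.join(base, "barcodes.tsv"), sep="\t", header=None)[0]
        try:
            mat = _check_counts(mat)
        except InputValidationError as exc:
            raise DataFormatError(f"{mtx}: {exc}") from exc
        return CellCounts(mat, list(genes.astype(str)), list(cells.astype(str)))
    raise ValueError(f"unknown format {format!r}")


def write_counts(counts: CellCounts, path, format: str = "tsv") -> None:
    import os

    if format == "tsv":
        df = pd.DataFrame(counts.matrix, index=counts.gene_ids, columns=counts.cell_ids)
        df.to_csv(path, sep="\t")
    elif format == "mtx":
        os.makedirs(path, exist_ok=True)
        mmwrite(os.path.join(path, "matrix.mtx"), coo_matrix(counts.matrix))
        pd.Series(counts.gene_ids).to_csv(os.path.join(path, "features.tsv"),
                                          sep="\t", header=False, index=False)
        pd.Series(counts.cell_ids).to_csv(os.path.join(path, "barcodes.tsv"),
                                          sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotations(path) -> CellAnnotations:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise DataFormatError(f"cannot parse annotation TSV {path}: {exc}") from exc
    return CellAnnotations(df)


def write_annotations(ann: CellAnnotations, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_network(path, nodes: list[str] | None = None) -> CellTypeNetwork:
    """Read a two-column TSV edge list.  If ``nodes`` is not given the node
    set is the union of edge endpoints."""
    edges = []
    seen_nodes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise DataFormatError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            a, b = parts
            if lineno == 1 and {a.lower(), b.lower()} <= {"source", "target", "from", "to", "node1", "node2"}:
                continue
            edges.append((a, b))
            for v in (a, b):
                if v not in seen_nodes:
                    seen_nodes.append(v)
    if nodes is None:
        nodes = seen_nodes
    try:
        return CellTypeNetwork(nodes, set(edges))
    except InputValidationError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_network(net: CellTypeNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def write_calls(table: pd.DataFrame, path) -> None:
    """Write a DE-call table with the fixed column set to TSV."""
    missing = [c for c in CALL_COLUMNS if c not in table.columns]
    if missing:
        raise InputValidationError(f"call table missing columns: {missing}")
    table.loc[:, CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: call table missing columns: {missing}")
    for col in ("expression_pass", "logfc_pass", "call"):
        df[col] = df[col].astype(bool)
    df["gene"] = df["gene"].astype(str)
    df["cell_type"] = df["cell_type"].astype(str)
    return df


def write_pseudobulk(pb: PseudobulkDataset, path) -> None:
    """Write pseudobulk in long format: gene, cell_type, sample, condition, count."""
    G, K, S = pb.tensor.shape
    df = pd.DataFrame({
        "gene": np.repeat(pb.gene_ids, K * S),
        "cell_type": np.tile(np.repeat(pb.cell_type_labels, S), G),
        "sample": np.tile(pb.sample_ids, G * K),
        "condition": np.tile(pb.sample_conditions, G * K),
        "count": pb.tensor.reshape(-1),
    })
    df.to_csv(path, sep="\t", index=False)


def read_pseudobulk(path, condition_order: tuple[str, str] | None = None) -> PseudobulkDataset:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cell_type": str,
                                                "sample": str, "condition": str})
    except Exception as exc:
        raise DataFormatError(f"cannot parse pseudobulk TSV {path}: {exc}") from exc
    need = {"gene", "cell_type", "sample", "condition", "count"}
    if not need <= set(df.columns):
        raise DataFormatError(f"{path}: pseudobulk TSV missing columns {sorted(need - set(df.columns))}")
    genes = list(dict.fromkeys(df["gene"]))
    cts = list(dict.fromkeys(df["cell_type"]))
    samp_cond = df.drop_duplicates("sample").set_index("sample")["condition"]
    conds = sorted(samp_cond.unique()) if condition_order is None else list(condition_order)
    if len(set(samp_cond.unique())) != 2:
        raise DataFormatError(f"{path}: exactly two conditions required")
    samples = [s for c in conds for s in sorted(samp_cond[samp_cond == c].index)]
    wide = df.set_index(["gene", "cell_type", "sample"])["count"]
    idx = pd.MultiIndex.from_product([genes, cts, samples], names=["gene", "cell_type", "sample"])
    try:
        tensor = wide.reindex(idx).to_numpy().reshape(len(genes), len(cts), len(samples))
    except Exception as exc:
        raise DataFormatError(f"{path}: inconsistent pseudobulk table: {exc}") from exc
    if np.isnan(np.asarray(tensor, dtype=float)).any():
        raise DataFormatError(f"{path}: missing (gene, cell_type, sample) combinations")
    return PseudobulkDataset(np.asarray(tensor, dtype=np.int64), genes, cts, samples,
                             [samp_cond[s] for s in samples])


def write_states(states: StateMatrix, path) -> None:
    pd.DataFrame(states.states, index=states.gene_ids,
                 columns=states.cell_type_labels).to_csv(path, sep="\t")


def read_states(path) -> StateMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return StateMatrix(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))
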