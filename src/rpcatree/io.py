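"""Readers, writers, and the end-to-end pipeline.

Matrices travel as dense CSV/TSV (cells as rows; header and row names
optional) or MatrixMarket files.  Missing entries are empty fields,
``NA``/``NaN``, or a configured numeric sentinel (e.g. 3 for SNV
genotype files that code dropout as an extra state).  Trees are written
as tab-separated edge lists, GraphML, and rooted Newick with Euclidean
center distances as branch lengths.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mst import TreeTopology
from .postprocess import CloneTree, summarize
from .rpca import DataKind, ObservedMatrix, rpca_decompose
from .solver import Hyperparams, SolverState, fit, select_hyperparams

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_tree_edgelist",
    "write_graphml",
    "write_newick",
    "RunConfig",
    "run_pipeline",
]

_NA_STRINGS = {"", "na", "nan", "n/a", "null", "none"}


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect:
        return {"csv": ",", "tsv": "\t"}[dialect]
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_matrix(
    path: str | Path,
    dialect: str | None = None,
    missing_sentinel: float | None = None,
    kind: DataKind | str = DataKind.continuous,
    transpose: bool = False,
) -> ObservedMatrix:
    """Read a dense CSV/TSV or MatrixMarket file into an observed matrix.

    ``dialect`` is ``"csv"``, ``"tsv"`` or ``"mtx"`` (inferred from the
    extension by default).  A header row and a row-name column are
    auto-detected for delimited files.  NA-like fields and the optional
    numeric ``missing_sentinel`` become unobserved entries (mask False,
    value zero-filled).  ``transpose`` flips genes-as-rows files into
    the canonical cells-as-rows orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "mtx" or (dialect is None and path.suffix.lower() == ".mtx"):
        from scipy.io import mmread

        X = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense") else mmread(path), dtype=float)
        X = np.atleast_2d(X)
        row_names = col_names = None
    else:
        sep = _infer_sep(path, dialect)
        first = path.read_text().splitlines()[0].split(sep)

        def _numeric_or_na(tok: str) -> bool:
            t = tok.strip().strip('"')
            if t.lower() in _NA_STRINGS:
                return True
            try:
                float(t)
                return True
            except ValueError:
                return False

        header = 0 if not all(_numeric_or_na(t) for t in first) else None
        try:
            df = pd.read_csv(path, sep=sep, header=header, na_values=list(_NA_STRINGS),
                             keep_default_na=True, skipinitialspace=True)
        except pd.errors.ParserError as exc:
            raise ValueError(f"failed to parse {path}: {exc}") from None
        row_names = None
        first_col = df.iloc[:, 0]
        if first_col.dtype == object and not first_col.map(
            lambda v: isinstance(v, float) or _numeric_or_na(str(v))
        ).all():
            row_names = first_col.astype(str).tolist()
            df = df.iloc[:, 1:]
        col_names = [str(c) for c in df.columns] if header == 0 else None
        values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        bad = np.isnan(values) & df.notna().to_numpy()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-numeric cell at data row {i + 1}, column {j + 1} of {path}: {df.iat[i, j]!r}"
            )
        X = values
    mask = np.isfinite(X)
    if missing_sentinel is not None:
        mask &= X != missing_sentinel
    X = np.where(mask, X, 0.0)
    if transpose:
        X, mask = X.T, mask.T
        row_names, col_names = col_names, row_names
    return ObservedMatrix(X, mask, DataKind(kind), row_names=row_names, col_names=col_names)


def write_matrix(path: str | Path, X: np.ndarray, row_names=None, col_names=None,
                 mask: np.ndarray | None = None) -> None:
    """Write a dense matrix as CSV/TSV (by extension); masked entries become NA."""
    path = Path(path)
    sep = _infer_sep(path, None)
    values = np.asarray(X, dtype=float)
    if mask is not None:
        values = np.where(np.asarray(mask, bool), values, np.nan)
    df = pd.DataFrame(values, index=row_names, columns=col_names)
    df.to_csv(path, sep=sep, index=row_names is not None, header=col_names is not None,
              na_rep="NA")


def write_tree_edgelist(path: str | Path, tree: TreeTopology, centers: np.ndarray | None = None) -> None:
    """Tab-separated ``u<TAB>v<TAB>weight`` edge list (weight = Euclidean distance)."""
    lines = []
    for i, j in tree.edges:
        w = float(np.linalg.norm(centers[i] - centers[j])) if centers is not None else 1.0
        lines.append(f"{i}\t{j}\t{w:.10g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(path: str | Path, tree: TreeTopology, centers: np.ndarray | None = None) -> None:
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(tree.n_vertices))
    for i, j in tree.edges:
        w = float(np.linalg.norm(centers[i] - centers[j])) if centers is not None else 1.0
        G.add_edge(i, j, weight=w)
    nx.write_graphml(G, str(path))


def newick_string(tree: TreeTopology, root: int, centers: np.ndarray | None = None,
                  names: list[str] | None = None) -> str:
    """Rooted Newick with Euclidean center distances as branch lengths."""
    children: dict[int, list[int]] = {v: [] for v in range(tree.n_vertices)}
    seen = {root}
    queue = [root]
    while queue:
        u = queue.pop(0)
        for v in np.nonzero(tree.B[u])[0]:
            v = int(v)
            if v not in seen:
                seen.add(v)
                children[u].append(v)
                queue.append(v)

    def name(v: int) -> str:
        return names[v] if names else f"c{v}"

    def rec(v: int) -> str:
        if not children[v]:
            return name(v)
        return "(" + ",".join(_with_len(c, v) for c in children[v]) + ")" + name(v)

    def _with_len(c: int, p: int) -> str:
        s = rec(c)
        if centers is not None:
            s += f":{float(np.linalg.norm(centers[c] - centers[p])):.10g}"
        return s

    return rec(root) + ";"


def write_newick(path: str | Path, tree: TreeTopology, root: int,
                 centers: np.ndarray | None = None, names: list[str] | None = None) -> None:
    Path(path).write_text(newick_string(tree, root, centers, names) + "\n")


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (mirrors the CLI flags)."""

    input: str | Path | ObservedMatrix
    outdir: str | Path = "rpcatree_out"
    kind: DataKind | str = DataKind.continuous
    dialect: str | None = None
    missing_sentinel: float | None = None
    transpose: bool = False
    seed: int = 0
    mode: str = "inexact"
    max_state: int | None = None
    hyper_overrides: dict = field(default_factory=dict)

    def load(self) -> ObservedMatrix:
        if isinstance(self.input, ObservedMatrix):
            return self.input
        return read_matrix(self.input, self.dialect, self.missing_sentinel,
                           self.kind, self.transpose)


def run_pipeline(config: RunConfig) -> dict:
    """Fit, postprocess, and write every artifact of a run.

    Writes the recovered matrix ``A`` (rounded for discrete kinds),
    the sparse error ``E``, hard labels, final centers (and clone
    genotypes for discrete data), the cluster tree (edge list, GraphML,
    Newick for rooted discrete trees), the per-iteration objective
    trace, and a JSON manifest capturing parameters, seed, and library
    versions.  Returns a dict of artifact paths plus the in-memory
    state.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs = config.load()
    kind = DataKind(config.kind)
    hyper = select_hyperparams(obs, seed=config.seed, **config.hyper_overrides)
    state = fit(obs, hyper, mode=config.mode)
    model, tree, clone_tree = summarize(state, kind, max_state=config.max_state)

    paths = {k: outdir / v for k, v in {
        "A": "recovered_A.csv", "E": "error_E.csv", "labels": "labels.csv",
        "centers": "centers.csv", "tree_edges": "tree_edges.tsv",
        "tree_graphml": "tree.graphml", "trace": "objective_trace.csv",
        "manifest": "manifest.json",
    }.items()}

    recovered = state.A
    if kind != DataKind.continuous:
        from .postprocess import round_genotypes

        recovered = round_genotypes(state.A, kind, config.max_state)
        paths["clone_genotypes"] = outdir / "clone_genotypes.csv"
        pd.DataFrame(clone_tree.clone_genotypes).to_csv(paths["clone_genotypes"], index=False, header=False)
        paths["newick"] = outdir / "tree.newick"
        write_newick(paths["newick"], tree, clone_tree.root, model.centers)
    write_matrix(paths["A"], recovered, obs.row_names, obs.col_names)
    write_matrix(paths["E"], state.E, obs.row_names, obs.col_names)
    ids = obs.row_names if obs.row_names else [f"cell{i}" for i in range(len(model.labels))]
    pd.DataFrame({"cell_id": ids, "cluster": model.labels}).to_csv(paths["labels"], index=False)
    pd.DataFrame(model.centers).to_csv(paths["centers"], index=False, header=False)
    write_tree_edgelist(paths["tree_edges"], tree, model.centers)
    write_graphml(paths["tree_graphml"], tree, model.centers)
    pd.DataFrame({"iteration": np.arange(1, len(state.objective_trace) + 1),
                  "objective": state.objective_trace,
                  "residual": state.residuals}).to_csv(paths["trace"], index=False)

    import scipy
    import sklearn

    manifest = {
        "seed": config.seed,
        "kind": kind.value,
        "mode": config.mode,
        "hyperparams": {k: v for k, v in dataclasses.asdict(hyper).items() if k != "mu" or v is not None},
        "n_clusters_final": int(model.n_clusters),
        "converged": bool(state.converged),
        "n_iter": int(state.n_iter),
        "versions": {"rpcatree": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "sklearn": sklearn.__version__},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return {"paths": {k: str(v) for k, v in paths.items()}, "state": state,
            "model": model, "tree": tree, "clone_tree": clone_tree}
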