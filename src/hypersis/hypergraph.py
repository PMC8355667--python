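"""Hypergraph data structures, matrices, random generation and file I/O.

A hypergraph is a node set ``{0, ..., n-1}`` together with a list of
hyperedges, each a subset of the nodes.  A partitioned hypergraph
additionally assigns every hyperedge to one of ``K`` categories, each of
which may carry its own infection-response function.

The matrices exposed here are the node-by-hyperedge incidence matrix ``I``,
the co-membership matrix ``W = I @ I.T`` (whose off-diagonal entry ``W[i, j]``
counts hyperedges containing both ``i`` and ``j`` and whose diagonal holds
node degrees), and the weighted-graph Laplacian induced by the off-diagonal
part of ``W``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Hypergraph",
    "PartitionedHypergraph",
    "LaplacianResult",
    "HypergraphError",
    "build_incidence",
    "comembership",
    "partition_comembership",
    "laplacian",
    "random_hypergraph",
    "read_hypergraph",
    "write_hypergraph",
    "max_hyperedge_size",
]


class HypergraphError(ValueError):
    """Structural problem with a hypergraph or one of its hyperedges."""


@dataclass
class Hypergraph:
    """Node set ``{0,...,n-1}`` plus an ordered list of hyperedges.

    Duplicate hyperedges are permitted; they add co-membership weight.
    ``node_labels`` optionally maps external labels to internal indices
    (preserved through file I/O).
    """

    n: int
    hyperedges: list[frozenset[int]]
    node_labels: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise HypergraphError("node count must be positive")
        edges = []
        for pos, h in enumerate(self.hyperedges):
            members = list(h)
            fs = frozenset(members)
            if len(fs) != len(members):
                raise HypergraphError(f"hyperedge {pos} contains duplicate nodes: {sorted(members)}")
            if not fs:
                raise HypergraphError(f"hyperedge {pos} is empty")
            bad = [i for i in fs if not (0 <= i < self.n)]
            if bad:
                raise HypergraphError(
                    f"hyperedge {pos} references node(s) {sorted(bad)} outside 0..{self.n - 1}"
                )
            edges.append(fs)
        self.hyperedges = edges

    @property
    def m(self) -> int:
        """Number of hyperedges."""
        return len(self.hyperedges)

    def labels_for(self, h: frozenset[int]) -> list[str]:
        if self.node_labels is None:
            return [str(i) for i in sorted(h)]
        inv = {v: k for k, v in self.node_labels.items()}
        return [inv[i] for i in sorted(h)]


@dataclass
class PartitionedHypergraph:
    """A hypergraph whose hyperedges are split into categories ``1..K``."""

    base: Hypergraph
    category_of: list[int]
    K: int

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise HypergraphError("K must be positive")
        if len(self.category_of) != self.base.m:
            raise HypergraphError(
                f"{len(self.category_of)} category assignments for {self.base.m} hyperedges"
            )
        for pos, k in enumerate(self.category_of):
            if not (1 <= k <= self.K):
                raise HypergraphError(f"hyperedge {pos} has category {k} outside 1..{self.K}")

    @property
    def n(self) -> int:
        return self.base.n

    def subhypergraph(self, k: int) -> Hypergraph:
        """Hypergraph consisting of only the category-``k`` hyperedges."""
        edges = [h for h, c in zip(self.base.hyperedges, self.category_of) if c == k]
        hg = object.__new__(Hypergraph)
        hg.n = self.base.n
        hg.hyperedges = edges
        hg.node_labels = self.base.node_labels
        return hg


def build_incidence(H: Hypergraph) -> sp.csr_matrix:
    """Return the sparse ``n x m`` incidence matrix with ``I[i, h] = 1``
    iff node ``i`` belongs to hyperedge ``h``."""
    rows, cols = [], []
    for h, members in enumerate(H.hyperedges):
        for i in members:
            rows.append(i)
            cols.append(h)
    data = np.ones(len(rows), dtype=np.float64)
    return sp.csr_matrix((data, (rows, cols)), shape=(H.n, H.m))


def comembership(H: Hypergraph, *, zero_diagonal: bool = False) -> np.ndarray:
    """Co-membership matrix ``W = I @ I.T`` (dense, symmetric, integer-valued).

    ``W[i, j]`` is the number of hyperedges containing both ``i`` and ``j``;
    the diagonal holds node degrees.  ``zero_diagonal=True`` returns the
    off-diagonal part, for comparison with the classic adjacency model.
    """
    I = build_incidence(H)
    W = (I @ I.T).toarray()
    if zero_diagonal:
        np.fill_diagonal(W, 0.0)
    return W


def partition_comembership(PH: PartitionedHypergraph) -> list[np.ndarray]:
    """Per-category co-membership matrices ``(W^(1), ..., W^(K))``.

    Their elementwise sum equals ``comembership(PH.base)``; an empty
    category yields a zero matrix in its slot.
    """
    n = PH.n
    out = []
    for k in range(1, PH.K + 1):
        sub = PH.subhypergraph(k)
        if sub.m == 0:
            out.append(np.zeros((n, n)))
        else:
            out.append(comembership(sub))
    return out


@dataclass
class LaplacianResult:
    """Weighted-graph Laplacian of the co-membership structure.

    ``matrix`` is ``D - W_off`` where ``W_off`` is ``W`` with its diagonal
    removed and ``D`` holds the off-diagonal row sums.  ``lambda_c`` is the
    smallest eigenvalue exceeding the zero tolerance (the algebraic
    connectivity for a connected structure) and ``n_zero`` counts numerically
    zero eigenvalues, which equals the number of connected components.
    """

    matrix: np.ndarray
    lambda_c: float
    n_zero: int
    eigenvalues: np.ndarray = field(repr=False, default=None)


def laplacian(H: Hypergraph, zero_tolerance: float = 1e-8) -> LaplacianResult:
    """Laplacian ``D - W_off`` of the weighted graph induced by W's
    off-diagonal part, with its null-space diagnostics.

    ``zero_tolerance`` is relative to the largest eigenvalue magnitude.
    """
    if H.n == 0:
        raise HypergraphError("empty node set")
    W_off = comembership(H, zero_diagonal=True)
    D = np.diag(W_off.sum(axis=1))
    delta = D - W_off
    evals = np.linalg.eigvalsh(delta)
    scale = max(abs(evals[-1]), 1.0)
    zero_mask = np.abs(evals) <= zero_tolerance * scale
    nonzero = evals[~zero_mask]
    lam_c = float(nonzero[0]) if nonzero.size else 0.0
    return LaplacianResult(matrix=delta, lambda_c=lam_c, n_zero=int(zero_mask.sum()), eigenvalues=evals)


def component_count(H: Hypergraph) -> int:
    """Connected components of the graph supported on W's off-diagonal part."""
    W_off = comembership(H, zero_diagonal=True)
    ncomp, _ = connected_components(sp.csr_matrix(W_off), directed=False)
    return int(ncomp)


def random_hypergraph(
    n: int,
    counts_by_size: dict[int, int],
    seed: int | np.random.Generator,
    *,
    partition_by_size: bool = False,
) -> Hypergraph | PartitionedHypergraph:
    """Draw hyperedges as independent uniform subsets, grouped by size.

    For each ``(size, count)`` pair, ``count`` hyperedges are drawn, each a
    uniformly random ``size``-subset of the nodes (no duplicate nodes within
    a hyperedge; duplicate hyperedges across draws are allowed).  With
    ``partition_by_size=True``, size-``s`` hyperedges get category ``s - 1``,
    so pairwise edges form category 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = sorted(counts_by_size)
    for s in sizes:
        if s < 2:
            raise HypergraphError(f"hyperedge size {s} < 2 rejected by the generator")
        if s > n:
            raise HypergraphError(f"hyperedge size {s} exceeds node count {n}")
        if counts_by_size[s] < 0:
            raise HypergraphError(f"negative count for size {s}")
    edges: list[frozenset[int]] = []
    cats: list[int] = []
    for s in sizes:
        for _ in range(counts_by_size[s]):
            edges.append(frozenset(rng.choice(n, size=s, replace=False).tolist()))
            cats.append(s - 1)
    H = Hypergraph(n=n, hyperedges=edges)
    if partition_by_size:
        K = max(cats) if cats else 1
        return PartitionedHypergraph(base=H, category_of=cats, K=K)
    return H


def max_hyperedge_size(H: Hypergraph) -> int:
    """Size ``e_max`` of the largest hyperedge."""
    if H.m == 0:
        raise HypergraphError("hypergraph has no hyperedges")
    return max(len(h) for h in H.hyperedges)


# ---------------------------------------------------------------------------
# File I/O
#
# Text dialect: one hyperedge per line, whitespace-separated node labels,
# optional trailing "#k" category token.  JSON dialect carries n, labelled
# hyperedges and categories explicitly.
# ---------------------------------------------------------------------------


class ParseError(ValueError):
    pass


def _as_partitioned(H, cats, any_cat):
    if not any_cat:
        return H
    K = max(cats)
    return PartitionedHypergraph(base=H, category_of=cats, K=K)


def read_hypergraph(path: str, fmt: str = "text"):
    """Read a hypergraph (returns :class:`PartitionedHypergraph` when the
    file carries categories, else :class:`Hypergraph`).

    Unknown labels are assigned fresh indices in order of first appearance.
    Size-1 hyperedges are tolerated with a warning (they contribute only
    diagonal co-membership weight).
    """
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        labels = {lab: i for i, lab in enumerate(doc["nodes"])}
        edges, cats, any_cat = [], [], False
        for rec in doc["hyperedges"]:
            members = [labels[x] for x in rec["nodes"]]
            if len(set(members)) != len(members):
                raise ParseError(f"duplicate node in hyperedge {rec['nodes']}")
            edges.append(frozenset(members))
            k = rec.get("category")
            any_cat = any_cat or k is not None
            cats.append(1 if k is None else int(k))
        H = Hypergraph(n=int(doc["n"]), hyperedges=edges, node_labels=labels)
        return _as_partitioned(H, cats, any_cat)
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    lines, cats, any_cat = [], [], False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            toks = line.split()
            cat = 1
            if toks[-1].startswith("#"):
                try:
                    cat = int(toks[-1][1:])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: bad category token {toks[-1]!r}") from exc
                any_cat = True
                toks = toks[:-1]
            if not toks:
                raise ParseError(f"line {lineno}: no nodes")
            if len(set(toks)) != len(toks):
                raise ParseError(f"line {lineno}: duplicate node in hyperedge {toks}")
            if len(toks) == 1:
                warnings.warn(f"line {lineno}: size-1 hyperedge (adds only diagonal weight)")
            lines.append(toks)
            cats.append(cat)
    if not lines:
        raise ParseError("no hyperedges found")
    all_toks = [t for toks in lines for t in toks]
    if all(t.isdigit() for t in all_toks):
        # integer dialect: tokens ARE node indices (exact round-trip with
        # the default writer, up to isolated trailing nodes)
        edges = [frozenset(int(t) for t in toks) for toks in lines]
        n = max(all_toks, key=int)
        H = Hypergraph(n=int(n) + 1, hyperedges=edges)
    else:
        labels: dict[str, int] = {}
        for toks in lines:
            for t in toks:
                labels.setdefault(t, len(labels))
        edges = [frozenset(labels[t] for t in toks) for toks in lines]
        H = Hypergraph(n=len(labels), hyperedges=edges, node_labels=labels)
    return _as_partitioned(H, cats, any_cat)


def write_hypergraph(H: Hypergraph | PartitionedHypergraph, path: str, fmt: str = "text") -> None:
    """Write a hypergraph; round-trips with :func:`read_hypergraph`."""
    base = H.base if isinstance(H, PartitionedHypergraph) else H
    cats = H.category_of if isinstance(H, PartitionedHypergraph) else None
    if fmt == "json":
        if base.node_labels is not None:
            inv = {v: k for k, v in base.node_labels.items()}
            nodes = [inv[i] for i in range(base.n)]
        else:
            nodes = [str(i) for i in range(base.n)]
        recs = []
        for pos, h in enumerate(base.hyperedges):
            rec = {"nodes": [nodes[i] for i in sorted(h)]}
            if cats is not None:
                rec["category"] = cats[pos]
            recs.append(rec)
        with open(path, "w") as fh:
            json.dump({"n": base.n, "nodes": nodes, "hyperedges": recs}, fh, indent=1)
        return
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        for pos, h in enumerate(base.hyperedges):
            toks = base.labels_for(h)
            if cats is not None:
                toks.append(f"#{cats[pos]}")
            fh.write(" ".join(toks) + "\n")


def write_sparse_coo(M, path: str) -> None:
    """Export any matrix as 0-based ``row col value`` text."""
    coo = sp.coo_matrix(M)
    with open(path, "w") as fh:
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {v:.17g}\n")
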