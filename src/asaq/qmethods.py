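"""Weighted quartet amalgamation: WO, QP and Willson-style tree building.

All three builders grow an unrooted binary tree by greedy taxon insertion,
differing in how the next step is chosen:

* WO (weight optimization) dynamically picks the (taxon, edge) pair that
  maximizes the added quartet weight, so the taxon addition order is driven by
  the weights themselves.
* QP (quartet puzzling) inserts taxa in a random order, choosing for each the
  edge that maximizes the same weight sum.
* WIL inserts the (taxon, edge) pair maximizing the number of quartets whose
  highest-weight split is displayed by the candidate tree (a consistency
  count rather than a weight sum).

Because the output depends on the random initial quartet (and order), each
builder is replicated and summarized by a majority-rule consensus tree, as
in standard practice.  Consensus, Robinson-Foulds distances and neighbor
joining are delegated to DendroPy.
"""

from __future__ import annotations

import io
import itertools
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

import dendropy
from dendropy.calculate import treecompare

from .algebraic import quartet_weights
from .errors import MissingWeightError, UndefinedDistanceError
from .paralinear import paralinear_distance
from .patterns import Alignment, SitePatternDistribution, pattern_counts

_CANONICAL_PAIRS = ((0, 1), (0, 2), (0, 3))  # partner of the smallest taxon


def canonical_split_index(quartet: Sequence[str], pair: tuple[str, str]) -> int:
    """Index (0..2) of the split pairing ``pair`` within a sorted quartet.

    Splits of the sorted quartet (a, b, c, d) are ordered ab|cd, ac|bd, ad|bc.
    """
    q = list(quartet)
    a = q[0]
    if a in pair:
        partner = pair[0] if pair[1] == a else pair[1]
    else:
        rest = [t for t in q if t not in pair]
        partner = rest[0] if rest[1] == a else rest[1]
    return q[1:].index(partner)


class QuartetWeightTable:
    """Map from 4-subsets of taxa to normalized weights over their three splits.

    Weights are stored relative to the sorted order of the four labels
    (splits ab|cd, ac|bd, ad|bc).
    """

    def __init__(self, taxa: Iterable[str]):
        self.taxa = sorted(taxa)
        self._weights: dict[tuple, np.ndarray] = {}
        self._meta: dict[tuple, tuple[str, str]] = {}

    @staticmethod
    def key(quartet: Sequence[str]) -> tuple:
        return tuple(sorted(quartet))

    def set_weights(self, quartet, weights, method: str = "", tag: str = "") -> None:
        k = self.key(quartet)
        w = np.asarray(weights, dtype=float)
        if w.shape != (3,):
            raise ValueError("expected three split weights")
        self._weights[k] = w
        self._meta[k] = (method, tag)

    def get(self, quartet) -> np.ndarray:
        k = self.key(quartet)
        try:
            return self._weights[k]
        except KeyError:
            raise MissingWeightError(f"no weights for quartet {k}") from None

    def __len__(self) -> int:
        return len(self._weights)

    def __contains__(self, quartet) -> bool:
        return self.key(quartet) in self._weights

    def items(self):
        return self._weights.items()

    def meta(self, quartet) -> tuple[str, str]:
        return self._meta.get(self.key(quartet), ("", ""))

    # -- transformations ----------------------------------------------------

    def binarize(self) -> "QuartetWeightTable":
        """0/1 weights: the argmax split gets 1 (ties break in canonical order)."""
        out = QuartetWeightTable(self.taxa)
        for k, w in self._weights.items():
            b = np.zeros(3)
            b[int(np.argmax(w))] = 1.0
            out.set_weights(k, b, *self._meta.get(k, ("", "")))
        return out

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = [
            (*k, *w, *self._meta.get(k, ("", "")))
            for k, w in sorted(self._weights.items())
        ]
        df = pd.DataFrame(
            rows,
            columns=["tax1", "tax2", "tax3", "tax4", "w_12|34", "w_13|24", "w_14|23", "method", "tag"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "QuartetWeightTable":
        df = pd.read_csv(path, sep="\t", dtype={f"tax{i}": str for i in (1, 2, 3, 4)})
        taxa = set()
        for col in ("tax1", "tax2", "tax3", "tax4"):
            taxa.update(df[col].astype(str))
        table = cls(taxa)
        for row in df.itertuples(index=False):
            table.set_weights(
                (str(row.tax1), str(row.tax2), str(row.tax3), str(row.tax4)),
                (row[4], row[5], row[6]),
                method=str(getattr(row, "method", "")),
                tag=str(getattr(row, "tag", "")),
            )
        return table

    def to_wqfm(self, path) -> None:
        """Export one weighted quartet newick per line (wQFM input format)."""
        with open(path, "w") as fh:
            for (a, b, c, d), w in sorted(self._weights.items()):
                fh.write(f"(({a},{b}),({c},{d})); {w[0]:.6g}\n")
                fh.write(f"(({a},{c}),({b},{d})); {w[1]:.6g}\n")
                fh.write(f"(({a},{d}),({b},{c})); {w[2]:.6g}\n")

    # -- reference tables ----------------------------------------------------

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "QuartetWeightTable":
        """Correctly weighted 0/1 table: weight 1 on each split the tree displays."""
        labels, D = topological_leaf_distances(tree)
        table = cls(labels)
        idx = {t: i for i, t in enumerate(labels)}
        for quartet in itertools.combinations(labels, 4):
            a, b, c, d = (idx[t] for t in quartet)
            sums = (D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c])
            w = np.zeros(3)
            w[int(np.argmin(sums))] = 1.0
            table.set_weights(quartet, w, method="tree")
        return table


def compute_weight_table(
    aln: Alignment,
    method: str = "asaq",
    m: int = 1,
    quartets: Iterable[Sequence[str]] | None = None,
) -> QuartetWeightTable:
    """Weight every 4-subset of an alignment's taxa (or a supplied subset)."""
    codes = aln.codes()
    row = {t: codes[i] for i, t in enumerate(aln.taxa)}
    table = QuartetWeightTable(aln.taxa)
    quartets = (
        itertools.combinations(sorted(aln.taxa), 4) if quartets is None else quartets
    )
    for quartet in quartets:
        q = tuple(sorted(quartet))
        counts = pattern_counts(np.vstack([row[t] for t in q]))
        p = SitePatternDistribution(taxa=q, values=counts / counts.sum(), n_sites=int(counts.sum()))
        w, tag = quartet_weights(p, method=method, m=m)
        table.set_weights(q, w.weights, method=method, tag=tag)
    return table


# ---------------------------------------------------------------------------
# growing-tree machinery
# ---------------------------------------------------------------------------

class _GrowingTree:
    """Mutable unrooted tree used during greedy insertion."""

    def __init__(self):
        self.adj: dict[int, set[int]] = defaultdict(set)
        self.taxon: dict[int, str] = {}
        self._next = 0

    def new_node(self, taxon: str | None = None) -> int:
        n = self._next
        self._next += 1
        self.adj[n] = set()
        if taxon is not None:
            self.taxon[n] = taxon
        return n

    def add_edge(self, u: int, v: int) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def insert_leaf(self, taxon: str, edge: tuple[int, int]) -> int:
        u, v = edge
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        w = self.new_node()
        self.add_edge(u, w)
        self.add_edge(w, v)
        leaf = self.new_node(taxon)
        self.add_edge(w, leaf)
        return leaf

    def node_distances(self) -> dict[int, dict[int, float]]:
        """All-pairs topological distances by BFS (the tree is tiny)."""
        dist = {}
        for src in self.adj:
            d = {src: 0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v in self.adj[u]:
                    if v not in d:
                        d[v] = d[u] + 1
                        stack.append(v)
            dist[src] = d
        return dist

    def newick(self) -> str:
        internal = [n for n in self.adj if n not in self.taxon]
        root = internal[0] if internal else next(iter(self.adj))

        def sub(node, parent):
            children = [v for v in self.adj[node] if v != parent]
            if not children:
                return self.taxon[node]
            return "(" + ",".join(sub(c, node) for c in children) + ")"

        return sub(root, None) + ";"


def _initial_quartet(table: QuartetWeightTable, taxa: list[str], rng) -> tuple[_GrowingTree, list[str]]:
    pick = sorted(rng.choice(len(taxa), size=4, replace=False))
    quartet = [taxa[i] for i in pick]
    w = table.get(quartet)
    split = int(np.argmax(w))
    a, b, c, d = quartet
    pairs = {0: ((a, b), (c, d)), 1: ((a, c), (b, d)), 2: ((a, d), (b, c))}[split]
    tree = _GrowingTree()
    u = tree.new_node()
    v = tree.new_node()
    tree.add_edge(u, v)
    for t in pairs[0]:
        leaf = tree.new_node(t)
        tree.add_edge(u, leaf)
    for t in pairs[1]:
        leaf = tree.new_node(t)
        tree.add_edge(v, leaf)
    return tree, quartet


def _step_arrays(tree: _GrowingTree):
    """Distances and triple indexing shared by all candidate insertions."""
    dist = tree.node_distances()
    nodes = sorted(tree.adj)
    pos = {n: i for i, n in enumerate(nodes)}
    D = np.array([[dist[u].get(v, np.inf) for v in nodes] for u in nodes], dtype=float)
    leaves = sorted(tree.taxon.items(), key=lambda kv: kv[1])  # (node, label)
    leaf_nodes = np.array([pos[n] for n, _ in leaves])
    labels = [lab for _, lab in leaves]
    triples = list(itertools.combinations(range(len(labels)), 3))
    I = np.array([t[0] for t in triples], dtype=np.intp)
    J = np.array([t[1] for t in triples], dtype=np.intp)
    K = np.array([t[2] for t in triples], dtype=np.intp)
    Dl = D[np.ix_(leaf_nodes, leaf_nodes)]
    return {
        "nodes": nodes,
        "pos": pos,
        "D": D,
        "leaf_nodes": leaf_nodes,
        "labels": labels,
        "I": I,
        "J": J,
        "K": K,
        "S_jk": Dl[J, K],
        "S_ik": Dl[I, K],
        "S_ij": Dl[I, J],
    }


def _taxon_weight_arrays(table: QuartetWeightTable, labels: list[str], x: str, arrays):
    """Per-triple weights in x-pairing order (x with i / j / k) and the
    x-pairing index of each quartet's argmax split."""
    I, J, K = arrays["I"], arrays["J"], arrays["K"]
    n = len(I)
    W = np.empty((n, 3))
    top = np.empty(n, dtype=np.intp)
    for t in range(n):
        li, lj, lk = labels[I[t]], labels[J[t]], labels[K[t]]
        q = tuple(sorted((x, li, lj, lk)))
        w = table.get(q)
        ci = canonical_split_index(q, (x, li))
        cj = canonical_split_index(q, (x, lj))
        ck = canonical_split_index(q, (x, lk))
        W[t, 0] = w[ci]
        W[t, 1] = w[cj]
        W[t, 2] = w[ck]
        c_arg = int(np.argmax(w))
        top[t] = (ci, cj, ck).index(c_arg)
    return W, top


def _edge_scores(tree, arrays, W, top_argmax, mode: str) -> dict[tuple[int, int], float]:
    """Score every candidate insertion edge for one unplaced taxon."""
    pos = arrays["pos"]
    D = arrays["D"]
    leaf_nodes = arrays["leaf_nodes"]
    I, J, K = arrays["I"], arrays["J"], arrays["K"]
    scores = {}
    ar = np.arange(len(I))
    for u, v in tree.edges():
        dx = np.minimum(D[pos[u], leaf_nodes], D[pos[v], leaf_nodes]) + 0.5
        s = np.stack(
            (dx[I] + arrays["S_jk"], dx[J] + arrays["S_ik"], dx[K] + arrays["S_ij"])
        )
        induced = np.argmin(s, axis=0)
        if mode == "weight":
            scores[(u, v)] = float(W[ar, induced].sum())
        else:  # consistency count
            scores[(u, v)] = float((induced == top_argmax).sum())
    return scores


def _argmax_random(options: list, scores: list[float], rng) -> object:
    best = max(scores)
    ties = [o for o, s in zip(options, scores) if s >= best - 1e-12]
    return ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]


def _greedy_build(table, rng, mode: str, dynamic_order: bool) -> str:
    taxa = list(table.taxa)
    if len(taxa) < 4:
        raise ValueError("need at least four taxa")
    tree, placed = _initial_quartet(table, taxa, rng)
    remaining = [t for t in taxa if t not in placed]
    if not dynamic_order:
        remaining = [remaining[i] for i in rng.permutation(len(remaining))]
    while remaining:
        arrays = _step_arrays(tree)
        labels = arrays["labels"]
        if dynamic_order:
            candidates, cand_scores = [], []
            for x in remaining:
                W, top = _taxon_weight_arrays(table, labels, x, arrays)
                es = _edge_scores(tree, arrays, W, top, mode)
                for e, s in es.items():
                    candidates.append((x, e))
                    cand_scores.append(s)
            x, edge = _argmax_random(candidates, cand_scores, rng)
        else:
            x = remaining[0]
            W, top = _taxon_weight_arrays(table, labels, x, arrays)
            es = _edge_scores(tree, arrays, W, top, mode)
            edges = list(es)
            edge = _argmax_random(edges, [es[e] for e in edges], rng)
        tree.insert_leaf(x, edge)
        remaining.remove(x)
    return tree.newick()


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def wo_build(table: QuartetWeightTable, seed=None) -> dendropy.Tree:
    """Weight optimization: dynamic taxon order maximizing added quartet weight."""
    nwk = _greedy_build(table, _as_rng(seed), mode="weight", dynamic_order=True)
    return dendropy.Tree.get(data=nwk, schema="newick")


def qp_build(table: QuartetWeightTable, seed=None) -> dendropy.Tree:
    """Quartet puzzling: random insertion order, best edge by quartet weight."""
    nwk = _greedy_build(table, _as_rng(seed), mode="weight", dynamic_order=False)
    return dendropy.Tree.get(data=nwk, schema="newick")


def wil_build(table: QuartetWeightTable, seed=None) -> dendropy.Tree:
    """Willson-style insertion maximizing the count of displayed argmax quartets."""
    nwk = _greedy_build(table, _as_rng(seed), mode="consistency", dynamic_order=True)
    return dendropy.Tree.get(data=nwk, schema="newick")


_BUILDERS = {"wo": ("weight", True), "qp": ("weight", False), "wil": ("consistency", True)}


def run_and_consense(
    method: str, table: QuartetWeightTable, n_replicates: int = 100, seed=None
) -> dendropy.Tree:
    """Majority-rule consensus (> 50%) of replicate greedy builds."""
    if method not in _BUILDERS:
        raise ValueError(f"unknown build method: {method!r}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _as_rng(seed)
    mode, dynamic = _BUILDERS[method]
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=tns)
    for _ in range(n_replicates):
        nwk = _greedy_build(table, rng, mode=mode, dynamic_order=dynamic)
        trees.append(dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns))
    cons = trees.consensus(min_freq=0.5 + 1e-9)
    cons.is_rooted = False
    return cons


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _to_newick(t) -> str:
    if isinstance(t, dendropy.Tree):
        return t.as_string(schema="newick", suppress_rooting=True)
    return str(t)


def rf_distance(t1, t2) -> int:
    """Robinson-Foulds distance: symmetric difference of internal bipartitions."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=_to_newick(t1), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=_to_newick(t2), schema="newick", taxon_namespace=tns)
    la = {leaf.taxon.label for leaf in a.leaf_node_iter()}
    lb = {leaf.taxon.label for leaf in b.leaf_node_iter()}
    if la != lb:
        raise ValueError("trees have different leaf sets")
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def normalized_rf(t1, t2) -> float:
    """RF divided by the total number of internal edges of the two trees."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=_to_newick(t1), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=_to_newick(t2), schema="newick", taxon_namespace=tns)
    a.is_rooted = False
    b.is_rooted = False

    def n_internal(t):
        return sum(
            1
            for e in t.preorder_edge_iter()
            if e.head_node.parent_node is not None and not e.head_node.is_leaf()
        )

    denom = n_internal(a) + n_internal(b)
    return rf_distance(t1, t2) / denom if denom else 0.0


def topological_leaf_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Sorted leaf labels and their pairwise path lengths in edge counts."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in pdm.taxon_iter())
    by_label = {t.label: t for t in pdm.taxon_iter()}
    n = len(labels)
    D = np.zeros((n, n))
    for i, li in enumerate(labels):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.path_edge_count(by_label[li], by_label[labels[j]])
    return labels, D


def paralinear_distance_matrix(aln: Alignment) -> tuple[list[str], np.ndarray]:
    """Pairwise paralinear distances for all taxa of an alignment.

    Columns with non-ACGT symbols are dropped per pair.  Raises
    :class:`UndefinedDistanceError` if any pairwise distance is undefined.
    """
    codes = aln.codes()
    n = len(aln.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] < 4) & (codes[j] < 4)
            if not ok.any():
                raise UndefinedDistanceError(f"no shared sites for {aln.taxa[i]}, {aln.taxa[j]}")
            idx = codes[i, ok].astype(np.intp) * 4 + codes[j, ok].astype(np.intp)
            J = np.bincount(idx, minlength=16).reshape(4, 4).astype(float)
            d = paralinear_distance(J / J.sum())
            if np.isnan(d):
                raise UndefinedDistanceError(
                    f"paralinear distance undefined for {aln.taxa[i]}, {aln.taxa[j]}"
                )
            D[i, j] = D[j, i] = d
    return list(aln.taxa), D


def write_phylip_distances(labels: Sequence[str], D: np.ndarray, path) -> None:
    """Write a distance matrix in PHYLIP square format (for external NJ tools)."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, D):
            fh.write(f"{lab:<10s} " + " ".join(f"{x:.6f}" for x in row) + "\n")


def nj_paralinear(aln: Alignment) -> dendropy.Tree:
    """Neighbor joining on the pairwise paralinear distance matrix."""
    if len(aln.taxa) < 4:
        raise ValueError("need at least four taxa")
    labels, D = paralinear_distance_matrix(aln)
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{x:.10f}" for x in D[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    tree = pdm.nj_tree()
    tree.is_rooted = False
    return tree


def binarize_weights(table: QuartetWeightTable) -> QuartetWeightTable:
    """Functional alias for :meth:`QuartetWeightTable.binarize`."""
    return table.binarize()
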