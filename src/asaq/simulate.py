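"""Sequence simulation under the general Markov (GM) and homogeneous GTR models.

GM alignments evolve on a rooted tree with an arbitrary root distribution and
an independent row-stochastic transition matrix on every edge; the model is
non-stationary, non-reversible and heterogeneous across lineages.  Branch
lengths are expected substitutions per site, realized through the determinant
convention det M_e = exp(-4 * l_e).  Sampled matrices are
diagonal-largest-in-column/row (DLC) for identifiability.

The module also builds the benchmark tree families used to exercise the
quartet methods: the (a, b) quartet tree space with its Felsenstein zone,
quartets with uniformly random branch lengths, two-category same-topology
quartet mixtures, and the three 12-taxon topologies CC, CD and DD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm


import dendropy

from .algebraic import quartet_weights
from .patterns import Alignment, SitePatternDistribution, pattern_counts

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# GM transition-matrix sampling
# ---------------------------------------------------------------------------

def _is_dlc(M: np.ndarray, tol: float = 1e-12) -> bool:
    off = M - np.diag(np.diag(M))
    return bool(np.all(np.diag(M) >= off.max(axis=1) - tol))


def sample_gm_matrix(length: float, rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
    """Random 4x4 row-stochastic DLC matrix with det M = exp(-4 * length).

    The matrix is the product of two matrix exponentials of independent random
    rate matrices (off-diagonal rates i.i.d. exponential) whose time spans
    split the branch length at a random proportion.  Since det expm(tQ) =
    exp(t tr Q), each factor's time is chosen so the product determinant
    equals exp(-4 length) exactly.  Products of two exponentials are generally
    not embeddable in a single continuous-time process, so the draws genuinely
    exercise the general Markov model; at the same time every eigenmode decays
    at its own rate, so long branches lose signal heterogeneously and converge
    to factor-specific compositions.  (A single convex-path construction that
    damps all contrasts simultaneously was found to manufacture long-branch
    attraction far beyond what matched continuous-time controls show.)
    Non-DLC products are rejected and resampled.  Because rows of a saturated
    matrix approach its stationary composition, the DLC constraint forces long
    branches toward uniform-stationary behaviour; retries therefore blend the
    off-diagonal rates toward their symmetrized (hence uniform-stationary)
    version, which restores DLC feasibility at any length while preserving the
    random decay spectrum.
    """
    if length < 0:
        raise ValueError("branch length must be non-negative")
    if length == 0:
        return np.eye(4)
    for attempt in range(max_tries):
        gamma = min(1.0, 4.0 * attempt / max_tries)  # symmetrize rates if DLC is hard
        w = rng.dirichlet(np.ones(2))
        parts = []
        for k in range(2):
            Q = rng.exponential(1.0, (4, 4))
            np.fill_diagonal(Q, 0.0)
            Q = (1.0 - gamma) * Q + gamma * 0.5 * (Q + Q.T)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            t = 4.0 * length * w[k] / (-np.trace(Q))
            parts.append(expm(t * Q))
        M = parts[0] @ parts[1]
        if _is_dlc(M):
            return M
    raise RuntimeError(f"could not sample a DLC matrix for length {length:g}")


# ---------------------------------------------------------------------------
# GTR model
# ---------------------------------------------------------------------------

@dataclass
class GTRModel:
    """Homogeneous general time-reversible model.

    Exchangeabilities are ordered (AC, AG, AT, CG, CT, GT).  The rate matrix
    is normalized so one unit of branch length is one expected substitution
    per site at stationarity.
    """

    exchangeabilities: Sequence[float]
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    Q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_freqs, dtype=float)
        if s.shape != (6,) or pi.shape != (4,):
            raise ValueError("need 6 exchangeabilities and 4 base frequencies")
        pi = pi / pi.sum()
        Q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for rate, (i, j) in zip(s, pairs):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        self.Q = Q / mu
        self.base_freqs = pi

    def transition(self, t: float) -> np.ndarray:
        """Row-stochastic transition matrix after branch length t."""
        return expm(self.Q * t)


#: GTR rates used for the 12-taxon GTR benchmark: instantaneous rates
#: 2 (A->C), 5 (A->G), 3 (A->T), 4 (C->G), 1 (C->T), 2 (G->T), equal freqs.
BENCHMARK_GTR = (2.0, 5.0, 3.0, 4.0, 1.0, 2.0)


# ---------------------------------------------------------------------------
# GM instances on trees
# ---------------------------------------------------------------------------

@dataclass
class GMInstance:
    """A rooted tree with a root distribution and per-edge transition matrices."""

    edges: list  # (parent, child, M, length) in preorder
    n_nodes: int
    root: int
    root_dist: np.ndarray
    leaf_labels: dict  # node index -> taxon label

    def __post_init__(self) -> None:
        for _, _, M, length in self.edges:
            if np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError("edge matrices must be row-stochastic")

    @property
    def taxa(self) -> list[str]:
        """Leaf labels in sorted order (the row order of simulated alignments)."""
        return sorted(self.leaf_labels.values())

    @classmethod
    def from_tree(
        cls,
        tree: dendropy.Tree,
        rng: np.random.Generator,
        model: GTRModel | None = None,
        root_dist: np.ndarray | None = None,
    ) -> "GMInstance":
        """Dress a dendropy tree (with branch lengths) with GM or GTR matrices.

        Under GM every edge gets an independent random DLC matrix with the
        determinant fixed by its length, and the root distribution defaults to
        a uniform draw from the simplex.  With a :class:`GTRModel` the edge
        matrices are expm(l * Q) and the root sits at the stationary
        distribution.
        """
        index = {}
        edges = []
        leaf_labels = {}
        counter = itertools.count()
        for node in tree.preorder_node_iter():
            idx = next(counter)
            index[node] = idx
            if node.is_leaf():
                leaf_labels[idx] = node.taxon.label
            if node.parent_node is not None:
                length = float(node.edge.length or 0.0)
                M = (
                    model.transition(length)
                    if model is not None
                    else sample_gm_matrix(length, rng)
                )
                edges.append((index[node.parent_node], idx, M, length))
        if root_dist is None:
            root_dist = (
                np.asarray(model.base_freqs) if model is not None else rng.dirichlet(np.ones(4))
            )
        return cls(
            edges=edges,
            n_nodes=next(counter),
            root=0,
            root_dist=np.asarray(root_dist, dtype=float),
            leaf_labels=leaf_labels,
        )

    # -- simulation ---------------------------------------------------------

    def simulate_codes(self, n_sites: int, rng: np.random.Generator) -> np.ndarray:
        """(n_leaves, n_sites) uint8 matrix of i.i.d. columns, rows in taxon order."""
        if n_sites < 1:
            raise ValueError("n_sites must be positive")
        states = np.empty((self.n_nodes, n_sites), dtype=np.uint8)
        cum_root = np.cumsum(self.root_dist)
        states[self.root] = np.searchsorted(cum_root, rng.random(n_sites), side="right").astype(np.uint8)
        for parent, child, M, _ in self.edges:
            cum = np.cumsum(M, axis=1)
            cum[:, -1] = 1.0
            r = rng.random(n_sites)
            states[child] = (r[:, None] > cum[states[parent]]).sum(axis=1).astype(np.uint8)
        leaf_nodes = sorted(self.leaf_labels)
        order = np.argsort([self.leaf_labels[n] for n in leaf_nodes], kind="stable")
        return states[np.asarray(leaf_nodes)[order]]

    def simulate_alignment(self, n_sites: int, rng: np.random.Generator) -> Alignment:
        codes = self.simulate_codes(n_sites, rng)
        rows = [_ACGT[c].tobytes().decode("ascii") for c in codes]
        return Alignment(taxa=self.taxa, rows=rows, length=n_sites)

    # -- exact distributions ------------------------------------------------

    def exact_leaf_distribution(self) -> np.ndarray:
        """Exact joint leaf distribution by tensor contraction (small trees only)."""
        if len(self.leaf_labels) > 6:
            raise ValueError("exact contraction supported for at most 6 leaves")
        letters = "abcdefghijklmnopqrstuvwxyz"
        sub_in = [letters[self.root]]
        ops = [self.root_dist]
        for parent, child, M, _ in self.edges:
            sub_in.append(letters[parent] + letters[child])
            ops.append(M)
        leaf_nodes = sorted(self.leaf_labels)
        order = np.argsort([self.leaf_labels[n] for n in leaf_nodes], kind="stable")
        out = "".join(letters[n] for n in np.asarray(leaf_nodes)[order])
        return np.einsum(",".join(sub_in) + "->" + out, *ops, optimize=True)

    def exact_quartet_distribution(self) -> SitePatternDistribution:
        t = self.exact_leaf_distribution()
        if t.ndim != 4:
            raise ValueError("instance does not have exactly four leaves")
        values = t.reshape(256)
        return SitePatternDistribution(
            taxa=tuple(self.taxa), values=values / values.sum(), n_sites=1
        )

    def node_marginal(self, node: int) -> np.ndarray:
        """Marginal state distribution at a node (root distribution propagated)."""
        pi = {self.root: self.root_dist}
        for parent, child, M, _ in self.edges:
            pi[child] = pi[parent] @ M
        return pi[node]

    def node_pair_joint(self, parent: int, child: int) -> np.ndarray:
        """Exact joint distribution of a parent/child node pair."""
        for p_, c_, M, _ in self.edges:
            if (p_, c_) == (parent, child):
                return np.diag(self.node_marginal(parent)) @ M
        raise KeyError((parent, child))


def gm_quartet(
    pendants: Sequence[float],
    interior: float,
    rng: np.random.Generator,
    labels: Sequence[str] = ("1", "2", "3", "4"),
) -> GMInstance:
    """GM instance on the quartet 12|34, rooted at the interior node joining 1 and 2.

    Node layout: 0 = root (adjacent to leaves 1, 2), 5 = the other interior
    node (adjacent to leaves 3, 4); ``interior`` is the length of edge 0-5.
    """
    l1, l2, l3, l4 = pendants
    edges = []
    for parent, child, length in [
        (0, 1, l1),
        (0, 2, l2),
        (0, 5, interior),
        (5, 3, l3),
        (5, 4, l4),
    ]:
        edges.append((parent, child, sample_gm_matrix(length, rng), length))
    return GMInstance(
        edges=edges,
        n_nodes=6,
        root=0,
        root_dist=rng.dirichlet(np.ones(4)),
        leaf_labels={1: labels[0], 2: labels[1], 3: labels[2], 4: labels[3]},
    )


def huelsenbeck_quartet(
    a: float, b: float, rng: np.random.Generator, interior: float | None = None
) -> GMInstance:
    """Quartet from the (a, b) tree space: leaves 1 and 3 (opposite sides of
    the interior edge) have pendant length a; leaves 2 and 4 and the interior
    edge have length b.  Large a with small b is the Felsenstein zone."""
    return gm_quartet((a, b, a, b), b if interior is None else interior, rng)


def mixture_distribution(
    instances: Sequence[GMInstance], proportions: Sequence[float]
) -> SitePatternDistribution:
    """Exact pattern distribution of a same-tree mixture."""
    props = np.asarray(proportions, dtype=float)
    if np.any(props <= 0) or abs(props.sum() - 1.0) > 1e-12:
        raise ValueError("proportions must be positive and sum to 1")
    values = sum(
        w * inst.exact_quartet_distribution().values for w, inst in zip(props, instances)
    )
    return SitePatternDistribution(
        taxa=instances[0].exact_quartet_distribution().taxa, values=values, n_sites=1
    )


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _success(p: SitePatternDistribution, method: str, m: int, truth: str = "12|34"):
    w, tag = quartet_weights(p, method, m)
    return (tag != "undefined" and w.topology == truth), w, tag


def random_quartet_experiment(
    interval: tuple[float, float],
    n_align: int,
    n_sites: int,
    rng: np.random.Generator,
    method: str = "asaq",
    m: int = 1,
    model: GTRModel | None = None,
) -> pd.DataFrame:
    """Quartets with the five branch lengths i.i.d. uniform on ``interval``.

    Data are generated on the tree 12|34; one row per alignment records the
    weight triple, the provenance tag and whether the argmax split is correct.
    """
    lo, hi = interval
    rows = []
    for _ in range(n_align):
        lengths = rng.uniform(lo, hi, size=5)
        if model is None:
            inst = gm_quartet(lengths[:4], lengths[4], rng)
        else:
            inst = _gtr_quartet(lengths[:4], lengths[4], model)
        p = _counts_to_distribution(inst.simulate_codes(n_sites, rng))
        ok, w, tag = _success(p, method, m)
        rows.append((*w.weights, tag, ok))
    return pd.DataFrame(rows, columns=["w_12|34", "w_13|24", "w_14|23", "tag", "correct"])


def _gtr_quartet(pendants, interior, model: GTRModel) -> GMInstance:
    edges = []
    for parent, child, length in [
        (0, 1, pendants[0]),
        (0, 2, pendants[1]),
        (0, 5, interior),
        (5, 3, pendants[2]),
        (5, 4, pendants[3]),
    ]:
        edges.append((parent, child, model.transition(length), length))
    return GMInstance(
        edges=edges,
        n_nodes=6,
        root=0,
        root_dist=np.asarray(model.base_freqs, dtype=float),
        leaf_labels={1: "1", 2: "2", 3: "3", 4: "4"},
    )


def _counts_to_distribution(codes: np.ndarray) -> SitePatternDistribution:
    counts = pattern_counts(codes)
    n = int(counts.sum())
    return SitePatternDistribution(taxa=("1", "2", "3", "4"), values=counts / n, n_sites=n)


def huelsenbeck_grid(
    step: float = 0.02,
    max_len: float = 1.5,
    reps: int = 100,
    n_sites: int = 1000,
    rng: np.random.Generator | None = None,
    method: str = "asaq",
    m: int = 1,
    model: GTRModel | None = None,
) -> pd.DataFrame:
    """Success fraction of a weighting method over the (a, b) tree-space grid.

    The grid runs from ``step`` to ``max_len`` in steps of ``step`` in both
    coordinates (zero-length edges are excluded), with ``reps`` alignments per
    point.
    """
    rng = rng if rng is not None else np.random.default_rng()
    values = np.arange(step, max_len + step / 2, step)
    rows = []
    for a in values:
        for b in values:
            n_ok = 0
            for _ in range(reps):
                inst = (
                    huelsenbeck_quartet(a, b, rng)
                    if model is None
                    else _gtr_quartet((a, b, a, b), b, model)
                )
                p = _counts_to_distribution(inst.simulate_codes(n_sites, rng))
                ok, _, _ = _success(p, method, m)
                n_ok += ok
            rows.append((a, b, n_ok / reps, reps))
    return pd.DataFrame(rows, columns=["a", "b", "success", "reps"])


#: interior lengths of the two-category quartet mixture design: 0.01 to 0.4 in
#: steps of 0.05
MIXTURE_R_VALUES = tuple(np.arange(0.01, 0.4, 0.05).round(2))

#: pendant patterns of the two mixture categories (a, b swapped)
MIXTURE_CATEGORIES = ((0.05, 0.75), (0.75, 0.05))


def mixture_category_quartet(
    a: float, b: float, r: float, rng: np.random.Generator
) -> GMInstance:
    """One mixture category on the quartet 12|34: the cherry (1, 2) gets
    pendant length a, the cherry (3, 4) gets b, the interior edge r."""
    return gm_quartet((a, a, b, b), r, rng)


def simulate_quartet_mixture_codes(
    r: float, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """One two-category mixture alignment (codes) on the quartet 12|34.

    Both categories share the interior length r and contribute the same
    number of sites; the (a, b) cherry pendant lengths are swapped between the
    categories, so every leaf is long in one category and short in the other
    (a heterotachy design in the spirit of partitioned branch-length-swap
    mixtures).
    """
    half = n_sites // 2
    parts = []
    for (a, b), n in zip(MIXTURE_CATEGORIES, (half, n_sites - half)):
        inst = mixture_category_quartet(a, b, r, rng)
        parts.append(inst.simulate_codes(n, rng))
    return np.hstack(parts)


def quartet_mixture_experiment(
    r_values: Sequence[float] = MIXTURE_R_VALUES,
    n_sites: int = 1000,
    reps: int = 100,
    rng: np.random.Generator | None = None,
    method: str = "asaq",
    m: int = 2,
) -> pd.DataFrame:
    """Success of a weighting method on the two-category quartet mixtures."""
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for r in r_values:
        n_ok = 0
        for _ in range(reps):
            codes = simulate_quartet_mixture_codes(r, n_sites, rng)
            p = _counts_to_distribution(codes)
            ok, _, _ = _success(p, method, m)
            n_ok += ok
        rows.append((r, n_ok / reps, reps))
    return pd.DataFrame(rows, columns=["r", "success", "reps"])


# ---------------------------------------------------------------------------
# 12-taxon benchmark trees
# ---------------------------------------------------------------------------

# Pendant-length multipliers (units of the internal length b) for the 6-leaf
# caterpillar blocks.  Both blocks carry two long (9b) and four short (1.5b)
# pendants; in C the long pair is a cherry, in D the long branches are
# separated by the interior path, creating the long-branch-attraction quartet
# on the last four leaves: d(leaf3, leaf4) = 4b while d(leaf2, leaf5) = 20b.
_C_PENDANTS = (1.5, 1.5, 1.5, 1.5, 9.0, 9.0)
_D_PENDANTS = (1.5, 1.5, 9.0, 1.5, 1.5, 9.0)


def _block(names: Sequence[str], pendants: Sequence[float], b: float) -> str:
    p = [m * b for m in pendants]
    return (
        f"({names[0]}:{p[0]},({names[1]}:{p[1]},({names[2]}:{p[2]},"
        f"({names[3]}:{p[3]},({names[4]}:{p[4]},{names[5]}:{p[5]}):{b}):{b}):{b}):{b}):{b / 2}"
    )


def twelve_taxon_newick(
    kind: str, b: float, swap_mixture: bool = False
) -> str:
    """Newick string for the 12-taxon benchmark topologies CC, CD and DD.

    Two 6-leaf blocks are glued by the root (the two half-length root edges
    form one internal edge of length b).  DD uses a mirrored leaf numbering in
    its first block, so the quoted path-length constraints hold in both
    blocks.  With ``swap_mixture`` (CD only) the pendant lengths of seq3/seq4
    and of seq7/seq8 are exchanged — the second system of the two-category
    mixture design.
    """
    if b <= 0:
        raise ValueError("internal branch length b must be positive")
    first = [f"seq{i}" for i in range(6)]
    second = [f"seq{i}" for i in range(6, 12)]
    if kind == "CC":
        blocks = (_block(first, _C_PENDANTS, b), _block(second, _C_PENDANTS, b))
    elif kind == "CD":
        c_pend = list(_C_PENDANTS)
        d_pend = list(_D_PENDANTS)
        if swap_mixture:
            c_pend[3], c_pend[4] = c_pend[4], c_pend[3]
            d_pend[1], d_pend[2] = d_pend[2], d_pend[1]
        blocks = (_block(first, c_pend, b), _block(second, d_pend, b))
    elif kind == "DD":
        blocks = (
            _block(list(reversed(first)), _D_PENDANTS, b),
            _block(second, _D_PENDANTS, b),
        )
    else:
        raise ValueError(f"unknown 12-taxon tree kind: {kind!r}")
    return f"({blocks[0]},{blocks[1]});"


def twelve_taxon_trees(kind: str, b: float) -> dendropy.Tree:
    """The CC / CD / DD benchmark tree with branch lengths, as a dendropy tree."""
    return dendropy.Tree.get(data=twelve_taxon_newick(kind, b), schema="newick")


def cd_mixture_codes(
    p: float, b: float, n_sites: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Two-category mixture alignment on the CD topology.

    A proportion ``p`` of sites evolves under the CD branch lengths and the
    rest under CD with the seq3/seq4 and seq7/seq8 pendant lengths exchanged.
    Returns (taxa in sorted order, code matrix).
    """
    n1 = int(round(p * n_sites))
    parts = []
    taxa = None
    for n, swap in ((n1, False), (n_sites - n1, True)):
        if n == 0:
            continue
        tree = dendropy.Tree.get(
            data=twelve_taxon_newick("CD", b, swap_mixture=swap), schema="newick"
        )
        inst = GMInstance.from_tree(tree, rng)
        taxa = inst.taxa
        parts.append(inst.simulate_codes(n, rng))
    return taxa, np.hstack(parts)


def _codes_to_alignment(taxa: Sequence[str], codes: np.ndarray) -> Alignment:
    rows = [_ACGT[c].tobytes().decode("ascii") for c in codes]
    return Alignment(taxa=list(taxa), rows=rows, length=codes.shape[1])


def twelve_taxon_experiment(
    kind: str,
    b: float,
    n_sites: int,
    reps: int,
    rng: np.random.Generator | None = None,
    weight_method: str = "asaq",
    m: int = 1,
    qmethod: str = "wo",
    build_replicates: int = 11,
    model: GTRModel | None = None,
) -> pd.DataFrame:
    """Average RF of rebuilt trees on unmixed CC/CD/DD benchmark alignments."""
    from . import qmethods  # local import: qmethods does not depend on simulate

    rng = rng if rng is not None else np.random.default_rng()
    truth = twelve_taxon_newick(kind, b)
    rows = []
    for rep in range(reps):
        tree = dendropy.Tree.get(data=truth, schema="newick")
        inst = GMInstance.from_tree(tree, rng, model=model)
        aln = _codes_to_alignment(inst.taxa, inst.simulate_codes(n_sites, rng))
        table = qmethods.compute_weight_table(aln, method=weight_method, m=m)
        built = qmethods.run_and_consense(qmethod, table, n_replicates=build_replicates, seed=rng)
        rows.append((rep, qmethods.rf_distance(built, truth)))
    return pd.DataFrame(rows, columns=["rep", "rf"])


def cd_mixture_experiment(
    p: float,
    b: float,
    n_sites: int,
    reps: int,
    rng: np.random.Generator | None = None,
    weight_method: str = "asaq",
    m: int = 2,
    qmethod: str = "wo",
    build_replicates: int = 11,
) -> pd.DataFrame:
    """Average Robinson-Foulds distance of rebuilt trees on CD-mixture data.

    Each replicate simulates one mixture alignment (proportion ``p`` of sites
    from the CD system, the rest from CD with the seq3/seq4 and seq7/seq8
    pendant lengths exchanged), weights all 495 quartets, builds the tree with
    the chosen amalgamation method and consensus replicates, and records the
    RF distance to the CD topology.  ``p = 1`` reduces to the unmixed CD
    experiment.
    """
    from . import qmethods  # local import: qmethods does not depend on simulate

    rng = rng if rng is not None else np.random.default_rng()
    truth = twelve_taxon_newick("CD", b)
    rows = []
    for rep in range(reps):
        taxa, codes = cd_mixture_codes(p, b, n_sites, rng)
        aln = _codes_to_alignment(taxa, codes)
        table = qmethods.compute_weight_table(aln, method=weight_method, m=m)
        tree = qmethods.run_and_consense(qmethod, table, n_replicates=build_replicates, seed=rng)
        rows.append((rep, qmethods.rf_distance(tree, truth)))
    return pd.DataFrame(rows, columns=["rep", "rf"])
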