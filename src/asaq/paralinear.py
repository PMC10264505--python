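"""Paralinear (log-det) distances and the distance-based quartet weights.

The paralinear distance between two leaves with joint nucleotide distribution
``J`` is

    d = -(1/4) * [ ln |det J| - (1/2) * ln(det D_x * det D_y) ]

where ``D_x`` and ``D_y`` are the diagonal matrices of the two marginal
compositions.  It is additive along the paths of a tree under the general
Markov model and requires no stationarity or time-reversibility.  The factor
1/4 puts it on the expected-substitutions-per-site scale (for a Jukes-Cantor
branch of length t it evaluates to exactly t).

For a quartet with distances ``d_xy`` the neighborliness score of a split
A|B = ij|kl is

    pl_{A|B} = min(d_ik + d_jl, d_il + d_jk) - d_ij - d_kl,

twice the interior-edge length when d is an additive tree metric.  At most one
of the three values is strictly positive.  The PL method returns the argmax
split; PL weights are the normalized exponentials of the three scores.  The 4P
variant scores each split by the gap between its four-point sum and the
second-smallest sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedDistanceError
from .patterns import SPLITS, SitePatternDistribution, pair_joint

# Pair indices for the three splits: (i,j),(k,l) with A = {i,j}.
_SPLIT_PAIRS = {
    "12|34": ((0, 1), (2, 3)),
    "13|24": ((0, 2), (1, 3)),
    "14|23": ((0, 3), (1, 2)),
}


def paralinear_distance(J: np.ndarray) -> float:
    """Paralinear distance from a 4x4 joint distribution.

    Returns NaN (undefined) when det J = 0 or a marginal entry is 0.  The
    returned value uses |det J|; the sign of the determinant is available via
    :func:`paralinear_matrix` for callers that must detect inconsistency with
    stochastic parameters.
    """
    J = np.asarray(J, dtype=float)
    if J.shape != (4, 4) or np.any(J < -1e-12) or abs(J.sum() - 1.0) > 1e-9:
        raise ValueError("J must be a 4x4 joint distribution")
    det = np.linalg.det(J)
    rx = J.sum(axis=1)
    ry = J.sum(axis=0)
    if det == 0.0 or np.any(rx == 0.0) or np.any(ry == 0.0):
        return float("nan")
    return float(
        -0.25 * (np.log(abs(det)) - 0.5 * (np.log(rx).sum() + np.log(ry).sum()))
    )


@dataclass
class ParalinearMatrix:
    """Symmetric matrix of pairwise paralinear distances with undefined flags."""

    d: np.ndarray
    defined: np.ndarray
    det_sign: np.ndarray = field(default=None)  # sign of det J per pair

    @property
    def all_defined(self) -> bool:
        n = self.d.shape[0]
        iu = np.triu_indices(n, 1)
        return bool(self.defined[iu].all())

    def has_nonpositive_det(self) -> bool:
        iu = np.triu_indices(self.d.shape[0], 1)
        return bool((self.det_sign[iu] <= 0).any())


def paralinear_matrix(p: SitePatternDistribution) -> ParalinearMatrix:
    """All six pairwise paralinear distances of a quartet distribution."""
    d = np.zeros((4, 4))
    defined = np.ones((4, 4), dtype=bool)
    sign = np.ones((4, 4))
    for x in range(4):
        for y in range(x + 1, 4):
            J = pair_joint(p, x, y)
            val = paralinear_distance(J)
            det = np.linalg.det(J)
            sign[x, y] = sign[y, x] = np.sign(det)
            if np.isnan(val):
                defined[x, y] = defined[y, x] = False
            else:
                d[x, y] = d[y, x] = val
    return ParalinearMatrix(d=d, defined=defined, det_sign=sign)


def pl_triple_from_distances(d: np.ndarray) -> np.ndarray:
    """The three neighborliness scores from a symmetric 4x4 distance matrix."""
    out = np.empty(3)
    for s, split in enumerate(SPLITS):
        (i, j), (k, l) = _SPLIT_PAIRS[split]
        out[s] = min(d[i, k] + d[j, l], d[i, l] + d[j, k]) - d[i, j] - d[k, l]
    return out


def pl_triple(p: SitePatternDistribution) -> np.ndarray:
    """Neighborliness scores (pl_12|34, pl_13|24, pl_14|23) of ``p``.

    Raises :class:`UndefinedDistanceError` when any paralinear distance is
    undefined; the combined decision rule falls through to the semi-algebraic
    score in that case.
    """
    pm = paralinear_matrix(p)
    if not pm.all_defined:
        raise UndefinedDistanceError("some paralinear distances are undefined")
    return pl_triple_from_distances(pm.d)


@dataclass
class QuartetWeights:
    """Normalized positive weights over the three splits of a quartet."""

    weights: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be 3 non-negative values summing to 1")
        self.weights = w

    @property
    def topology(self) -> str:
        # ties break deterministically in canonical split order
        return SPLITS[int(np.argmax(self.weights))]


def _softmax(scores: np.ndarray) -> np.ndarray:
    e = np.exp(scores - scores.max())
    return e / e.sum()


def pl_weights(p: SitePatternDistribution) -> QuartetWeights:
    """PL weights: normalized exponentials of the neighborliness scores."""
    return QuartetWeights(weights=_softmax(pl_triple(p)), method="pl")


def fourpoint_weights(p: SitePatternDistribution) -> QuartetWeights:
    """4P weights from the gaps between the three four-point sums.

    For split ij|kl the four-point sum is d_ij + d_kl; the split score is the
    second-smallest sum minus the split's own sum (positive only for the
    unique minimal sum), exponentiated and normalized.
    """
    pm = paralinear_matrix(p)
    if not pm.all_defined:
        raise UndefinedDistanceError("some paralinear distances are undefined")
    d = pm.d
    sums = np.array(
        [d[i, j] + d[k, l] for (i, j), (k, l) in (_SPLIT_PAIRS[s] for s in SPLITS)]
    )
    second = np.sort(sums)[1]
    return QuartetWeights(weights=_softmax(second - sums), method="4p")
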