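"""Flattening-rank (Erik+2) and semi-algebraic (SAQ) scores, and their combination.

Under the general Markov model the 16x16 flattening of the generating split of
a quartet has rank at most 4, and at most 4m for an m-category mixture on the
same tree, while the other two flattenings are generically of higher rank.
Erik+2 scores each split by how far its flattening is from the rank-4m
variety.  SAQ additionally penalizes violation of the nonnegativity that
stochastic (row-stochastic, nonnegative) parameters impose on the low-rank
factorization.  The combined method checks whether the distance-based PL
topology agrees with Erik+2 and, if it does not (or the paralinear distances
are inconsistent with stochastic parameters), defers to SAQ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedDistanceError
from .paralinear import (
    QuartetWeights,
    fourpoint_weights,
    paralinear_matrix,
    pl_triple_from_distances,
    pl_weights,
)
from .patterns import SPLITS, SitePatternDistribution, flattening


@dataclass
class Erik2Config:
    """Number of same-tree mixture categories assumed by the rank test.

    m is capped at 3: a flattening from an m-category mixture has rank at most
    4m, and discriminating it from a generic distribution needs 4m < 16.
    """

    m: int = 1

    def __post_init__(self) -> None:
        if self.m not in (1, 2, 3):
            raise ValueError("mixture category count m must be 1, 2 or 3")


@dataclass
class ScoreTriple:
    """Non-negative per-split scores; smaller means better fit."""

    scores: np.ndarray
    method: str


def _normalized_flattenings(p: SitePatternDistribution) -> list[np.ndarray]:
    out = []
    for split in SPLITS:
        m = flattening(p, split).matrix
        nrm = np.linalg.norm(m)
        out.append(m / nrm if nrm > 0 else m)
    return out


def erik2_scores(p: SitePatternDistribution, cfg: Erik2Config | None = None) -> ScoreTriple:
    """Frobenius distance of each unit-norm flattening to the rank-4m matrices.

    score_S = sqrt(sum of squared singular values beyond the 4m-th) of the
    flattening of split S normalized to unit Frobenius norm.
    """
    cfg = cfg or Erik2Config()
    r = 4 * cfg.m
    scores = np.empty(3)
    for s, mat in enumerate(_normalized_flattenings(p)):
        sv = np.linalg.svd(mat, compute_uv=False)
        scores[s] = float(np.sqrt(np.sum(sv[r:] ** 2)))
    return ScoreTriple(scores=scores, method="erik2")


# axis order that brings each split's cherry pair to the front of the tensor
_SPLIT_AXES = {"12|34": (0, 1, 2, 3), "13|24": (0, 2, 1, 3), "14|23": (0, 3, 1, 2)}


_EM_PATH = None


def _fit_split_model(counts: np.ndarray, n_iter: int = 120, tol: float = 3e-9) -> float:
    """Log-likelihood per site of the stochastic quartet model on split 12|34.

    Fits p(x) = sum_{s,t} pi_s A1[s,x1] A2[s,x2] B[s,t] A3[t,x3] A4[t,x4] by
    EM, i.e. the general Markov model with the interior edge separating the
    first two leaves from the last two and all parameters constrained to be
    stochastic.  The initialization is deterministic and symmetric
    (identity-flavoured transition matrices, uniform root distribution): it
    anchors the latent states to the observed letters, breaks the
    label-permutation symmetry of the latent space, and makes the fitted
    likelihood exactly equivariant under relabeling of the four taxa.
    """
    n = counts.sum()
    pi = np.full(4, 0.25)  # symmetric start: keeps the fit relabeling-equivariant
    eye = 0.6 * np.eye(4) + 0.1
    A1, A2, A3, A4 = eye.copy(), eye.copy(), eye.copy(), eye.copy()
    B = 0.7 * np.eye(4) + 0.075
    global _EM_PATH
    if _EM_PATH is None:
        _EM_PATH = np.einsum_path(
            "s,sa,sb,st,tc,td->stabcd", pi, A1, A2, B, A3, A4, optimize="optimal"
        )[0]
    prev = -np.inf
    ll = prev
    for it in range(n_iter):
        P = np.einsum("s,sa,sb,st,tc,td->stabcd", pi, A1, A2, B, A3, A4, optimize=_EM_PATH)
        px = P.sum(axis=(0, 1)) + 1e-300
        ll = float((counts * np.log(px)).sum()) / n
        if it > 10 and ll - prev < tol:
            break
        prev = ll
        N = P * (counts / px)[None, None]
        pi = N.sum(axis=(1, 2, 3, 4, 5))
        pi /= pi.sum()
        for arr, axes in ((A1, (1, 3, 4, 5)), (A2, (1, 2, 4, 5)), (B, (2, 3, 4, 5)),
                          (A3, (0, 2, 3, 5)), (A4, (0, 2, 3, 4))):
            upd = N.sum(axis=axes)
            arr[:] = upd / (upd.sum(axis=1, keepdims=True) + 1e-300)
    return ll


def saq_scores(p: SitePatternDistribution, n_iter: int = 120) -> ScoreTriple:
    """Semi-algebraic split scores.

    Each split is scored by the Kullback-Leibler divergence per site from the
    empirical pattern distribution to the maximum-likelihood fit of the
    stochastic general Markov model on that split (EM fit; see
    :func:`_fit_split_model`).  The fit simultaneously enforces the rank-4
    structure of the split's flattening and the nonnegativity (semi-algebraic)
    constraints of stochastic parameters, so the score vanishes exactly on
    distributions generated with stochastic parameters on the split and stays
    bounded away from zero on the other two splits for generic parameters.
    """
    counts = p.values.reshape(4, 4, 4, 4) * max(p.n_sites, 1)
    base = float(np.sum(p.values[p.values > 0] * np.log(p.values[p.values > 0])))
    scores = np.empty(3)
    for s, split in enumerate(SPLITS):
        c = np.transpose(counts, _SPLIT_AXES[split])
        ll = _fit_split_model(np.ascontiguousarray(c), n_iter=n_iter)
        scores[s] = max(base - ll, 0.0)  # KL(empirical || fitted) >= 0
    return ScoreTriple(scores=scores, method="saq")


def _weights_from_scores(t: ScoreTriple) -> QuartetWeights:
    """Normalized exp(-score/tau) with tau the mean score.

    Positive, normalized and strictly decreasing in the score; scale-free in
    the score units.  Equal (e.g. all-zero) scores give uniform weights.
    """
    s = t.scores
    tau = s.mean()
    if tau <= 0:
        w = np.full(3, 1.0 / 3.0)
    else:
        e = np.exp(-(s - s.min()) / tau)
        w = e / e.sum()
    return QuartetWeights(weights=w, method=t.method)


def erik2_weights(p: SitePatternDistribution, cfg: Erik2Config | None = None) -> QuartetWeights:
    return _weights_from_scores(erik2_scores(p, cfg))


def saq_weights(p: SitePatternDistribution) -> QuartetWeights:
    return _weights_from_scores(saq_scores(p))


def asaq(
    p: SitePatternDistribution, cfg: Erik2Config | None = None
) -> tuple[QuartetWeights, str]:
    """Combined quartet weighting; returns (weights, provenance tag).

    1. Compute all six paralinear distances.  If any is undefined or negative,
       the data are inconsistent with stochastic general-Markov parameters:
       return the SAQ weights.  (With the |det| convention the distances are
       provably non-negative for every valid distribution, so the operative
       trigger is an undefined distance from a degenerate marginal.)
    2. Otherwise compare the PL topology (argmax neighborliness) with the
       Erik+2 topology (argmin rank score, with the configured number of
       mixture categories).  On agreement return the Erik+2 weights, tagged
       'erik2'; on disagreement return the SAQ weights, tagged 'saq'.
    """
    cfg = cfg or Erik2Config()
    pm = paralinear_matrix(p)
    iu = np.triu_indices(4, 1)
    if not pm.all_defined or np.any(pm.d[iu] < 0):
        return saq_weights(p), "saq"
    pl_top = SPLITS[int(np.argmax(pl_triple_from_distances(pm.d)))]
    e2 = erik2_scores(p, cfg)
    e2_top = SPLITS[int(np.argmin(e2.scores))]
    if pl_top == e2_top:
        return _weights_from_scores(e2), "erik2"
    return saq_weights(p), "saq"


WEIGHT_METHODS = ("pl", "4p", "erik2", "saq", "asaq")


def quartet_weights(
    p: SitePatternDistribution, method: str = "asaq", m: int = 1
) -> tuple[QuartetWeights, str]:
    """Compute one weighting system on a quartet distribution.

    Returns (weights, tag); the tag is the method name except for the
    combined method, where it records which branch produced the output
    ('erik2' or 'saq').  Distance-based methods return uniform weights tagged
    'undefined' when a paralinear distance does not exist.
    """
    if method == "asaq":
        return asaq(p, Erik2Config(m=m))
    if method == "erik2":
        return erik2_weights(p, Erik2Config(m=m)), "erik2"
    if method == "saq":
        return saq_weights(p), "saq"
    if method not in ("pl", "4p"):
        raise ValueError(f"unknown weighting method: {method!r}")
    try:
        if method == "pl":
            return pl_weights(p), "pl"
        return fourpoint_weights(p), "4p"
    except UndefinedDistanceError:
        return QuartetWeights(weights=np.full(3, 1.0 / 3.0), method=method), "undefined"
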