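"""Alignments, quartet site-pattern distributions and flattening matrices.

A quartet site-pattern distribution is the empirical joint distribution of
nucleotides observed at four leaves, a vector ``p`` of 256 frequencies indexed
lexicographically over (A, C, G, T)^4 with leaf 1 most significant.  Its three
*flattenings* rearrange ``p`` into 16x16 matrices, one per bipartition of the
four leaves; under the general Markov model the flattening of the generating
split has rank at most 4 (4m for an m-category same-tree mixture), which is
what the algebraic scores downstream exploit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import AlignIO

from .errors import AlignmentFormatError, DegenerateDataError

NUCLEOTIDES = "ACGT"

#: Canonical order of the three quartet splits, relative to the taxon ordering.
SPLITS = ("12|34", "13|24", "14|23")

# byte -> nucleotide code lookup; 255 marks gap/ambiguity
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(NUCLEOTIDES):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


@dataclass
class Alignment:
    """A multiple sequence alignment over {A,C,G,T} plus gap/ambiguity symbols."""

    taxa: list[str]
    rows: list[str]
    length: int

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentFormatError("duplicate taxon labels")
        if self.length < 1:
            raise AlignmentFormatError("alignment has no sites")
        if any(len(r) != self.length for r in self.rows):
            raise AlignmentFormatError("rows have unequal lengths")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def codes(self) -> np.ndarray:
        """Return the (n_taxa, length) uint8 code matrix (255 = non-ACGT)."""
        return np.vstack(
            [_CODE[np.frombuffer(r.encode("ascii"), dtype=np.uint8)] for r in self.rows]
        )

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.taxa, self.rows):
                fh.write(f">{name}\n{row}\n")


@dataclass
class SitePatternDistribution:
    """Joint distribution of site patterns at an ordered quartet of leaves."""

    taxa: tuple[str, str, str, str]
    values: np.ndarray  # shape (256,), sums to 1
    n_sites: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (256,):
            raise ValueError("expected 256 pattern frequencies")
        if np.any(self.values < 0):
            raise ValueError("pattern frequencies must be non-negative")
        if abs(self.values.sum() - 1.0) > 1e-12:
            raise ValueError("pattern frequencies must sum to 1")

    def tensor(self) -> np.ndarray:
        return self.values.reshape(4, 4, 4, 4)


@dataclass
class Flattening:
    """A 16x16 rearrangement of a quartet distribution along one split."""

    split: str
    matrix: np.ndarray


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA or (relaxed/sequential) PHYLIP alignment.

    Taxon order is preserved as it appears in the file.
    """
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format: {format!r}")
    try:
        msa = AlignIO.read(path, fmt)
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise AlignmentFormatError(f"could not parse {path} as {format}: {exc}") from exc
    taxa = [rec.id for rec in msa]
    rows = [str(rec.seq).upper() for rec in msa]
    if not rows:
        raise AlignmentFormatError("empty alignment")
    return Alignment(taxa=taxa, rows=rows, length=msa.get_alignment_length())


def read_alignment_string(text: str, format: str = "fasta") -> Alignment:
    return read_alignment(io.StringIO(text), format=format)


def pattern_counts(codes: np.ndarray) -> np.ndarray:
    """256-vector of raw pattern counts from a (4, L) code matrix.

    Columns containing any non-ACGT symbol are dropped.
    """
    ok = (codes < 4).all(axis=0)
    if not ok.any():
        raise DegenerateDataError("no usable columns for this quartet")
    c = codes[:, ok].astype(np.intp)
    idx = ((c[0] * 4 + c[1]) * 4 + c[2]) * 4 + c[3]
    return np.bincount(idx, minlength=256).astype(float)


def count_patterns(
    aln: Alignment,
    quartet: Sequence[str],
    gap_policy: str = "drop_column",
) -> SitePatternDistribution:
    """Empirical site-pattern distribution for four named taxa.

    The only supported gap policy drops every column showing a non-ACGT symbol
    in any of the four rows, so the result is a proper distribution over
    {A,C,G,T}^4.
    """
    if gap_policy != "drop_column":
        raise ValueError(f"unknown gap policy: {gap_policy!r}")
    if len(quartet) != 4:
        raise ValueError("a quartet needs exactly four taxa")
    rows = np.vstack(
        [
            _CODE[np.frombuffer(aln.row(t).encode("ascii"), dtype=np.uint8)]
            for t in quartet
        ]
    )
    counts = pattern_counts(rows)
    n_used = int(counts.sum())
    return SitePatternDistribution(
        taxa=tuple(quartet), values=counts / n_used, n_sites=n_used
    )


def distribution_from_counts(counts: np.ndarray, taxa=("1", "2", "3", "4")) -> SitePatternDistribution:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise DegenerateDataError("empty pattern counts")
    return SitePatternDistribution(taxa=tuple(taxa), values=counts / n, n_sites=int(round(n)))


def flattening(p: SitePatternDistribution, split: str) -> Flattening:
    """Flattening matrix of ``p`` along ``split`` (one of '12|34', '13|24', '14|23')."""
    t = p.tensor()
    if split == "12|34":
        m = t.reshape(16, 16)
    elif split == "13|24":
        m = t.transpose(0, 2, 1, 3).reshape(16, 16)
    elif split == "14|23":
        m = t.transpose(0, 3, 1, 2).reshape(16, 16)
    else:
        raise ValueError(f"unknown split: {split!r}")
    return Flattening(split=split, matrix=np.ascontiguousarray(m))


def unflatten(f: Flattening) -> SitePatternDistribution:
    """Invert :func:`flattening`, recovering the source distribution exactly."""
    t = f.matrix.reshape(4, 4, 4, 4)
    if f.split == "12|34":
        v = t
    elif f.split == "13|24":
        v = t.transpose(0, 2, 1, 3)
    elif f.split == "14|23":
        v = t.transpose(0, 2, 3, 1)
    else:
        raise ValueError(f"unknown split: {f.split!r}")
    return SitePatternDistribution(
        taxa=("1", "2", "3", "4"), values=np.ascontiguousarray(v).reshape(256), n_sites=1
    )


def pair_joint(p: SitePatternDistribution, x: int, y: int) -> np.ndarray:
    """4x4 joint distribution of leaves ``x`` and ``y`` (0-based indices)."""
    if x == y:
        raise ValueError("pair_joint requires two distinct leaves")
    t = p.tensor()
    axes = tuple(a for a in range(4) if a not in (x, y))
    j = t.sum(axis=axes)
    if x > y:
        j = j.T
    return j
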