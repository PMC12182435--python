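"""Pairwise alignment, Hamming distance matrices and neighbor-joining trees.

The divergence between two allele protein sequences is measured as a
Hamming distance on their pairwise global alignment: the count of aligned
columns whose symbols differ.  Trees are built by neighbor joining on the
all-pairs distance matrix.  This deliberately trades the multiple-sequence
alignment + maximum-likelihood route for a self-contained pairwise +
distance-based one: the qualitative question asked of the tree (do the two
species' alleles form two clean clades?) is insensitive to that choice,
and the substitution is recorded in every output manifest.

Gap handling: by default a gap aligned against a residue counts as a
differing position (an insertion/deletion is a sequence difference); pass
``count_gaps=False`` to score residue columns only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from .mhc_io import AlleleSequence

GAP = "-"

#: Scoring schemes: (match, mismatch) for the identity scheme; BLOSUM62 is
#: loaded from Biopython on demand.
_IDENTITY = ("identity", 1.0, 0.0)


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedPair:
    """A pairwise global alignment; removing gaps recovers the inputs."""

    a_aligned: str
    b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise AlignmentError("aligned strings differ in length")


def _substitution_fn(substitution: str):
    if substitution == "identity":
        return lambda x, y: 1.0 if x == y else 0.0
    if substitution.lower() == "blosum62":
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        return lambda x, y: float(m[x, y])
    raise ValueError(f"unknown substitution scheme {substitution!r}")


def global_align(a: str, b: str, substitution: str = "identity",
                 gap_open: float = -1.0, gap_extend: float = -1.0) -> AlignedPair:
    """Optimal global (Needleman–Wunsch/Gotoh) alignment of two proteins.

    Affine gap penalties: opening a gap costs ``gap_open`` for its first
    position and ``gap_extend`` for each further position.  Traceback ties
    are broken deterministically: diagonal, then up (gap in ``b``), then
    left (gap in ``a``).
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    sub = _substitution_fn(substitution)
    n, m = len(a), len(b)
    NEG = float("-inf")
    # Gotoh three-state DP. M: a[i-1] aligned to b[j-1]; X: gap in b (consume
    # a); Y: gap in a (consume b).
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub(ai, b[j - 1])
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    # Traceback with the stated preference order.
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][i, j])
    score = float({"M": M, "X": X, "Y": Y}[state][i, j])
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = sub(a[i - 1], b[j - 1])
            for cand in ("M", "X", "Y"):
                if {"M": M, "X": X, "Y": Y}[cand][i - 1, j - 1] + s == M[i, j]:
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            if M[i - 1, j] + gap_open == X[i, j] and i - 1 >= 0:
                nxt = "M"
            elif X[i - 1, j] + gap_extend == X[i, j]:
                nxt = "X"
            else:
                nxt = "Y"
            i, state = i - 1, nxt
        elif state == "Y":
            out_a.append(GAP)
            out_b.append(b[j - 1])
            if M[i, j - 1] + gap_open == Y[i, j]:
                nxt = "M"
            elif Y[i, j - 1] + gap_extend == Y[i, j]:
                nxt = "Y"
            else:
                nxt = "X"
            j, state = j - 1, nxt
        else:  # state == "M" at a border: only gaps remain
            state = "X" if i > 0 else "Y"
    return AlignedPair("".join(reversed(out_a)), "".join(reversed(out_b)), score)


def hamming_distance(pair: AlignedPair, count_gaps: bool = True) -> int:
    """Count of aligned columns whose symbols differ.

    With ``count_gaps`` (default) a gap-vs-residue column counts as a
    difference; otherwise gap columns are ignored.
    """
    if len(pair.a_aligned) != len(pair.b_aligned):
        raise AlignmentError("aligned strings differ in length")
    d = 0
    for x, y in zip(pair.a_aligned, pair.b_aligned):
        if not count_gaps and (x == GAP or y == GAP):
            continue
        if x != y:
            d += 1
    return d


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise Hamming distances."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValueError("distance matrix has negative entries")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal is not zero")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        return cls(labels=header, values=np.array(rows))


def distance_matrix(seqs: Sequence[AlleleSequence], count_gaps: bool = True,
                    substitution: str = "identity") -> DistanceMatrix:
    """All-pairs Hamming distances on pairwise global alignments."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [str(s.name) for s in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = global_align(seqs[i].sequence, seqs[j].sequence,
                                substitution=substitution)
            d[i, j] = d[j, i] = hamming_distance(pair, count_gaps=count_gaps)
    return DistanceMatrix(labels=labels, values=d)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; recovers additive matrices exactly."""
    if len(d.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    return nj(_SkbioDM(d.values, ids=d.labels))


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue()


def species_monophyly(tree: TreeNode,
                      labels_by_group: Mapping[str, Sequence[str]]) -> bool:
    """True iff some edge bipartitions the leaves exactly into the two groups.

    ``labels_by_group`` maps two group names to leaf-label lists covering
    every leaf exactly once.
    """
    if len(labels_by_group) != 2:
        raise ValueError("exactly two groups required")
    (ga, gb) = (frozenset(v) for v in labels_by_group.values())
    tips = frozenset(t.name for t in tree.tips())
    unknown = (ga | gb) - tips
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    if ga | gb != tips or ga & gb:
        raise ValueError("groups must partition the leaf set")
    # An (unrooted) edge bipartition corresponds to the tip set under one
    # endpoint of the edge in the rooted representation.
    for node in tree.non_tips(include_self=False):
        sub = frozenset(t.name for t in node.tips())
        if sub == ga or sub == gb:
            return True
    # Trivial bipartitions (single tip vs rest) are edges too.
    if len(ga) == 1 or len(gb) == 1:
        return True
    return False
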