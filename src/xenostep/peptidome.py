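"""Sliding-window peptide extraction and cross-universe overlap statistics.

The *peptidome* of a pool of MHC protein sequences is the set of unique
fixed-length subsequences (15mers by default) obtainable by sliding a
window one residue at a time over every sequence.  Windows containing the
unknown-residue symbol 'X' are dropped: an indeterminate peptide can
neither be matched against another pool nor scored for binding.  Overlap
between two pools (e.g. the human- and swine-derived peptidomes) is exact
set intersection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .mhc_io import AlleleSequence


def enumerate_kmers(seq: str, k: int) -> list[str]:
    """All length-``k`` windows of ``seq`` at step 1, in start-position order.

    Windows containing 'X' are skipped.  A sequence shorter than ``k``
    yields no windows.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "X" not in w:
            out.append(w)
    return out


@dataclass
class Peptidome:
    """A unique set of k-length peptides with source-allele bookkeeping."""

    k: int
    peptides: set[str] = field(default_factory=set)
    sources: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides

    def add(self, peptide: str, source: str) -> None:
        if len(peptide) != self.k:
            raise ValueError(f"peptide length {len(peptide)} != k={self.k}")
        self.peptides.add(peptide)
        self.sources.setdefault(peptide, set()).add(source)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("peptide\tn_sources\tsources\n")
            for pep in sorted(self.peptides):
                src = sorted(self.sources.get(pep, ()))
                fh.write(f"{pep}\t{len(src)}\t{','.join(src)}\n")


def build_peptidome(seqs: Iterable[AlleleSequence], k: int = 15) -> Peptidome:
    """Union of unique k-mers across sequences, with contributing alleles."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences given")
    pome = Peptidome(k=k)
    for s in seqs:
        for w in enumerate_kmers(s.sequence, k):
            pome.add(w, str(s.name))
    return pome


@dataclass(frozen=True)
class OverlapStats:
    """Exact overlap between two peptide pools.

    ``shared_pct_of_combined`` is 100·n_shared/(n_a+n_b) rounded to one
    decimal: the shared count relative to the summed pool sizes (the
    intersection is counted once in the numerator but appears in both
    terms of the denominator).  With ``denominator="union"`` the
    percentage uses |A ∪ B| instead.
    """

    n_a: int
    n_b: int
    n_shared: int
    shared_pct_of_combined: float


def overlap_stats(a: Peptidome, b: Peptidome,
                  denominator: str = "combined") -> OverlapStats:
    if a.k != b.k:
        raise ValueError(f"peptide length mismatch: {a.k} != {b.k}")
    shared = len(a.peptides & b.peptides)
    return OverlapStats(
        n_a=len(a), n_b=len(b), n_shared=shared,
        shared_pct_of_combined=shared_percentage(len(a), len(b), shared,
                                                 denominator=denominator),
    )


def shared_percentage(n_a: int, n_b: int, n_shared: int,
                      denominator: str = "combined") -> float:
    """Shared peptides as a percentage of the combined pools, 1 decimal."""
    if denominator == "combined":
        denom = n_a + n_b
    elif denominator == "union":
        denom = n_a + n_b - n_shared
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return 0.0
    return round(100.0 * n_shared / denom, 1)


def overlap_report(stats: OverlapStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "n_a": stats.n_a,
        "n_b": stats.n_b,
        "n_shared": stats.n_shared,
        "shared_pct_of_combined": stats.shared_pct_of_combined,
    }, indent=2) + "\n")
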