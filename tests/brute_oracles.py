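"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way (explicit
loops, no sets beyond final collection, no shared code with the package's
pipeline) so that agreement with the package is meaningful.
"""

from __future__ import annotations

from xenostep.binding import CORE_LENGTH, MockClassIIPredictor
from xenostep.mhc_io import AlleleDB, Genotype


def hamming_loop(a_aligned: str, b_aligned: str, count_gaps: bool = True) -> int:
    """Per-column scan."""
    assert len(a_aligned) == len(b_aligned)
    d = 0
    for i in range(len(a_aligned)):
        x, y = a_aligned[i], b_aligned[i]
        if not count_gaps and ("-" in (x, y)):
            continue
        if x != y:
            d += 1
    return d


def overlap_double_loop(list_a: list[str], list_b: list[str]) -> int:
    """Count of distinct members of A also found in B, by nested scan."""
    shared = []
    for p in list_a:
        if p in shared:
            continue
        for q in list_b:
            if p == q:
                shared.append(p)
                break
    return len(shared)


def percentile_rank_sorted(background_scores: list[float], score: float) -> float:
    """Percent of background scores >= score, by explicit counting."""
    n_ge = 0
    for s in background_scores:
        if s >= score:
            n_ge += 1
    return 100.0 * n_ge / len(background_scores)


def kmers_slice_loop(seq: str, k: int) -> list[str]:
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "X" not in w:
            out.append(w)
    return out


def t2_exhaustive(recipient: Genotype, donor: Genotype, db: AlleleDB,
                  predictor: MockClassIIPredictor, threshold_pct: float,
                  k: int = 15) -> set[tuple[str, str]]:
    """Exhaustive enumeration over every (peptide, presenter, core) combination.

    Returns the epitope set as (presenter two-field string, core) pairs.
    Rebuilds the self-filter, best-window choice and percentile rank from
    the predictor's primitives with plain loops.
    """
    self_windows: list[str] = []
    for allele in recipient.all_alleles():
        seq = db.get(allele).sequence
        for i in range(len(seq) - k + 1):
            if "X" not in seq[i:i + k]:
                self_windows.append(seq[i:i + k])

    donor_windows: list[str] = []
    for allele in donor.all_alleles():
        seq = db.get(allele).sequence
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "X" not in w and w not in donor_windows:
                donor_windows.append(w)

    epitopes: set[tuple[str, str]] = set()
    for presenter in recipient.presenter_alleles():
        pseq = db.get(presenter).sequence
        bg = list(predictor._background_scores(pseq))
        for pep in donor_windows:
            if pep in self_windows:
                continue
            # best window: max score, lowest offset on ties
            best_score, best_off = None, None
            for off in range(len(pep) - CORE_LENGTH + 1):
                s = predictor.window_score(pseq, pep[off:off + CORE_LENGTH])
                if best_score is None or s > best_score:
                    best_score, best_off = s, off
            rank = percentile_rank_sorted(bg, best_score)
            if rank <= threshold_pct:
                epitopes.add((str(presenter.two_field()),
                              pep[best_off:best_off + CORE_LENGTH]))
    return epitopes


def step_exhaustive(recipient: Genotype, graft1: Genotype, graft2: Genotype,
                    db: AlleleDB, predictor: MockClassIIPredictor,
                    threshold_pct: float, k: int = 15) -> set[tuple[str, str]]:
    e1 = t2_exhaustive(recipient, graft1, db, predictor, threshold_pct, k)
    e2 = t2_exhaustive(recipient, graft2, db, predictor, threshold_pct, k)
    return {e for e in e1 if e in e2}
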