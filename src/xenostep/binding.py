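"""Class-II peptide-binding prediction: plug-in contract plus a bundled mock.

The epitope pipeline needs, for each (recipient class-II presenter,
donor-derived 15mer) pair, a *binding rank*: the percentile of the
peptide's predicted binding strength against a background peptide set
(lower = stronger binder), together with the 9mer core the presenter is
predicted to hold in its groove.  Production systems obtain this from a
trained predictor (NetMHCIIpan-class); this module defines the contract
such a predictor must satisfy and ships a deterministic mock so the whole
pipeline is testable without a trained model.

The mock assigns each (presenter sequence, 9mer window) pair a
pseudo-random score — a BLAKE2 hash of the pair mapped to [0, 1) — takes
the best of the seven 9mer windows in a 15mer as its core, and converts
that score to a rank percentile against a fixed background of 10,000
15mers drawn once from a fixed-seed residue-frequency model.  Hash
scoring makes rank distributions exchangeable across peptide pools
regardless of their residue composition: a fixed position-weight matrix
would instead hand every residue-usage-skewed pool (such as one species'
allele universe) a systematic rank shift under some presenters, which
would distort exactly the cross-universe comparisons this package makes.
Overlapping 15mers share window scores, so the characteristic collapse
of neighbouring peptides onto one dominant core is preserved.

The mock is a pure function of (presenter sequence, peptide): identical
inputs always give identical calls.  Only recipient (human-side)
class-II molecules are ever scored as presenters; graft MHC is treated
purely as a peptide source.
"""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mhc_io import AMINO_ACIDS, AlleleName

CORE_LENGTH = 9
PEPTIDE_LENGTH = 15
#: Default presentation cutoff: rank percentile <= 10 (the conventional
#: weak-binder threshold).
DEFAULT_THRESHOLD_PCT = 10.0

#: Background model: mildly non-uniform residue frequencies (roughly
#: vertebrate proteome-like ordering), fixed for reproducibility.
_BACKGROUND_SEED = 20_250_621
_BACKGROUND_SIZE = 10_000
_BACKGROUND_FREQS = np.array([
    8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
    2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.3, 6.9, 1.1, 2.9,
])
_BACKGROUND_FREQS = _BACKGROUND_FREQS / _BACKGROUND_FREQS.sum()


@dataclass(frozen=True)
class BindingCall:
    """Predicted presentation of one 15mer by one class-II presenter."""

    presenter: AlleleName
    peptide: str
    rank_pct: float
    core: str
    core_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.core_offset <= PEPTIDE_LENGTH - CORE_LENGTH):
            raise ValueError(f"core_offset {self.core_offset} out of range")
        if self.core != self.peptide[self.core_offset:self.core_offset + CORE_LENGTH]:
            raise ValueError("core is not the stated window of the peptide")
        if not (0.0 <= self.rank_pct <= 100.0):
            raise ValueError(f"rank_pct {self.rank_pct} outside [0, 100]")


def is_presented(call: BindingCall, threshold_pct: float = DEFAULT_THRESHOLD_PCT) -> bool:
    """True iff the call's rank is at or below the cutoff (inclusive)."""
    if not (0 < threshold_pct <= 100):
        raise ValueError(f"threshold_pct must be in (0, 100], got {threshold_pct}")
    return call.rank_pct <= threshold_pct


class ClassIIPredictor(ABC):
    """Plug-in contract for class-II binding predictors.

    An implementation must be deterministic — identical
    (presenter sequence, peptide) inputs give identical calls — and must
    return, for each 15mer, a rank percentile in [0, 100] (lower =
    stronger) and the offset of the predicted 9mer binding core.
    Adapters wrapping external trained predictors satisfy the same
    interface.
    """

    @abstractmethod
    def predict(self, presenter: AlleleName, presenter_seq: str,
                peptides: Sequence[str]) -> list[BindingCall]:
        """One :class:`BindingCall` per peptide, in input order."""


class MockClassIIPredictor(ClassIIPredictor):
    """Deterministic hashed-window mock predictor with percentile ranks.

    Window scores are uniform pseudo-random numbers keyed by
    (presenter sequence, 9mer); the background best-window score
    distribution is computed once per presenter and cached.
    """

    def __init__(self, background_size: int = _BACKGROUND_SIZE,
                 background_seed: int = _BACKGROUND_SEED):
        self.background_size = background_size
        self.background_seed = background_seed
        self._background: list[str] | None = None
        self._bg_scores_cache: dict[str, np.ndarray] = {}
        self._call_cache: dict[tuple[str, str], tuple[float, int]] = {}

    # -- internals ---------------------------------------------------------

    def _background_peptides(self) -> list[str]:
        if self._background is None:
            rng = np.random.default_rng(self.background_seed)
            idx = rng.choice(len(AMINO_ACIDS),
                             size=(self.background_size, PEPTIDE_LENGTH),
                             p=_BACKGROUND_FREQS)
            self._background = ["".join(AMINO_ACIDS[i] for i in row)
                                for row in idx]
        return self._background

    @staticmethod
    def window_score(presenter_seq: str, core: str) -> float:
        """Pseudo-random score in [0, 1) keyed by (presenter, 9mer)."""
        h = hashlib.blake2b(f"{presenter_seq}|{core}".encode(),
                            digest_size=8).digest()
        return int.from_bytes(h, "big") / 2**64

    def best_window(self, presenter_seq: str, peptide: str) -> tuple[float, int]:
        """Best 9mer window score and its offset (lowest offset on ties)."""
        best, best_off = -1.0, 0
        for off in range(len(peptide) - CORE_LENGTH + 1):
            s = self.window_score(presenter_seq, peptide[off:off + CORE_LENGTH])
            if s > best:
                best, best_off = s, off
        return best, best_off

    def _background_scores(self, presenter_seq: str) -> np.ndarray:
        """Sorted best-window scores of the background set for a presenter."""
        s = self._bg_scores_cache.get(presenter_seq)
        if s is None:
            s = np.sort([self.best_window(presenter_seq, pep)[0]
                         for pep in self._background_peptides()])
            self._bg_scores_cache[presenter_seq] = s
        return s

    def _rank_pct(self, presenter_seq: str, score: float) -> float:
        """Percent of background peptides scoring at least ``score``."""
        bg = self._background_scores(presenter_seq)
        n_ge = len(bg) - np.searchsorted(bg, score, side="left")
        return 100.0 * float(n_ge) / len(bg)

    # -- contract ----------------------------------------------------------

    def predict(self, presenter: AlleleName, presenter_seq: str,
                peptides: Sequence[str]) -> list[BindingCall]:
        if not presenter_seq:
            raise ValueError(f"no sequence for presenter {presenter}")
        calls = []
        for pep in peptides:
            if len(pep) != PEPTIDE_LENGTH:
                raise ValueError(
                    f"peptide length must be {PEPTIDE_LENGTH}, got {len(pep)}")
            key = (presenter_seq, pep)
            cached = self._call_cache.get(key)
            if cached is None:
                score, offset = self.best_window(presenter_seq, pep)
                cached = (self._rank_pct(presenter_seq, score), offset)
                self._call_cache[key] = cached
            rank, offset = cached
            calls.append(BindingCall(
                presenter=presenter, peptide=pep, rank_pct=rank,
                core=pep[offset:offset + CORE_LENGTH], core_offset=offset))
        return calls
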