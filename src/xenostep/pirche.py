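"""Indirect T-cell epitope scoring: PIRCHE-T2 and the STEP memory score.

A donor MHC molecule is digested (conceptually) into 15mer peptides.  A
peptide poses an indirect CD4+ T-cell risk when it (a) is *foreign* — not
found anywhere in the recipient's own MHC-derived peptidome (the
self-filter) — and (b) is predicted to be *presented* by one of the
recipient's class-II (DRB1-like) molecules.  An epitope is the pair
(recipient presenter allele at two-field resolution, presented 9mer core
peptide); the PIRCHE-T2 score is the number of unique such epitopes a
donor exposes to a recipient.

For a recipient facing two sequential grafts, the STEP (shared T-cell
epitope) score counts the epitopes the second graft shares with the
first: repeat exposure to the same epitope can reactivate memory T cells.
STEP is a set intersection, so it is symmetric in graft order and never
exceeds either graft's own T2 score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from .binding import (DEFAULT_THRESHOLD_PCT, ClassIIPredictor, is_presented)
from .mhc_io import AlleleDB, AlleleName, Genotype
from .peptidome import Peptidome, build_peptidome


class Epitope(NamedTuple):
    """(presenter, core) pair; presenter equality is two-field."""

    presenter: AlleleName
    core: str


@dataclass
class T2Result:
    """Unique predicted epitope set for one (recipient, donor) pair."""

    recipient_id: str
    donor_id: str
    epitopes: set[Epitope]
    provenance: dict[Epitope, set[str]] = field(default_factory=dict)

    @property
    def score(self) -> int:
        return len(self.epitopes)


@dataclass
class StepResult:
    """Epitopes shared between two sequential grafts for one recipient."""

    recipient_id: str
    first_graft_id: str
    second_graft_id: str
    shared_epitopes: set[Epitope]

    @property
    def score(self) -> int:
        return len(self.shared_epitopes)


def self_peptidome(recipient: Genotype, seqdb: AlleleDB, k: int = 15) -> Peptidome:
    """Union peptidome over every recipient allele at every locus."""
    alleles = recipient.all_alleles()
    seqs = [seqdb.get(a) for a in alleles]
    return build_peptidome(seqs, k=k)


def _donor_peptides(donor: Genotype, seqdb: AlleleDB, k: int) -> dict[str, set[str]]:
    """Unique donor k-mers with their contributing donor alleles."""
    pome = build_peptidome([seqdb.get(a) for a in donor.all_alleles()], k=k)
    return {pep: pome.sources[pep] for pep in pome.peptides}


def pirche_t2(recipient: Genotype, donor: Genotype, seqdb: AlleleDB,
              predictor: ClassIIPredictor,
              threshold_pct: float = DEFAULT_THRESHOLD_PCT,
              k: int = 15,
              epitope_identity: str = "core",
              self_filter: str = "peptide") -> T2Result:
    """Predicted indirectly recognisable epitopes of ``donor`` in ``recipient``.

    Pipeline: enumerate donor 15mers over all donor loci; drop peptides
    present in the recipient's self peptidome; score the survivors
    against each recipient presenter; keep presented calls; collect
    unique (presenter, core) epitopes.

    ``epitope_identity``: ``"core"`` counts (presenter, 9mer core) pairs;
    ``"peptide"`` counts (presenter, full 15mer) pairs instead, a stricter
    identity for sensitivity analysis.  ``self_filter``: ``"peptide"``
    removes donor 15mers found verbatim in the self peptidome; ``"core"``
    additionally removes a presented call whose 9mer core occurs inside
    any self 15mer.
    """
    if epitope_identity not in ("core", "peptide"):
        raise ValueError(f"unknown epitope_identity {epitope_identity!r}")
    if self_filter not in ("peptide", "core"):
        raise ValueError(f"unknown self_filter {self_filter!r}")
    presenters = recipient.presenter_alleles()
    if not presenters:
        raise ValueError(
            f"recipient {recipient.individual_id!r} has no presenter alleles "
            f"at loci {recipient.presenter_loci}")
    self_pome = self_peptidome(recipient, seqdb, k=k)
    donor_peps = _donor_peptides(donor, seqdb, k=k)
    foreign = sorted(p for p in donor_peps if p not in self_pome)
    self_cores: set[str] | None = None
    if self_filter == "core":
        self_cores = set()
        for pep in self_pome.peptides:
            for i in range(len(pep) - 9 + 1):
                self_cores.add(pep[i:i + 9])
    epitopes: set[Epitope] = set()
    provenance: dict[Epitope, set[str]] = {}
    for presenter in presenters:
        pseq = seqdb.get(presenter).sequence
        for call in predictor.predict(presenter, pseq, foreign):
            if not is_presented(call, threshold_pct):
                continue
            if self_cores is not None and call.core in self_cores:
                continue
            unit = call.core if epitope_identity == "core" else call.peptide
            epi = Epitope(presenter.two_field(), unit)
            epitopes.add(epi)
            provenance.setdefault(epi, set()).add(call.peptide)
    return T2Result(recipient_id=recipient.individual_id,
                    donor_id=donor.individual_id,
                    epitopes=epitopes, provenance=provenance)


def step_score(recipient: Genotype, graft1: Genotype, graft2: Genotype,
               seqdb: AlleleDB, predictor: ClassIIPredictor,
               threshold_pct: float = DEFAULT_THRESHOLD_PCT,
               k: int = 15,
               epitope_identity: str = "core",
               self_filter: str = "peptide") -> StepResult:
    """Epitopes of the second graft already seen in the first graft."""
    t1 = pirche_t2(recipient, graft1, seqdb, predictor, threshold_pct,
                   k=k, epitope_identity=epitope_identity, self_filter=self_filter)
    t2 = pirche_t2(recipient, graft2, seqdb, predictor, threshold_pct,
                   k=k, epitope_identity=epitope_identity, self_filter=self_filter)
    return StepResult(recipient_id=recipient.individual_id,
                      first_graft_id=graft1.individual_id,
                      second_graft_id=graft2.individual_id,
                      shared_epitopes=t1.epitopes & t2.epitopes)


def write_epitope_tsv(result: T2Result | StepResult, path: str | Path) -> None:
    """One epitope per row: presenter, core/peptide unit, source peptides."""
    epis = result.epitopes if isinstance(result, T2Result) else result.shared_epitopes
    prov = result.provenance if isinstance(result, T2Result) else {}
    with open(path, "w") as fh:
        fh.write("presenter\tcore\tsource_peptides\n")
        for epi in sorted(epis, key=lambda e: (str(e.presenter), e.core)):
            peps = ",".join(sorted(prov.get(epi, ())))
            fh.write(f"{epi.presenter}\t{epi.core}\t{peps}\n")
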