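"""Fully specified toy MHC worlds with recorded ground truth.

Real cross-species epitope analyses hinge on database snapshots and
trained predictors that cannot ship with a package, so every recovery
test here runs on a generated world instead: two allele universes (a
human-like and a swine-like species) built over *disjoint* residue
vocabularies, a weighted haplotype table for the human-like species, and
a reference xenodonor genotype.

The disjoint vocabularies are the load-bearing trick: no 15mer can be
shared between the species by accident, so after *injecting* exactly G
human-derived 15mers into swine alleles (at window offsets spaced so
that no straddling window is ever vocabulary-pure), the cross-species
peptidome overlap is provably exactly G.  Every stochastic choice is
drawn from one seeded stream, so a (spec, seed) pair regenerates the
world byte-for-byte; the realized sequences, injection placements and
divergences are returned as :class:`WorldTruth` for tests to assert
against.

Substitution-only variation (no indels) keeps all sequences the same
length, so Hamming ground truth is exact and alignment never introduces
gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import HaplotypeTable
from .mhc_io import (AlleleName, AlleleSequence, Genotype, parse_allele_name,
                     write_allele_fasta)

#: Disjoint default vocabularies (10 + 10 of the 20 amino acids).
HUMAN_VOCAB = "ACDEFGHIKL"
SWINE_VOCAB = "MNPQRSTVWY"


class WorldSpecError(ValueError):
    """Raised when a world specification is internally infeasible."""


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a two-species toy world.

    ``within_species_divergence`` is the expected Hamming distance between
    two same-locus alleles of one species; between-species distances are
    pinned near ``sequence_length`` by the disjoint vocabularies.
    ``n_injected_shared_kmers`` (G) human-derived 15mers are copied into
    swine alleles to create exactly G cross-species shared peptides.
    """

    seed: int = 0
    n_alleles_per_locus: int = 4
    loci_a: tuple[str, ...] = ("A", "B", "C", "DRB1")
    loci_b: tuple[str, ...] = ("1", "2", "3", "DRB1")
    species_a: str = "HLA"
    species_b: str = "SLA"
    sequence_length: int = 90
    within_species_divergence: int = 10
    between_species_divergence: int = 90
    n_injected_shared_kmers: int = 5
    k: int = 15
    vocab_a: str = HUMAN_VOCAB
    vocab_b: str = SWINE_VOCAB
    n_haplotypes: int = 6
    haplotype_weight_decay: float = 0.7

    def validate(self) -> None:
        if set(self.vocab_a) & set(self.vocab_b):
            raise WorldSpecError("species vocabularies must be disjoint")
        if len(self.vocab_a) < 2 or len(self.vocab_b) < 2:
            raise WorldSpecError("vocabularies need at least 2 residues")
        if self.within_species_divergence > self.sequence_length:
            raise WorldSpecError("within-species divergence exceeds sequence length")
        if self.between_species_divergence <= self.within_species_divergence:
            raise WorldSpecError("between-species divergence must exceed within")
        if self.sequence_length < self.k:
            raise WorldSpecError("sequences shorter than the peptide length")
        if self.n_injected_shared_kmers > self._total_injection_slots():
            raise WorldSpecError(
                f"G={self.n_injected_shared_kmers} shared k-mers requested but "
                f"only {self._total_injection_slots()} non-overlapping slots exist")
        if self.n_alleles_per_locus < 1 or self.n_haplotypes < 1:
            raise WorldSpecError("need at least one allele and one haplotype")

    def _slots_per_allele(self) -> int:
        # Injection start offsets 0, k+1, 2(k+1), ...: one native residue
        # between consecutive injections so no straddling window is pure.
        return (self.sequence_length - self.k) // (self.k + 1) + 1

    def _total_injection_slots(self) -> int:
        return self._slots_per_allele() * self.n_alleles_per_locus * len(self.loci_b)


@dataclass
class WorldTruth:
    """Realized ground truth of a generated world."""

    base_sequences: dict[str, dict[str, str]]  # species -> locus -> base seq
    injected: list[dict]  # {"peptide", "allele", "offset"}
    mean_within_divergence: dict[str, float]  # species -> same-locus mean
    mean_between_divergence: float
    haplotype_table: HaplotypeTable


@dataclass
class World:
    """A generated two-species world plus its ground truth."""

    spec: WorldSpec
    alleles: dict[str, list[AlleleSequence]]  # species -> alleles
    haplotype_table: HaplotypeTable
    xenodonor: Genotype
    truth: WorldTruth

    def all_alleles(self) -> list[AlleleSequence]:
        return [a for sp in self.alleles.values() for a in sp]

    def seqdb(self):
        from .mhc_io import AlleleDB

        return AlleleDB(self.all_alleles())

    def write_fasta(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = {}
        for species, alleles in self.alleles.items():
            path = directory / f"{species.lower()}_alleles.fasta"
            write_allele_fasta(alleles, path)
            out[species] = path
        return out


def cohort_world_spec(seed: int) -> WorldSpec:
    """Study conditions for cohort-scale analyses.

    Relative to the toy defaults, sequences are full-length MHC-protein
    scale (360 residues): at toy lengths the handful of strong 9mer cores
    per presenter compresses every score towards zero and the human/xeno
    score distributions blur together.  The haplotype pool (30 haplotypes,
    geometric decay 0.9, 6 alleles per locus) is diverse enough that a
    donor genotype-identical to a patient is rare while allele sharing
    between random donors stays common — the regime in which two human
    grafts share epitopes but a human and a swine graft hardly do.
    The swine universe spans seven loci (class I and II), matching the
    published reference xenodonor's genotype structure, so a swine graft
    is a proportionally larger peptide source than a human one.  Twelve
    human 15mers are injected into swine alleles so cross-species sharing
    is present but small.
    """
    return WorldSpec(seed=seed, n_alleles_per_locus=6, sequence_length=360,
                     within_species_divergence=10,
                     between_species_divergence=360,
                     loci_b=("1", "2", "3", "DRB1", "DQB1", "DQA", "DRA"),
                     n_injected_shared_kmers=12, n_haplotypes=30,
                     haplotype_weight_decay=0.9)


def perturb_allele(seq: str, n_substitutions: int, seed: int,
                   vocabulary: str | None = None) -> str:
    """Substitute exactly ``n_substitutions`` positions with different residues.

    Each chosen position receives a residue from ``vocabulary`` (default:
    the residues occurring in ``seq``) that differs from the original.
    """
    if n_substitutions > len(seq):
        raise ValueError(
            f"cannot substitute {n_substitutions} positions in a length-"
            f"{len(seq)} sequence")
    if n_substitutions == 0:
        return seq
    vocab = vocabulary if vocabulary is not None else "".join(sorted(set(seq)))
    if len(set(vocab)) < 2:
        raise ValueError("vocabulary must contain at least 2 residues")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_substitutions, replace=False)
    chars = list(seq)
    for pos in positions:
        choices = [c for c in vocab if c != chars[pos]]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _random_seq(rng: np.random.Generator, vocab: str, length: int) -> str:
    return "".join(vocab[i] for i in rng.integers(0, len(vocab), size=length))


def _perturb_with_rng(rng: np.random.Generator, seq: str, n: int, vocab: str) -> str:
    positions = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for pos in positions:
        choices = [c for c in vocab if c != chars[pos]]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _mean_pairwise_hamming(groups: Sequence[Sequence[str]]) -> float:
    """Mean Hamming over all same-group pairs (equal-length sequences)."""
    dists = []
    for group in groups:
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                dists.append(sum(x != y for x, y in zip(group[i], group[j])))
    return float(np.mean(dists)) if dists else 0.0


def generate_world(spec: WorldSpec) -> World:
    """Generate a world; deterministic from ``spec`` (including its seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_sub = round(spec.within_species_divergence / 2)

    base: dict[str, dict[str, str]] = {}
    alleles: dict[str, list[AlleleSequence]] = {}
    for species, loci, vocab in ((spec.species_a, spec.loci_a, spec.vocab_a),
                                 (spec.species_b, spec.loci_b, spec.vocab_b)):
        base[species] = {}
        alleles[species] = []
        for locus in loci:
            base_seq = _random_seq(rng, vocab, spec.sequence_length)
            base[species][locus] = base_seq
            for a in range(spec.n_alleles_per_locus):
                seq = _perturb_with_rng(rng, base_seq, n_sub, vocab)
                name = parse_allele_name(f"{species}-{locus}*{a + 1:02d}:01")
                alleles[species].append(AlleleSequence(name=name, sequence=seq))

    # Inject G human-derived 15mers into swine alleles at spaced offsets.
    injected: list[dict] = []
    if spec.n_injected_shared_kmers:
        human_windows = sorted({
            a.sequence[i:i + spec.k]
            for a in alleles[spec.species_a]
            for i in range(len(a.sequence) - spec.k + 1)
        })
        if len(human_windows) < spec.n_injected_shared_kmers:
            raise WorldSpecError("not enough distinct human windows to inject")
        pick = rng.choice(len(human_windows),
                          size=spec.n_injected_shared_kmers, replace=False)
        peptides = [human_windows[int(i)] for i in pick]
        slots = [(ai, off)
                 for ai in range(len(alleles[spec.species_b]))
                 for off in range(0, spec.sequence_length - spec.k + 1,
                                  spec.k + 1)]
        slot_pick = rng.choice(len(slots), size=len(peptides), replace=False)
        swine = alleles[spec.species_b]
        seqs = [list(a.sequence) for a in swine]
        for pep, si in zip(peptides, slot_pick):
            ai, off = slots[int(si)]
            seqs[ai][off:off + spec.k] = pep
            injected.append({"peptide": pep, "allele": str(swine[ai].name),
                             "offset": off})
        alleles[spec.species_b] = [
            AlleleSequence(name=a.name, sequence="".join(s))
            for a, s in zip(swine, seqs)
        ]

    # Human haplotype table: one allele per locus per haplotype.
    by_locus_a = {
        locus: [a.name for a in alleles[spec.species_a] if a.name.gene == locus]
        for locus in spec.loci_a
    }
    haps = []
    for _ in range(spec.n_haplotypes):
        hap = tuple(by_locus_a[locus][int(rng.integers(spec.n_alleles_per_locus))]
                    for locus in spec.loci_a)
        haps.append(hap)
    # Registry haplotype frequency spectra are heavy-tailed with a stable
    # shape; a fixed geometric decay emulates that without letting the
    # population structure itself fluctuate between seeds (only the allele
    # composition of each haplotype is random).
    weights = spec.haplotype_weight_decay ** np.arange(spec.n_haplotypes)
    weights = weights / weights.sum()
    table = HaplotypeTable(loci=list(spec.loci_a),
                           haplotypes=[(h, float(w)) for h, w in zip(haps, weights)])

    # Xenodonor: mirrors the published reference genotype's structure —
    # three class I alleles at the first locus, two per locus elsewhere.
    xeno_loci: dict[str, list[AlleleName]] = {}
    for li, locus in enumerate(spec.loci_b):
        names = [a.name for a in alleles[spec.species_b] if a.name.gene == locus]
        n_pick = min(3 if li == 0 else 2, len(names))
        pick = rng.choice(len(names), size=n_pick, replace=False)
        xeno_loci[locus] = [names[int(i)] for i in sorted(pick)]
    xenodonor = Genotype(individual_id="xenodonor", species=spec.species_b,
                         loci=xeno_loci, presenter_loci=["DRB1"])

    seq_groups_a = [[a.sequence for a in alleles[spec.species_a]
                     if a.name.gene == locus] for locus in spec.loci_a]
    seq_groups_b = [[a.sequence for a in alleles[spec.species_b]
                     if a.name.gene == locus] for locus in spec.loci_b]
    between = float(np.mean([
        sum(x != y for x, y in zip(sa.sequence, sb.sequence))
        for sa in alleles[spec.species_a] for sb in alleles[spec.species_b]
    ]))
    truth = WorldTruth(
        base_sequences=base,
        injected=injected,
        mean_within_divergence={
            spec.species_a: _mean_pairwise_hamming(seq_groups_a),
            spec.species_b: _mean_pairwise_hamming(seq_groups_b),
        },
        mean_between_divergence=between,
        haplotype_table=table,
    )
    return World(spec=spec, alleles=alleles, haplotype_table=table,
                 xenodonor=xenodonor, truth=truth)
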