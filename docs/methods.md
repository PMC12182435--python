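# Methods

## Scope and model

`xenostep` quantifies indirect CD4+ T-cell antigenicity between two MHC
allele universes. The underlying immunological model is the standard
indirect-recognition pipeline: donor MHC proteins are processed into
linear 15mer peptides; peptides that the recipient's own MHC proteins
also produce are treated as self and discarded; the remainder are
scored for binding to each of the recipient's class-II (DRB1-like)
presenter molecules; a presented peptide contributes the *epitope*
(presenter allele, 9mer binding core). The T2 score of a
recipient/donor pair is the size of that epitope set; the STEP score of
a recipient facing two sequential grafts is the size of the
intersection of the two grafts' epitope sets, a proxy for the risk that
memory T cells primed by the first graft recognise the second.

Assumptions worth stating explicitly:

- **Peptide-level self-filtering.** A donor 15mer is removed if it
  occurs verbatim in the recipient's self peptidome. A stricter variant
  (`self_filter="core"`) additionally removes presented calls whose
  9mer core occurs inside any self 15mer.
- **Epitope identity is exact.** Two epitopes are equal iff the
  presenter's 2-field allele name and the full 9mer core match.
  Near-identical peptides that might cross-react are counted as
  distinct (`epitope_identity="peptide"` is available as an even
  stricter identity). This makes every sharing statistic a lower bound
  on biological cross-reactivity.
- **Presentation is one-sided.** Only recipient class-II molecules
  present; graft MHC is purely a peptide source. Donor grafts
  contribute peptides from *all* their loci (class I and II), matching
  how a xenograft genotype is typed.
- **Allele identity is the 2-field name.** Deeper (synonymous/
  non-coding) fields are parsed and preserved but ignored in every set
  operation.
- **Loci may carry one to three alleles.** Reference xenodonor lines
  are published with three class I alleles at one locus, so strict
  diploidy is not enforced.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `k` | 15 | peptide window length (residues) |
| core length | 9 | class-II binding core (residues) |
| `threshold_pct` | 10.0 | presentation cutoff: rank percentile ≤ threshold counts as presented (inclusive). 10% is the conventional weak-binder cutoff |
| `count_gaps` | True | a gap-vs-residue alignment column counts as a Hamming difference |
| overlap denominator | `combined` | shared % = 100·shared/(nA+nB); `union` uses \|A ∪ B\| |
| `epitope_identity` | `core` | `(presenter, 9mer core)`; `peptide` counts full 15mers |
| `self_filter` | `peptide` | verbatim 15mer filter; `core` also filters self cores |

## Sequence comparison

Divergence between two allele proteins is the Hamming distance — the
count of differing columns — on their pairwise global alignment
(Needleman–Wunsch/Gotoh, affine gaps, deterministic tie-breaking:
diagonal, then up, then left). The default scoring is an identity
scheme (match +1, mismatch 0, gap −1) because distance, not similarity,
is the quantity of interest; BLOSUM62 is available. Trees are built by
neighbor joining (via scikit-bio) on the all-pairs distance matrix, and
`species_monophyly` reports whether some tree edge bipartitions the
leaves exactly into the two species. This pairwise + distance-based
route replaces the common MSA + maximum-likelihood workflow: it needs
no external binaries, neighbor joining provably recovers additive
metrics, and the qualitative claim it supports (two clean species
clades) is insensitive to the substitution; the method is recorded in
every output manifest. Gap handling in published Hamming counts is
often unstated; both conventions are exposed (`count_gaps`).

## The mock binding predictor

Real pipelines use a trained class-II predictor; `xenostep` defines the
predictor *contract* (deterministic; per 15mer: rank percentile in
[0, 100], lower = stronger, plus the 9mer core offset) and bundles
`MockClassIIPredictor` so the pipeline is fully testable offline.

The mock assigns each (presenter sequence, 9mer) pair a pseudo-random
score in [0, 1) — a BLAKE2 hash of the pair — scores a 15mer by its
best of seven 9mer windows, and converts the score to a percentile
against a fixed background of 10,000 15mers drawn once from a
fixed-seed residue-frequency model. Design rationale: an earlier
position-weight-matrix variant turned out to be structurally unfair to
residue-composition-skewed peptide pools — under any fixed random
weight matrix, a pool restricted to a residue subset (exactly what a
synthetic species universe is) acquires a presenter-specific shift and
spread in its score distribution, so nominally 10% presentation rates
ranged from ~2% to ~14% depending on species. Hash scoring makes rank
distributions exchangeable across pools while preserving the two
properties the pipeline actually exercises: determinism, and identical
scores for the shared 9mer windows of overlapping 15mers (which is what
collapses neighbouring peptides onto one dominant core, as real
predictors do). The mock carries no binding biology; absolute T2/STEP
magnitudes are therefore meaningful only relative to each other within
a run, never comparable to scores from trained predictors.

## Synthetic worlds

The generator builds two allele universes over *disjoint* residue
vocabularies (default: human-like `ACDEFGHIKL`, swine-like
`MNPQRSTVWY`). Disjointness makes the zero-sharing baseline provable,
so cross-species sharing can be *injected* exactly: G distinct 15mers
are copied from human alleles into swine alleles at window offsets
spaced k+1 apart, leaving at least one native residue between
insertions, so no window straddling an injection is ever
vocabulary-pure and the realized cross-species overlap is exactly G.
Placements are recorded in `WorldTruth` together with the realized
sequences and divergences. Within a species, each locus has a base
sequence and each allele perturbs it with `within_divergence/2`
substitutions; variation is substitution-only, which keeps sequences
equal-length and Hamming ground truth exact. All randomness flows from
one seeded generator, so a (spec, seed) pair regenerates the world
byte-for-byte.

Haplotype tables assign each haplotype one allele per locus and a
weight following a fixed geometric decay (default ratio 0.7).
Registry frequency spectra are heavy-tailed with a stable shape;
making the shape deterministic (only the allele composition varies
with the seed) avoids degenerate near-monomorphic populations that
unconstrained random weights occasionally produce. Virtual individuals
are two weight-proportional haplotype draws with replacement; each
individual's genotype comes from an RNG substream keyed by
(seed, role, index), so enlarging the donor panel never perturbs
already-drawn patients. For human-after-human repeat transplants the
two human donors are drawn independently per patient (how production
analyses pick the "first" donor is not standardised; independent draws
are the neutral choice).

### Cohort-scale study conditions

Unit tests run on toy worlds (90-residue sequences, 4 alleles per
locus). Cohort analyses use `cohort_world_spec`: 360-residue sequences
(full MHC-protein scale), 6 alleles per locus, 30 haplotypes with decay
0.9, seven swine loci mirroring the published reference xenodonor's
genotype structure (three class I alleles at the first locus, two per
locus elsewhere), within-species divergence 10 versus between-species
divergence 360 (ratio 36), and G = 12 injected shared 15mers. Two of
these choices matter qualitatively and were fixed on mechanistic
grounds: at toy lengths the few strong 9mer cores per presenter
compress all scores towards zero and blur the human/xeno separation;
and a 4-locus swine universe understates a xenograft's peptide load
relative to the 7-locus reference genotype. The bundled cohort runs use
100 patients × 50 donors, which keeps the full simulation around a
minute on one CPU while leaving the score patterns stable across seeds.

### What passing tests do and do not show

The synthetic worlds emulate the *structure* of the real analysis (two
divergent universes, weighted haplotype sampling, a multi-locus
xenodonor), not its content: real allele databases are larger and
internally more heterogeneous, real binding is motif-driven rather than
hash-uniform, and real haplotype tables encode linkage that the
generator does not model. Passing tests therefore demonstrate that the
pipeline's logic is exact (oracle equivalence, parameter recovery,
invariants) and that the qualitative cross-species patterns — xenograft
mismatch load above any human donor, order-independence of shared
epitopes, low cross-species versus human-after-human memory — follow
from divergence structure alone. They do not validate absolute score
magnitudes against clinical data.

## Numerical choices and degenerate inputs

- Alignment traceback ties break deterministically (diagonal, up,
  left); equal-length same-vocabulary sequences align gap-free under
  the identity scheme.
- Best-core ties (equal window scores) take the lowest offset;
  presentation at exactly the threshold counts as presented.
- Percentile ranks count background scores ≥ the peptide's score, so
  the strongest background peptide itself ranks 100/N, and rank 0 is
  possible for peptides stronger than all background.
- Medians over even-length vectors are the mean of the central order
  statistics; optimum-patient selection retains all ties.
- Duplicate alleles (homozygosity) are retained in genotypes and
  collapse in every set operation; duplicate FASTA names are an error
  unless deduplication is requested.
- Windows containing the unknown residue 'X' are dropped during
  peptidome extraction — an indeterminate peptide can neither be
  matched nor scored.
- Empty sequences, empty genotypes, non-amino-acid residues, asymmetric
  or negative distance matrices, and infeasible world specifications
  (injection count exceeding available slots, overlapping vocabularies)
  are rejected with specific errors before any computation.

## Known limitations

- The bundled predictor is a mock; absolute T2/STEP values have no
  clinical calibration, and published score magnitudes from trained
  predictors cannot be reproduced with it.
- Published corpus-level quantities (peptidome sizes, mean cross-species
  Hamming distances) depend on specific database snapshots and are out
  of reach of a self-contained package; the pipeline reproduces the
  *formulas and patterns*, and ingests real FASTA/TSV data when the
  user supplies it.
- No structural (B-cell epitope) analysis: sequence identity is the
  only notion of epitope equality, so cross-reactivity via structural
  or electrostatic similarity is invisible here.
- Substitution-only simulation: no indels, recombination or realistic
  MHC evolution; alignment of real alleles with length variation is
  supported, but the generator never produces it.
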