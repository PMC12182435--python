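"""Virtual patient/donor cohorts from weighted haplotype frequencies.

Genotypes are simulated the way registry studies do it: a population is
summarised as a table of multi-locus haplotypes with frequencies, and an
individual is two haplotypes drawn independently with replacement,
proportionally to weight.  A cohort of patients is paired exhaustively
with a donor panel (every patient × every donor) and additionally with a
fixed reference xenodonor genotype; the T2 score of every pairing and the
STEP score of repeat-transplant scenarios (swine-after-human SAH,
human-after-swine HAS, human-after-human HAH) are summarised per patient.

Reproducibility: every individual's genotype comes from an RNG substream
keyed by (seed, role, index), so enlarging the donor panel never perturbs
the patients already drawn.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .binding import DEFAULT_THRESHOLD_PCT, ClassIIPredictor
from .mhc_io import AlleleDB, AlleleName, Genotype, parse_allele_name
from .pirche import StepResult, pirche_t2, step_score

_ROLE_CODES = {"patient": 1, "donor": 2, "repeat": 3}


@dataclass
class HaplotypeTable:
    """Weighted multi-locus haplotypes; weights normalised to sum to 1."""

    loci: list[str]
    haplotypes: list[tuple[tuple[AlleleName, ...], float]]

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("haplotype table is empty")
        if any(w <= 0 for _, w in self.haplotypes):
            raise ValueError("haplotype weights must be positive")
        for alleles, _ in self.haplotypes:
            if len(alleles) != len(self.loci):
                raise ValueError("haplotype does not span all loci")
        total = sum(w for _, w in self.haplotypes)
        self.haplotypes = [(a, w / total) for a, w in self.haplotypes]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.haplotypes])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.loci) + "\tfrequency\n")
            for alleles, w in self.haplotypes:
                fh.write("\t".join(str(a) for a in alleles) + f"\t{w:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeTable":
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[-1] != "frequency":
                raise ValueError("last haplotype TSV column must be 'frequency'")
            loci = header[:-1]
            haps = []
            for row in reader:
                if not row:
                    continue
                alleles = tuple(parse_allele_name(a) for a in row[:-1])
                haps.append((alleles, float(row[-1])))
        return cls(loci=loci, haplotypes=haps)


def _individual_rng(seed: int, role: str, index: int) -> np.random.Generator:
    code = _ROLE_CODES.get(role)
    if code is None:
        raise ValueError(f"unknown role {role!r}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), code, int(index)]))


def sample_genotype(table: HaplotypeTable, rng_seed: int, individual_id: str,
                    role: str = "patient", index: int = 0,
                    species: str = "HLA",
                    presenter_loci: Sequence[str] | None = None) -> Genotype:
    """Two weight-proportional haplotype draws, combined per locus.

    Deterministic given (rng_seed, role, index).
    """
    rng = _individual_rng(rng_seed, role, index)
    idx = rng.choice(len(table.haplotypes), size=2, replace=True, p=table.weights)
    loci: dict[str, list[AlleleName]] = {locus: [] for locus in table.loci}
    for i in idx:
        alleles, _ = table.haplotypes[int(i)]
        for locus, allele in zip(table.loci, alleles):
            loci[locus].append(allele)
    return Genotype(individual_id=individual_id, species=species, loci=loci,
                    presenter_loci=list(presenter_loci) if presenter_loci
                    else ["DRB1"])


@dataclass(frozen=True)
class PairingScheme:
    """``"cross"`` pairs every A with every B (|A|·|B| pairs);
    ``"all_vs_all_self"`` forms every ordered pair within one list,
    including self-pairs (n² pairs)."""

    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("cross", "all_vs_all_self"):
            raise ValueError(f"unknown pairing mode {self.mode!r}")


def enumerate_pairs(a: Sequence, b: Sequence | None = None,
                    scheme: PairingScheme = PairingScheme("cross"),
                    ) -> tuple[int, Iterator[tuple]]:
    """Exact pair count and a streaming iterator over the pairs."""
    if scheme.mode == "cross":
        if b is None:
            raise ValueError("cross pairing needs two lists")
        if not a or not b:
            raise ValueError("pairing lists must be non-empty")
        count = len(a) * len(b)

        def gen():
            for x in a:
                for y in b:
                    yield (x, y)
    else:
        if b is not None:
            raise ValueError("all_vs_all_self pairing takes a single list")
        if not a:
            raise ValueError("pairing list must be non-empty")
        count = len(a) ** 2

        def gen():
            for x in a:
                for y in a:
                    yield (x, y)
    return count, gen()


@dataclass
class CohortSummary:
    """Raw scores and per-patient summaries for a simulated cohort."""

    patients: list[Genotype]
    donors: list[Genotype]
    xenodonor_id: str
    #: shape (n_patients, n_donors) human-donor T2 scores
    human_scores: np.ndarray
    #: per-patient T2 against the reference xenodonor
    xeno_scores: np.ndarray
    seed: int
    threshold_pct: float

    @property
    def patient_medians(self) -> np.ndarray:
        """Median human-donor T2 per patient (mean of central order stats)."""
        return np.median(self.human_scores, axis=1)

    def optimum_patients(self) -> dict[str, list[str]]:
        """Patients with the lowest / highest median T2; ties retained."""
        med = self.patient_medians
        best = med.min()
        worst = med.max()
        ids = [p.individual_id for p in self.patients]
        return {
            "best": [i for i, m in zip(ids, med) if m == best],
            "worst": [i for i, m in zip(ids, med) if m == worst],
        }

    def scores_frame(self) -> pd.DataFrame:
        """Long table: patient_id, donor_id, donor_source, t2."""
        rows = []
        for i, p in enumerate(self.patients):
            for j, d in enumerate(self.donors):
                rows.append((p.individual_id, d.individual_id, "human",
                             int(self.human_scores[i, j])))
            rows.append((p.individual_id, self.xenodonor_id, "xeno",
                         int(self.xeno_scores[i])))
        return pd.DataFrame(rows, columns=["patient_id", "donor_id",
                                           "donor_source", "t2"])

    def pooled_by_source(self) -> dict[str, np.ndarray]:
        return {"human": self.human_scores.ravel().copy(),
                "xeno": self.xeno_scores.copy()}


def simulate_cohort(n_patients: int, n_donors: int, table: HaplotypeTable,
                    xenodonor: Genotype, seqdb: AlleleDB,
                    predictor: ClassIIPredictor,
                    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
                    seed: int = 0) -> CohortSummary:
    """T2 of every patient × (human donor ∪ xenodonor) pairing."""
    if n_patients < 1 or n_donors < 1:
        raise ValueError("need at least one patient and one donor")
    patients = [sample_genotype(table, seed, f"patient-{i:04d}", "patient", i)
                for i in range(n_patients)]
    donors = [sample_genotype(table, seed, f"donor-{j:04d}", "donor", j)
              for j in range(n_donors)]
    human = np.zeros((n_patients, n_donors), dtype=int)
    xeno = np.zeros(n_patients, dtype=int)
    for i, p in enumerate(patients):
        for j, d in enumerate(donors):
            human[i, j] = pirche_t2(p, d, seqdb, predictor, threshold_pct).score
        xeno[i] = pirche_t2(p, xenodonor, seqdb, predictor, threshold_pct).score
    return CohortSummary(patients=patients, donors=donors,
                         xenodonor_id=xenodonor.individual_id,
                         human_scores=human, xeno_scores=xeno,
                         seed=seed, threshold_pct=threshold_pct)


DIRECTIONS = ("SAH", "HAS", "HAH")


def repeat_transplant_analysis(summary: CohortSummary, xenodonor: Genotype,
                               seqdb: AlleleDB, predictor: ClassIIPredictor,
                               directions: Iterable[str] = DIRECTIONS,
                               seed: int | None = None) -> pd.DataFrame:
    """STEP score per patient per repeat-transplant direction.

    For each patient two human donors are drawn independently (uniformly)
    from the donor panel: the first is the prior/subsequent human graft
    in SAH and HAS, and the pair forms the HAH control.  Returns a long
    table (patient_id, direction, step); medians and zero-score fractions
    are recomputed from it by :func:`repeat_transplant_summary`.
    """
    directions = list(directions)
    unknown = set(directions) - set(DIRECTIONS)
    if unknown:
        raise ValueError(f"unknown directions {sorted(unknown)}")
    if seed is None:
        seed = summary.seed
    rows = []
    for i, patient in enumerate(summary.patients):
        rng = _individual_rng(seed, "repeat", i)
        j1, j2 = (int(x) for x in rng.integers(0, len(summary.donors), size=2))
        h1, h2 = summary.donors[j1], summary.donors[j2]
        for direction in directions:
            if direction == "SAH":
                res = step_score(patient, h1, xenodonor, seqdb, predictor,
                                 summary.threshold_pct)
            elif direction == "HAS":
                res = step_score(patient, xenodonor, h1, seqdb, predictor,
                                 summary.threshold_pct)
            else:
                res = step_score(patient, h1, h2, seqdb, predictor,
                                 summary.threshold_pct)
            rows.append((patient.individual_id, direction, res.score))
    return pd.DataFrame(rows, columns=["patient_id", "direction", "step"])


def repeat_transplant_summary(steps: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Median STEP and zero-score fraction per direction."""
    out: dict[str, dict[str, float]] = {}
    for direction, grp in steps.groupby("direction"):
        v = grp["step"].to_numpy()
        out[str(direction)] = {
            "median": float(np.median(v)),
            "zero_fraction": float(np.mean(v == 0)),
            "n": int(len(v)),
        }
    return out


def write_summary_json(summary: CohortSummary, path: str | Path,
                       step_summary: dict | None = None) -> None:
    med = summary.patient_medians
    data = {
        "n_patients": len(summary.patients),
        "n_donors": len(summary.donors),
        "seed": summary.seed,
        "threshold_pct": summary.threshold_pct,
        "human_t2_median": float(np.median(summary.human_scores)),
        "xeno_t2_median": float(np.median(summary.xeno_scores)),
        "best_patient_median": float(med.min()),
        "worst_patient_median": float(med.max()),
        "optimum_patients": summary.optimum_patients(),
    }
    if step_summary is not None:
        data["step"] = step_summary
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
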