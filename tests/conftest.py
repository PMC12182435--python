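from __future__ import annotations

import numpy as np
import pytest

from xenostep.binding import MockClassIIPredictor
from xenostep.mhc_io import AlleleDB, AlleleSequence, Genotype, parse_allele_name
from xenostep.synthetic_data import WorldSpec, generate_world


@pytest.fixture(scope="session")
def default_world():
    """One shared toy world at the generator's defaults."""
    return generate_world(WorldSpec(seed=11))


@pytest.fixture(scope="session")
def predictor():
    return MockClassIIPredictor()


def make_tiny_world(rng: np.random.Generator, vocab: str = "ACDE",
                    max_len: int = 40, k: int = 15):
    """A random micro-world for exhaustive-oracle comparisons.

    At most 5 alleles of length <= ``max_len`` over a small vocabulary
    (small alphabets force window collisions, so the self-filter and
    epitope dedup actually engage).  Returns (recipient, donor1, donor2,
    AlleleDB).
    """
    n_alleles = int(rng.integers(3, 6))
    alleles = []
    for i in range(n_alleles):
        length = int(rng.integers(k, max_len + 1))
        seq = "".join(vocab[j] for j in rng.integers(0, len(vocab), size=length))
        name = parse_allele_name(f"T-{'L' if i % 2 else 'DRB1'}*{i + 1:02d}:01")
        alleles.append(AlleleSequence(name=name, sequence=seq))
    db = AlleleDB(alleles)
    drb1 = [a.name for a in alleles if a.name.gene == "DRB1"]
    others = [a.name for a in alleles if a.name.gene != "DRB1"]
    recipient = Genotype(
        individual_id="r", species="T",
        loci={"DRB1": [drb1[0]],
              "L": [others[0]] if others else []},
        presenter_loci=["DRB1"])
    donor_pool = [a.name for a in alleles]
    d1 = [donor_pool[int(i)] for i in
          rng.choice(len(donor_pool), size=min(2, len(donor_pool)), replace=False)]
    d2 = [donor_pool[int(i)] for i in
          rng.choice(len(donor_pool), size=min(2, len(donor_pool)), replace=False)]
    donor1 = Genotype(individual_id="d1", species="T",
                      loci={"X": d1}, presenter_loci=["DRB1"])
    donor2 = Genotype(individual_id="d2", species="T",
                      loci={"X": d2}, presenter_loci=["DRB1"])
    return recipient, donor1, donor2, db
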