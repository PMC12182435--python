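import numpy as np
import pandas as pd
import pytest

from xenostep.cohort import (HaplotypeTable, PairingScheme, enumerate_pairs,
                             repeat_transplant_analysis,
                             repeat_transplant_summary, sample_genotype,
                             simulate_cohort, write_summary_json)
from xenostep.mhc_io import Genotype, parse_allele_name
from xenostep.synthetic_data import WorldSpec, generate_world


def _table(rows, loci=("A", "DRB1")):
    haps = [(tuple(parse_allele_name(a) for a in alleles), w)
            for alleles, w in rows]
    return HaplotypeTable(loci=list(loci), haplotypes=haps)


class TestHaplotypeTable:
    def test_weights_normalized(self):
        t = _table([(("HLA-A*01:01", "HLA-DRB1*01:01"), 3.0),
                    (("HLA-A*02:01", "HLA-DRB1*02:01"), 1.0)])
        assert t.weights.sum() == pytest.approx(1.0)
        assert t.weights[0] == pytest.approx(0.75)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            _table([(("HLA-A*01:01", "HLA-DRB1*01:01"), 0.0)])

    def test_haplotype_must_span_loci(self):
        with pytest.raises(ValueError, match="span"):
            HaplotypeTable(loci=["A", "DRB1"],
                           haplotypes=[((parse_allele_name("HLA-A*01:01"),), 1.0)])

    def test_tsv_round_trip(self, tmp_path, default_world):
        t = default_world.haplotype_table
        path = tmp_path / "h.tsv"
        t.to_tsv(path)
        back = HaplotypeTable.from_tsv(path)
        assert back.loci == t.loci
        assert [h for h, _ in back.haplotypes] == [h for h, _ in t.haplotypes]
        assert np.allclose(back.weights, t.weights)


class TestSampleGenotype:
    def test_single_haplotype_always_homozygous(self):
        t = _table([(("HLA-A*01:01", "HLA-DRB1*01:01"), 1.0)])
        g = sample_genotype(t, 0, "p", "patient", 0)
        assert [str(a) for a in g.loci["A"]] == ["HLA-A*01:01", "HLA-A*01:01"]

    def test_deterministic_per_role_and_index(self):
        t = _table([(("HLA-A*01:01", "HLA-DRB1*01:01"), 1.0),
                    (("HLA-A*02:01", "HLA-DRB1*02:01"), 1.0)])
        a = sample_genotype(t, 5, "x", "patient", 3)
        b = sample_genotype(t, 5, "y", "patient", 3)
        assert a.loci == b.loci  # same substream regardless of label
        draws = {str(sample_genotype(t, 5, "x", "donor", i).loci["A"][0])
                 for i in range(20)}
        assert len(draws) > 1  # different indices explore the table

    def test_equal_weight_homozygosity_fraction(self):
        """Two equal-weight haplotypes: P(homozygous) = 1/2."""
        t = _table([(("HLA-A*01:01", "HLA-DRB1*01:01"), 1.0),
                    (("HLA-A*02:01", "HLA-DRB1*02:01"), 1.0)])
        n = 10_000
        hom = sum(
            len({str(a) for a in sample_genotype(t, 99, f"p{i}", "patient", i)
                 .loci["A"]}) == 1
            for i in range(n))
        # 3 sigma of Binomial(n, 1/2)
        assert abs(hom / n - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_draw_frequencies_match_weights(self):
        """Empirical haplotype draw frequencies within 3 sigma of weights."""
        t = _table([(("HLA-A*01:01", "HLA-DRB1*01:01"), 0.6),
                    (("HLA-A*02:01", "HLA-DRB1*02:01"), 0.3),
                    (("HLA-A*03:01", "HLA-DRB1*03:01"), 0.1)])
        n = 25_000
        counts = {"01": 0, "02": 0, "03": 0}
        for i in range(n):
            g = sample_genotype(t, 7, f"p{i}", "patient", i)
            for a in g.loci["A"]:
                counts[a.fields[0]] += 1
        for w, key in zip((0.6, 0.3, 0.1), ("01", "02", "03")):
            freq = counts[key] / (2 * n)
            assert abs(freq - w) < 3 * np.sqrt(w * (1 - w) / (2 * n))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeTable(loci=["A"], haplotypes=[])


class TestEnumeratePairs:
    def test_cross_cohort_count(self):
        n, _ = enumerate_pairs(list(range(4000)), list(range(1000)),
                               PairingScheme("cross"))
        assert n == 4_000_000

    def test_all_vs_all_self_count(self):
        n, it = enumerate_pairs(list(range(138)), scheme=PairingScheme("all_vs_all_self"))
        assert n == 19_044
        assert sum(1 for _ in it) == 19_044

    def test_single_pair(self):
        n, it = enumerate_pairs([1], [2], PairingScheme("cross"))
        assert n == 1 and list(it) == [(1, 2)]

    def test_streaming_matches_count(self):
        n, it = enumerate_pairs(list("abc"), list("xy"), PairingScheme("cross"))
        pairs = list(it)
        assert len(pairs) == n == 6
        assert pairs[0] == ("a", "x")

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            PairingScheme("bogus")
        with pytest.raises(ValueError):
            enumerate_pairs([1], [2], PairingScheme("all_vs_all_self"))


@pytest.fixture(scope="module")
def small_cohort(predictor):
    world = generate_world(WorldSpec(seed=21, sequence_length=180,
                                     between_species_divergence=180))
    db = world.seqdb()
    summary = simulate_cohort(8, 5, world.haplotype_table, world.xenodonor,
                              db, predictor, 10.0, seed=21)
    return world, db, summary


class TestSimulateCohort:
    def test_minimal_cohort_has_two_scores(self, default_world, predictor):
        db = default_world.seqdb()
        s = simulate_cohort(1, 1, default_world.haplotype_table,
                            default_world.xenodonor, db, predictor, seed=3)
        assert s.human_scores.shape == (1, 1)
        assert s.xeno_scores.shape == (1,)
        assert len(s.scores_frame()) == 2

    def test_monomorphic_population_scores_zero(self, default_world, predictor):
        """If every individual carries the same haplotype, every human
        donor is a complete self-match."""
        db = default_world.seqdb()
        hap = default_world.haplotype_table.haplotypes[0][0]
        t = HaplotypeTable(loci=default_world.haplotype_table.loci,
                           haplotypes=[(hap, 1.0)])
        s = simulate_cohort(3, 3, t, default_world.xenodonor, db, predictor,
                            seed=0)
        assert np.all(s.human_scores == 0)
        assert np.all(s.xeno_scores > 0)

    def test_bitwise_reproducible_from_seed(self, small_cohort, predictor):
        world, db, summary = small_cohort
        again = simulate_cohort(8, 5, world.haplotype_table, world.xenodonor,
                                db, predictor, 10.0, seed=21)
        assert np.array_equal(summary.human_scores, again.human_scores)
        assert np.array_equal(summary.xeno_scores, again.xeno_scores)
        other = simulate_cohort(8, 5, world.haplotype_table, world.xenodonor,
                                db, predictor, 10.0, seed=22)
        assert not np.array_equal(summary.human_scores, other.human_scores)

    def test_summary_consistent_with_raw_scores(self, small_cohort):
        _, _, s = small_cohort
        frame = s.scores_frame()
        human = frame[frame.donor_source == "human"]
        for i, p in enumerate(s.patients):
            v = human[human.patient_id == p.individual_id].t2.to_numpy()
            assert len(v) == len(s.donors)
            assert np.median(v) == s.patient_medians[i]
        med = s.patient_medians
        opt = s.optimum_patients()
        ids = [p.individual_id for p in s.patients]
        assert set(opt["best"]) == {i for i, m in zip(ids, med) if m == med.min()}
        assert set(opt["worst"]) == {i for i, m in zip(ids, med) if m == med.max()}

    def test_summary_json_written(self, small_cohort, tmp_path):
        _, _, s = small_cohort
        path = tmp_path / "summary.json"
        write_summary_json(s, path)
        import json

        data = json.loads(path.read_text())
        assert data["n_patients"] == 8
        assert data["human_t2_median"] == float(np.median(s.human_scores))


class TestRepeatTransplantAnalysis:
    def test_sah_equals_has_elementwise(self, small_cohort, predictor):
        """Shared epitopes do not depend on which graft came first."""
        world, db, summary = small_cohort
        steps = repeat_transplant_analysis(summary, world.xenodonor, db,
                                           predictor)
        sah = steps[steps.direction == "SAH"].set_index("patient_id").step
        has = steps[steps.direction == "HAS"].set_index("patient_id").step
        assert (sah == has.reindex(sah.index)).all()

    def test_same_donor_twice_gives_t2(self, default_world, predictor):
        """HAH with one donor drawn twice degenerates to that donor's T2."""
        from xenostep.pirche import pirche_t2

        db = default_world.seqdb()
        s = simulate_cohort(2, 1, default_world.haplotype_table,
                            default_world.xenodonor, db, predictor, seed=5)
        steps = repeat_transplant_analysis(s, default_world.xenodonor, db,
                                           predictor)
        hah = steps[steps.direction == "HAH"].set_index("patient_id").step
        for i, p in enumerate(s.patients):
            t2 = pirche_t2(p, s.donors[0], db, predictor).score
            assert hah[p.individual_id] == t2

    def test_summary_internally_consistent(self, small_cohort, predictor):
        world, db, summary = small_cohort
        steps = repeat_transplant_analysis(summary, world.xenodonor, db,
                                           predictor)
        agg = repeat_transplant_summary(steps)
        for direction, stats in agg.items():
            v = steps[steps.direction == direction].step.to_numpy()
            assert stats["median"] == float(np.median(v))
            assert stats["zero_fraction"] == float(np.mean(v == 0))

    def test_unknown_direction_rejected(self, small_cohort, predictor):
        world, db, summary = small_cohort
        with pytest.raises(ValueError):
            repeat_transplant_analysis(summary, world.xenodonor, db, predictor,
                                       directions=["XYZ"])
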