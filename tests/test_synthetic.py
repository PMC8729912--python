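import numpy as np
import pytest

from prgscan.errors import PrgScanError
from prgscan.hmm_build import build_profile_hmm
from prgscan.domain_scan import viterbi_local
from prgscan.seqio import AA_ALPHABET
from prgscan.synthetic import (
    ARCHITECTURES,
    SimConfig,
    largest_remainder_counts,
    make_generator_hmm,
    make_reference_msa,
    make_reference_set,
    make_synthetic_proteome,
    read_truth_tsv,
    sample_from_hmm,
    write_truth_tsv,
)

from conftest import degenerate_hmm
from oracles import expected_emitted_length


class TestSampleFromHmm:
    def test_degenerate_model_emits_consensus(self):
        hmm = degenerate_hmm("MKVWLE")
        assert sample_from_hmm(hmm, seed=0) == "MKVWLE"

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(1)
        gen = make_generator_hmm("NBS", 60, 0.2, rng)
        assert sample_from_hmm(gen, seed=5) == sample_from_hmm(gen, seed=5)
        assert sample_from_hmm(gen, seed=5) != sample_from_hmm(gen, seed=6)

    def test_mean_length_matches_chain_expectation(self):
        rng = np.random.default_rng(2)
        gen = make_generator_hmm("LRR", 40, 0.3, rng)
        lengths = [len(sample_from_hmm(gen, seed=s)) for s in range(1000)]
        expected = expected_emitted_length(gen)
        se = np.std(lengths, ddof=1) / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - expected) <= 3 * se


class TestReferenceMsa:
    def test_zero_divergence_rows_equal_consensus(self):
        msa, gen = make_reference_msa("TIR", 4, 0.0, seed=3)
        for i in range(len(msa)):
            assert msa.ungapped(i).sequence == gen.consensus

    def test_row_count_and_positive_width(self):
        msa, gen = make_reference_msa("KIN", 7, 0.15, seed=4)
        assert len(msa) == 7
        assert msa.width >= gen.length

    def test_built_model_redetects_all_rows(self):
        msa, _ = make_reference_msa("NBS", 6, 0.2, seed=5)
        hmm = build_profile_hmm(msa, "NBS", "TNL")
        for rec in msa.ungapped_records():
            assert viterbi_local(hmm, rec.sequence).score > 0

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(PrgScanError, match="at least 2 rows"):
            make_reference_msa("NBS", 1, 0.1, seed=1)


class TestReferenceSet:
    def test_regions_match_msa_widths(self, refset):
        for region in refset.regions:
            msa = refset.class_msas[region.msa_id]
            assert region.col_end <= msa.width

    def test_determinism_per_seed(self):
        a = make_reference_set(seed=17, n_rows=4)
        b = make_reference_set(seed=17, n_rows=4)
        assert a.class_msas == b.class_msas
        assert a.regions == b.regions

    def test_lysm_regions_equal_width_for_pooling(self, refset):
        widths = {
            r.msa_id: r.col_end - r.col_start + 1
            for r in refset.regions
            if r.domain_label == "LYSM"
        }
        assert widths["LYK"] == widths["LYP"]


class TestProteome:
    def test_exact_counts_by_largest_remainder(self):
        counts = largest_remainder_counts(
            100, {"TNL": 0.5, "RLK": 0.5}, ["TNL", "RLK"]
        )
        assert counts == {"TNL": 50, "RLK": 50}
        counts = largest_remainder_counts(
            10, {"TNL": 0.34, "RLK": 0.33, "RLP": 0.33}, ["TNL", "RLK", "RLP"]
        )
        assert sum(counts.values()) == 10 and counts["TNL"] == 4

    def test_mix_counts_and_architecture_order(self, refset):
        cfg = SimConfig(seed=7, n_proteins=20, class_mix={"TNL": 0.5, "RLK": 0.5})
        records, truth = make_synthetic_proteome(cfg, refset.generators)
        assert len(records) == 20
        classes = [e.class_label for e in truth.entries]
        assert classes.count("TNL") == 10 and classes.count("RLK") == 10
        for e in truth.entries:
            labels = [l for l, _, _ in e.segments]
            assert tuple(labels) == ARCHITECTURES[e.class_label]
            rec = next(r for r in records if r.id == e.protein_id)
            prev_end = 0
            for label, start, end in e.segments:
                assert prev_end < start <= end <= len(rec.sequence)
                prev_end = end

    def test_zero_noise_plants_verbatim_consensus(self, refset):
        cfg = SimConfig(
            seed=7, n_proteins=3, class_mix={"RLP": 1.0}, substitution_noise=0.0
        )
        records, truth = make_synthetic_proteome(cfg, refset.generators)
        lrr = refset.generators["LRR"].consensus
        for e in truth.entries:
            rec = next(r for r in records if r.id == e.protein_id)
            label, start, end = e.segments[0]
            assert label == "LRR"
            assert rec.sequence[start - 1 : end] == lrr

    def test_byte_identical_outputs_per_seed(self, refset, tmp_path):
        cfg = SimConfig(seed=23, n_proteins=8)
        r1, t1 = make_synthetic_proteome(cfg, refset.generators)
        r2, t2 = make_synthetic_proteome(cfg, refset.generators)
        assert r1 == r2 and t1 == t2

    def test_truth_tsv_round_trip(self, refset, tmp_path):
        cfg = SimConfig(seed=2, n_proteins=7)
        _, truth = make_synthetic_proteome(cfg, refset.generators)
        p = tmp_path / "truth.tsv"
        write_truth_tsv(truth, p)
        assert read_truth_tsv(p) == truth

    def test_missing_generator_is_an_error(self):
        cfg = SimConfig(seed=1, n_proteins=2, class_mix={"TNL": 1.0})
        with pytest.raises(PrgScanError, match="needs a generator"):
            make_synthetic_proteome(cfg, {})


class TestSimConfig:
    def test_rejects_bad_proportions(self):
        with pytest.raises(PrgScanError, match="sum to 1"):
            SimConfig(class_mix={"TNL": 0.4, "RLK": 0.4})

    def test_rejects_large_noise(self):
        with pytest.raises(PrgScanError, match="substitution_noise"):
            SimConfig(substitution_noise=0.6)

    def test_rejects_unknown_keys(self):
        with pytest.raises(PrgScanError, match="unknown config keys"):
            SimConfig.from_dict({"n_protein": 5})

    def test_dict_round_trip(self):
        cfg = SimConfig(seed=5, n_proteins=12)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg
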