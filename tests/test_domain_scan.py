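import numpy as np
import pytest
from scipy.special import logsumexp

from prgscan.domain_scan import (
    DomainHit,
    blosum62_hit_score,
    forward_local,
    resolve_overlaps,
    scan_protein,
    viterbi_local,
)
from prgscan.errors import SequenceError
from prgscan.seqio import AA_ALPHABET, ProteinRecord
from prgscan.synthetic import make_reference_msa
from prgscan.hmm_build import build_profile_hmm, calibrate_threshold

from conftest import degenerate_hmm
from oracles import enumerate_alignment_scores, random_profile_hmm


class TestViterbiForward:
    def test_degenerate_model_scores_negative_log_background(self):
        consensus = "MKVW"
        hmm = degenerate_hmm(consensus)
        aln = viterbi_local(hmm, consensus)
        expected = -sum(np.log(1 / 20) for _ in consensus)
        assert aln.score == pytest.approx(expected)
        assert (aln.start, aln.end) == (1, 4)

    def test_single_path_model_forward_equals_viterbi(self):
        hmm = degenerate_hmm("MKV")
        seq = "MKV"
        # the only positive-mass paths are sub-runs of the consensus
        v = viterbi_local(hmm, seq).score
        f = forward_local(hmm, seq)
        scores = enumerate_alignment_scores(hmm, seq)
        finite = scores[np.isfinite(scores)]
        assert v == pytest.approx(finite.max())
        assert f == pytest.approx(logsumexp(finite))

    def test_matches_enumeration_on_small_models(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            hmm = random_profile_hmm(rng, int(rng.integers(1, 5)))
            seq = "".join(rng.choice(list(AA_ALPHABET + "X"), size=int(rng.integers(1, 7))))
            scores = enumerate_alignment_scores(hmm, seq)
            assert viterbi_local(hmm, seq).score == pytest.approx(
                scores.max(), abs=1e-9
            )
            assert forward_local(hmm, seq) == pytest.approx(
                logsumexp(scores), abs=1e-9
            )

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            hmm = random_profile_hmm(rng, int(rng.integers(1, 6)))
            seq = "".join(rng.choice(list(AA_ALPHABET), size=int(rng.integers(1, 12))))
            assert forward_local(hmm, seq) >= viterbi_local(hmm, seq).score - 1e-12

    def test_appending_background_never_decreases_score(self):
        msa, _ = make_reference_msa("NBS", 5, 0.1, seed=3)
        hmm = build_profile_hmm(msa, "NBS", "TNL")
        core = msa.ungapped(0).sequence
        base = viterbi_local(hmm, core).score
        padded = viterbi_local(hmm, "GSGSGS" + core + "TTSTST").score
        assert padded >= base - 1e-9

    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceError, match="empty"):
            viterbi_local(degenerate_hmm("MK"), "")
        with pytest.raises(SequenceError, match="empty"):
            forward_local(degenerate_hmm("MK"), "")


class TestBlosumScoring:
    def test_worked_examples(self):
        assert blosum62_hit_score("ARN", "ARN") == 15  # 4 + 5 + 6
        assert blosum62_hit_score("A", "R") == -1

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = "".join(rng.choice(list(AA_ALPHABET), size=int(rng.integers(1, 12))))
            b = "".join(rng.choice(list(AA_ALPHABET), size=int(rng.integers(1, 12))))
            assert blosum62_hit_score(a, b) == blosum62_hit_score(b, a)

    def test_x_scores_zero_against_everything(self):
        for res in AA_ALPHABET:
            assert blosum62_hit_score("X", res) == 0

    def test_empty_inputs_rejected(self):
        with pytest.raises(SequenceError):
            blosum62_hit_score("", "ARN")


@pytest.fixture(scope="module")
def nbs_model():
    msa, gen = make_reference_msa("NBS", 6, 0.12, seed=21)
    hmm = build_profile_hmm(msa, "NBS", "TNL")
    return calibrate_threshold(hmm, msa.ungapped_records()), gen


class TestScanProtein:
    def test_planted_segment_recovered(self, nbs_model):
        model, gen = nbs_model
        rng = np.random.default_rng(5)
        bg = lambda n: "".join(rng.choice(list("GSTNDQEKRA"), size=n))
        planted = gen.consensus
        seq = bg(80) + planted + bg(80)
        protein = ProteinRecord(id="p", sequence=seq)
        hits = scan_protein([model], protein)
        assert len(hits) == 1
        hit = hits[0]
        true_start, true_end = 81, 80 + len(planted)
        overlap = min(hit.end, true_end) - max(hit.start, true_start) + 1
        assert overlap / (true_end - true_start + 1) >= 0.8
        assert hit.blosum_score >= model.min_blosum_score

    def test_poly_p_yields_no_hits(self, nbs_model):
        model, _ = nbs_model
        hits = scan_protein([model], ProteinRecord(id="p", sequence="P" * 50))
        assert hits == []

    def test_two_separated_segments_give_two_hits(self, nbs_model):
        model, gen = nbs_model
        rng = np.random.default_rng(9)
        bg = lambda n: "".join(rng.choice(list("GSTNDQEKRA"), size=n))
        seq = bg(30) + gen.consensus + bg(100) + gen.consensus + bg(30)
        hits = scan_protein([model], ProteinRecord(id="p", sequence=seq))
        assert len(hits) == 2
        first, second = hits
        assert first.end < second.start  # non-overlapping by construction


class TestResolveOverlaps:
    def hit(self, label, start, end, score=10.0, blosum=50):
        return DomainHit("p", label, start, end, f"m_{label}", score, blosum)

    def test_same_label_overlap_merged_to_union(self):
        merged = resolve_overlaps([self.hit("NBS", 10, 50, 12.0, 60),
                                   self.hit("NBS", 40, 90, 8.0, 70)])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (10, 90)
        assert merged[0].logodds_score == 12.0 and merged[0].blosum_score == 70

    def test_different_labels_never_merged(self):
        kept = resolve_overlaps([self.hit("NBS", 10, 50), self.hit("LRR", 45, 120)])
        assert len(kept) == 2

    def test_disjoint_same_label_unchanged(self):
        hits = [self.hit("NBS", 10, 50), self.hit("NBS", 60, 90)]
        assert resolve_overlaps(hits) == hits
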