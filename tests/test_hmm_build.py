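import math

import numpy as np
import pytest

from prgscan.errors import CalibrationError, ModelError
from prgscan.hmm_build import (
    build_models,
    build_profile_hmm,
    calibrate_threshold,
    extract_domain_segments,
    filter_hmms,
    read_region_table,
    write_region_table,
)
from prgscan.model import DomainRegion, ProfileHMM, TRANSITION_KEYS
from prgscan.seqio import Msa, ProteinRecord
from prgscan.synthetic import make_reference_msa

from conftest import degenerate_hmm


def two_row_msa(*rows):
    return Msa(rows=tuple((f"r{i}", row) for i, row in enumerate(rows)))


class TestExtractSegments:
    def test_region_slice(self):
        msa = two_row_msa("MKVAAKWQRL", "MKVAAKWQRL")
        region = DomainRegion("TNL", "NBS", 3, 5)
        sub = extract_domain_segments(msa, region)
        assert sub.width == 3 and len(sub) == 2
        assert sub.rows[0][1] == "VAA"

    def test_full_width_is_identity(self):
        msa = two_row_msa("MKVA", "MK-A")
        sub = extract_domain_segments(msa, DomainRegion("TNL", "NBS", 1, 4))
        assert sub.rows == msa.rows

    def test_all_gap_rows_dropped(self):
        msa = two_row_msa("MKVAA", "MK---", "MKWQR")
        sub = extract_domain_segments(msa, DomainRegion("TNL", "NBS", 3, 5))
        assert len(sub) == 2
        assert all(rid != "r1" for rid, _ in sub.rows)

    def test_region_outside_width(self):
        msa = two_row_msa("MKVA", "MKVA")
        with pytest.raises(ModelError, match="exceeds MSA width"):
            extract_domain_segments(msa, DomainRegion("TNL", "NBS", 2, 9))


class TestBuildProfileHmm:
    def test_laplace_arithmetic_on_identical_rows(self):
        hmm = build_profile_hmm(two_row_msa("MK", "MK"), "NBS", "TNL")
        assert hmm.length == 2
        m_idx = "ACDEFGHIKLMNPQRSTVWY".index("M")
        assert hmm.match_emissions[0, m_idx] == pytest.approx(3 / 22)
        assert hmm.consensus == "MK"

    def test_gap_majority_column_is_not_match_state(self):
        # column 2 has 3 gaps in 4 rows (0.75 >= 0.5): not a match state
        msa = Msa(rows=(("a", "M-K"), ("b", "M-K"), ("c", "M-K"), ("d", "MAK")))
        hmm = build_profile_hmm(msa, "NBS", "TNL")
        assert hmm.length == 2

    def test_all_vectors_normalized(self):
        msa, _ = make_reference_msa("LRR", 6, 0.2, seed=5)
        hmm = build_profile_hmm(msa, "LRR", "RLK")
        hmm.validate()  # checks every probability vector sums to 1
        assert np.all(hmm.match_emissions > 0)

    def test_all_gap_majority_errors(self):
        msa = Msa(rows=(("a", "M--"), ("b", "-K-"), ("c", "--V")))
        with pytest.raises(ModelError, match="no match columns"):
            build_profile_hmm(msa, "NBS", "TNL")

    def test_serialization_round_trip_bit_identical(self, tmp_path):
        msa, _ = make_reference_msa("KIN", 5, 0.15, seed=9)
        hmm = build_profile_hmm(msa, "KIN", "RLK").with_threshold(42)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        hmm.to_json(p1)
        ProfileHMM.from_json(p1).to_json(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestFilterHmms:
    def test_criterion_i_rejects_non_hmm_domains(self):
        tm_like = degenerate_hmm("LLLL")
        tm_like = ProfileHMM(**{**tm_like.__dict__, "domain_label": "TM"})
        retained, rejections = filter_hmms([tm_like], {tm_like.name: []})
        assert retained == []
        assert rejections[0].criterion == "i"

    def test_criterion_ii_rejects_model_missing_its_training_seq(self):
        msa, _ = make_reference_msa("NBS", 5, 0.1, seed=2)
        hmm = build_profile_hmm(msa, "NBS", "TNL")
        # a sequence the model cannot possibly recognize: its worst residue everywhere
        alien = ProteinRecord(id="alien", sequence="P" * 30)
        retained, rejections = filter_hmms(
            [hmm], {hmm.name: msa.ungapped_records() + [alien]}
        )
        if rejections:  # the alien sequence must trigger criterion ii
            assert rejections[0].criterion == "ii"
            assert "alien" in rejections[0].reason
            assert retained == []
        else:
            pytest.fail("model recognized a poly-P sequence as NBS")

    def test_criterion_ii_passes_on_true_training_rows(self):
        msa, _ = make_reference_msa("NBS", 5, 0.1, seed=2)
        hmm = build_profile_hmm(msa, "NBS", "TNL")
        retained, rejections = filter_hmms([hmm], {hmm.name: msa.ungapped_records()})
        assert retained == [hmm] and rejections == []

    def test_criterion_iii_keeps_higher_f_score(self):
        msa, gen = make_reference_msa("NBS", 6, 0.1, seed=4)
        good = build_profile_hmm(msa, "NBS", "TNL")
        # legacy model that recognizes nothing: emissions concentrated off-domain
        bad = degenerate_hmm("WWWWWWWW")
        positives = [(r, True) for r in msa.ungapped_records()]
        negatives = [(ProteinRecord(id=f"n{i}", sequence="PGSGSGPGSGPGSG"), False)
                     for i in range(3)]
        bench = {"NBS": positives + negatives}
        retained, rejections = filter_hmms(
            [good], {good.name: msa.ungapped_records()},
            legacy={"NBS": bad}, benchmark=bench,
        )
        assert retained == [good] and rejections == []
        # and the other way around: a new model losing to legacy is rejected
        retained2, rejections2 = filter_hmms(
            [bad], {bad.name: msa.ungapped_records()[:1]},
            legacy={"NBS": good}, benchmark=bench,
        )
        assert any(r.criterion in ("ii", "iii") for r in rejections2)

    def test_no_training_sequences_is_an_error(self):
        msa, _ = make_reference_msa("NBS", 4, 0.1, seed=6)
        hmm = build_profile_hmm(msa, "NBS", "TNL")
        with pytest.raises(ModelError, match="no training sequences"):
            filter_hmms([hmm], {})


class TestCalibration:
    def test_threshold_is_floored_minimum(self):
        msa, _ = make_reference_msa("LYSM", 6, 0.15, seed=8)
        hmm = build_profile_hmm(msa, "LYSM", "LYK")
        from prgscan.domain_scan import blosum62_hit_score, viterbi_local

        scores = []
        for rec in msa.ungapped_records():
            aln = viterbi_local(hmm, rec.sequence)
            scores.append(
                blosum62_hit_score(rec.sequence[aln.start - 1:aln.end], hmm.consensus)
            )
        calibrated = calibrate_threshold(hmm, msa.ungapped_records())
        assert calibrated.min_blosum_score == math.floor(min(scores))

    def test_recalibration_is_idempotent(self):
        msa, _ = make_reference_msa("TIR", 5, 0.1, seed=10)
        hmm = build_profile_hmm(msa, "TIR", "TNL")
        c1 = calibrate_threshold(hmm, msa.ungapped_records())
        c2 = calibrate_threshold(c1, msa.ungapped_records())
        assert c1.min_blosum_score == c2.min_blosum_score

    def test_unrecognized_positive_raises(self):
        msa, _ = make_reference_msa("TIR", 5, 0.1, seed=10)
        hmm = build_profile_hmm(msa, "TIR", "TNL")
        with pytest.raises(CalibrationError, match="no hit"):
            calibrate_threshold(hmm, [ProteinRecord(id="p", sequence="P" * 40)])


class TestBuildModels:
    def test_pooled_lysm_model_built(self, refset, calibrated_models):
        names = {m.name for m in calibrated_models}
        assert "pooled_LYSM_1" in names
        pooled = next(m for m in calibrated_models if m.name == "pooled_LYSM_1")
        assert pooled.class_of_origin == "pooled"

    def test_lecm_subtypes_get_separate_models(self):
        msa, _ = make_reference_msa("LECM", 6, 0.15, seed=12, length=40)
        regions = [
            DomainRegion("LECRK", "LECM", 1, 20, subtype="legume"),
            DomainRegion("LECRK", "LECM", 21, 40, subtype="bulb"),
        ]
        candidates, training = build_models({"LECRK": msa}, regions)
        names = {c.name for c in candidates}
        assert names == {"LECRK_LECM_legume_1", "LECRK_LECM_bulb_1"}

    def test_region_table_round_trip(self, tmp_path, refset):
        p = tmp_path / "regions.tsv"
        write_region_table(refset.regions, p)
        assert tuple(read_region_table(p)) == refset.regions
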