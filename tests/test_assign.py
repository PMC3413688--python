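"""Hit parsing, match criteria, best-hit selection and matrix building."""

import itertools

import pandas as pd
import pytest

from amfsoil.assign import (AlignmentHit, HitParseError, MatchCriteria,
                            assign_reads, best_hit, build_matrix, parse_hits,
                            passes_criteria)
from amfsoil.community import EmptyMatrixError, filter_matrix


def hit(q="r1", s="VT00113", ident=98.5, length=380, evalue=1e-160, bits=560.0):
    return AlignmentHit(q, s, ident, length, evalue, bits)


ROW = "r1\tVT00113\t98.5\t380\t0\t0\t1\t380\t1\t380\t1e-160\t560"


class TestParseHits:
    def test_parses_twelve_column_row(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(ROW + "\n")
        [h] = list(parse_hits(p))
        assert h == hit()

    def test_empty_file_gives_empty_stream(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert list(parse_hits(p)) == []

    def test_row_count_excludes_comments(self, tmp_path):
        p = tmp_path / "hits.tsv"
        rows = [ROW.replace("r1", f"r{i}") for i in range(7)]
        p.write_text("# comment\n" + "\n".join(rows) + "\n# another\n")
        assert len(list(parse_hits(p))) == 7

    def test_unknown_id_named_in_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(ROW + "\n")
        with pytest.raises(HitParseError, match="VT00113"):
            list(parse_hits(p, subject_lengths={"OTHER": 500}))

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(ROW + "\n" + ROW.replace("98.5", "abc") + "\n")
        with pytest.raises(HitParseError, match="line 2"):
            list(parse_hits(p))


class TestCriteria:
    def test_identity_below_threshold_fails(self):
        assert not passes_criteria(hit(ident=96.9), 380, 380)
        assert passes_criteria(hit(ident=97.0), 380, 380)

    def test_length_difference_uses_shorter_sequence(self):
        assert not passes_criteria(hit(ident=97.0, length=369), 380, 500)
        assert passes_criteria(hit(ident=97.0, length=370), 380, 500)

    def test_evalue_bound_is_strict(self):
        assert not passes_criteria(hit(evalue=1e-50), 380, 380)
        assert passes_criteria(hit(evalue=0.9e-50), 380, 380)

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            MatchCriteria(min_identity=-1)


class TestBestHit:
    SLEN = {"VT00099": 380, "VT00101": 380, "VT00113": 380}

    def test_highest_bitscore_wins(self):
        hits = [hit(s="VT00101", bits=540.0), hit(s="VT00113", bits=560.0)]
        assert best_hit(hits, 380, self.SLEN) == "VT00113"

    def test_no_passing_hit_gives_none(self):
        assert best_hit([hit(ident=90.0)], 380, self.SLEN) is None
        assert best_hit([], 380, self.SLEN) is None

    def test_tie_broken_by_evalue_then_subject_id(self):
        tied = [hit(s="VT00101"), hit(s="VT00099")]
        assert best_hit(tied, 380, self.SLEN) == "VT00099"
        by_evalue = [hit(s="VT00101", evalue=1e-170), hit(s="VT00099")]
        assert best_hit(by_evalue, 380, self.SLEN) == "VT00101"

    def test_order_independent(self):
        hits = [hit(s="VT00101", bits=550.0), hit(s="VT00099", bits=550.0),
                hit(s="VT00113", bits=540.0)]
        results = {best_hit(list(p), 380, self.SLEN)
                   for p in itertools.permutations(hits)}
        assert results == {"VT00099"}

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            best_hit([hit(q="r1"), hit(q="r2")], 380, self.SLEN)


class TestAssignReads:
    def test_vectorised_path_matches_best_hit(self, tmp_path):
        rows = [
            "r1\tVT00113\t98.5\t380\t0\t0\t1\t380\t1\t380\t1e-160\t560",
            "r1\tVT00101\t99.0\t380\t0\t0\t1\t380\t1\t380\t1e-150\t540",
            "r2\tVT00101\t96.0\t380\t0\t0\t1\t380\t1\t380\t1e-160\t560",
        ]
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join(rows) + "\n")
        qlen = {"r1": 380, "r2": 380}
        slen = {"VT00113": 380, "VT00101": 380}
        assert assign_reads(p, qlen, slen) == {"r1": "VT00113"}


def design_for(samples):
    return pd.DataFrame({"plot": ["A"] * len(samples)},
                        index=pd.Index(samples, name="sample_id"))


class TestBuildMatrix:
    def test_counts_reads_per_cell(self):
        m = build_matrix([("r1", "S1", "VT1"), ("r2", "S1", "VT1"),
                          ("r3", "S1", "VT1"), ("r4", "S1", "VT2")],
                         design_for(["S1"]))
        assert m.data.loc["S1"].tolist() == [3, 1]

    def test_empty_stream_gives_zero_matrix(self):
        m = build_matrix([], design_for(["S1", "S2"]))
        assert m.shape == (2, 0) and m.row_totals().sum() == 0

    def test_total_equals_assigned_reads(self, rng):
        reads = [(f"r{i}", f"S{rng.integers(3) + 1}", f"VT{rng.integers(4) + 1}")
                 for i in range(200)]
        m = build_matrix(reads, design_for(["S1", "S2", "S3"]))
        assert int(m.data.values.sum()) == 200

    def test_unknown_sample_is_error(self):
        with pytest.raises(KeyError):
            build_matrix([("r1", "SX", "VT1")], design_for(["S1"]))


class TestFilterMatrix:
    def test_sample_threshold_boundary(self):
        data = pd.DataFrame({"VT1": [9, 10], "VT2": [0, 2]}, index=["S1", "S2"])
        from amfsoil.community import CommunityMatrix
        f, log = filter_matrix(CommunityMatrix(data))
        assert f.sample_ids == ["S2"] and log.samples_low_count == ["S1"]

    def test_singleton_vt_removed(self):
        from amfsoil.community import CommunityMatrix
        data = pd.DataFrame({"VT1": [12, 13], "VT2": [1, 0]}, index=["S1", "S2"])
        f, log = filter_matrix(CommunityMatrix(data))
        assert f.vt_ids == ["VT1"] and log.vt_singleton == ["VT2"]

    def test_clean_matrix_unchanged(self, toy_counts):
        f, log = filter_matrix(toy_counts)
        assert f.data.equals(toy_counts.data)
        assert not any(log.as_dict().values())

    def test_iterates_to_fixed_point(self):
        # removing the light sample turns VT2 into a singleton, whose removal
        # drops S2 below threshold in turn
        from amfsoil.community import CommunityMatrix
        data = pd.DataFrame({"VT1": [0, 9, 50], "VT2": [9, 1, 0],
                             "VT3": [0, 0, 30]}, index=["S1", "S2", "S3"])
        f, log = filter_matrix(CommunityMatrix(data))
        assert f.sample_ids == ["S3"]
        assert set(log.samples_low_count) == {"S1", "S2"}

    def test_never_increases_cells(self, toy_counts):
        f, _ = filter_matrix(toy_counts, min_sample_hits=20)
        shared = f.data.index
        assert (f.data.le(toy_counts.data.loc[shared, f.data.columns])).all().all()

    def test_all_samples_removed_is_error(self):
        from amfsoil.community import CommunityMatrix
        data = pd.DataFrame({"VT1": [3, 4]}, index=["S1", "S2"])
        with pytest.raises(EmptyMatrixError):
            filter_matrix(CommunityMatrix(data))


class TestNormalise:
    def test_row_proportions(self, toy_counts):
        n = toy_counts.normalise()
        assert n.data.loc["A1"].tolist() == pytest.approx([30 / 41, 10 / 41, 0, 1 / 41])
        assert n.data.sum(axis=1).tolist() == pytest.approx([1, 1, 1, 1])

    def test_idempotent(self, toy_counts):
        once = toy_counts.normalise()
        twice = once.normalise()
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_zero_row_names_sample(self):
        from amfsoil.community import CommunityMatrix
        data = pd.DataFrame({"VT1": [5, 0]}, index=["S1", "S2"])
        with pytest.raises(ValueError, match="S2"):
            CommunityMatrix(data).normalise()
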