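"""Vector trimming, pairwise E-values, redundant-partner grouping, exports."""

import numpy as np
import pandas as pd
import pytest

from subscreen import seqgroup as sg


@pytest.fixture(scope="module")
def vector_db():
    return sg.default_vector_db()


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _rc(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


class TestTrim:
    def test_vector_prefix_trimmed_at_junction(self, rng, vector_db):
        arm = dict(vector_db)["vector_arm_left"]
        insert = _rand(rng, 150)
        rec = sg.SeqRecordSSH("t1-F", arm[-30:] + insert)
        out = sg.trim_vector(rec)
        assert out.trimmed_range == (30, 180)
        assert not out.rejected
        assert out.insert == insert

    def test_no_vector_similarity_is_noop(self, rng):
        rec = sg.SeqRecordSSH("t2-F", _rand(rng, 180))
        out = sg.trim_vector(rec)
        assert out.trimmed_range == (0, 180)

    def test_reverse_complemented_vector_suffix_trimmed(self, rng, vector_db):
        arm = dict(vector_db)["vector_arm_left"]
        insert = _rand(rng, 150)
        rec = sg.SeqRecordSSH("t3-F", insert + _rc(arm[-30:]))
        out = sg.trim_vector(rec)
        assert out.trimmed_range == (0, 150)

    def test_both_ends_with_adaptors(self, rng, vector_db):
        db = dict(vector_db)
        insert = _rand(rng, 200)
        seq = db["vector_arm_left"][-40:] + db["ssh_adaptor_1"] + insert \
            + db["ssh_adaptor_2r"] + db["vector_arm_right"][:40]
        out = sg.trim_vector(sg.SeqRecordSSH("t4-F", seq))
        assert not out.rejected
        assert out.insert == insert

    def test_internal_vector_hit_rejected_as_chimeric(self, rng, vector_db):
        ad = dict(vector_db)["ssh_adaptor_1"]
        rec = sg.SeqRecordSSH("t5-F", _rand(rng, 100) + ad + _rand(rng, 100))
        out = sg.trim_vector(rec)
        assert out.rejected and out.reject_reason == "chimeric"

    def test_fully_vector_sequence_rejected_not_raised(self, vector_db):
        arm = dict(vector_db)["vector_arm_left"]
        out = sg.trim_vector(sg.SeqRecordSSH("t6-F", arm))
        assert out.rejected

    def test_trimming_is_idempotent(self, rng, vector_db):
        arm = dict(vector_db)["vector_arm_right"]
        rec = sg.SeqRecordSSH("t7-F", arm[:35] + _rand(rng, 160) + arm[-35:])
        once = sg.trim_vector(rec)
        twice = sg.trim_vector(once)
        assert once.trimmed_range == twice.trimmed_range
        assert once.insert == twice.insert

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            sg.trim_vector(sg.SeqRecordSSH("t8-F", ""))


class TestPairwiseEvalue:
    def test_identical_200mers_partner_level_evalue(self, rng):
        s = _rand(rng, 200)
        a, b = sg.SeqRecordSSH("a-F", s), sg.SeqRecordSSH("b-F", s)
        score, ev = sg.pairwise_evalue(a, b)
        assert score == 200
        p = sg.AlignmentParams()
        assert ev == pytest.approx(p.K * 200 * 200 * np.exp(-p.lam * 200), rel=1e-9)
        assert ev < 1e-10

    def test_symmetry(self, rng):
        s = _rand(rng, 150)
        a = sg.SeqRecordSSH("a-F", s + _rand(rng, 80))
        b = sg.SeqRecordSSH("b-F", _rand(rng, 60) + s)
        assert sg.pairwise_evalue(a, b) == sg.pairwise_evalue(b, a)

    def test_reverse_complement_detected(self, rng):
        s = _rand(rng, 200)
        a, b = sg.SeqRecordSSH("a-F", s), sg.SeqRecordSSH("b-F", _rc(s))
        score, ev = sg.pairwise_evalue(a, b)
        assert score == 200 and ev < 1e-10

    def test_random_pairs_rarely_reach_the_cutoff(self, rng):
        low = 0
        for _ in range(100):
            a = sg.SeqRecordSSH("a", _rand(rng, 200))
            b = sg.SeqRecordSSH("b", _rand(rng, 200))
            _, ev = sg.pairwise_evalue(a, b)
            if ev < 1e-10:
                low += 1
        assert low <= 1

    def test_self_score_bounded_by_match_times_length(self, rng):
        a = sg.SeqRecordSSH("a-F", _rand(rng, 123))
        score, _ = sg.pairwise_evalue(a, a)
        assert score == 123  # match * len upper bound attained on self

    def test_short_sequence_is_an_error(self, rng):
        a = sg.SeqRecordSSH("a", _rand(rng, 10))
        b = sg.SeqRecordSSH("b", _rand(rng, 200))
        with pytest.raises(ValueError, match="min_length"):
            sg.pairwise_evalue(a, b)


class TestGrouping:
    def test_direct_relation_and_singleton(self, rng):
        s = _rand(rng, 200)
        seqs = [
            sg.SeqRecordSSH("A-F", s),
            sg.SeqRecordSSH("B-F", s),
            sg.SeqRecordSSH("C-F", _rand(rng, 200)),
        ]
        groups = sg.group_redundant(seqs)
        parts = sorted(tuple(g.member_ids) for g in groups)
        assert parts == [("A-F", "B-F"), ("C-F",)]

    def test_transitive_closure_chains_groups(self, rng):
        t = _rand(rng, 450)
        a = sg.SeqRecordSSH("A-F", t[:200])      # overlaps B by 75
        b = sg.SeqRecordSSH("B-F", t[125:325])   # overlaps A and C
        c = sg.SeqRecordSSH("C-F", t[250:450])   # overlaps B by 75, not A
        _, e_ac = sg.pairwise_evalue(a, c)
        assert e_ac > 1e-10  # A and C unrelated directly
        groups = sg.group_redundant([a, b, c])
        assert len(groups) == 1
        assert sorted(groups[0].member_ids) == ["A-F", "B-F", "C-F"]

    def test_representative_is_longest_member(self, rng):
        t = _rand(rng, 300)
        short = sg.SeqRecordSSH("S-F", t[:180])
        long = sg.SeqRecordSSH("L-F", t[:240])
        groups = sg.group_redundant([short, long])
        assert groups[0].representative == "L-F"

    def test_order_invariance(self, rng):
        t1, t2 = _rand(rng, 400), _rand(rng, 400)
        seqs = [
            sg.SeqRecordSSH("A-F", t1[:220]),
            sg.SeqRecordSSH("B-F", t1[150:390]),
            sg.SeqRecordSSH("C-F", t2[:200]),
            sg.SeqRecordSSH("D-F", t2[100:330]),
            sg.SeqRecordSSH("E-F", _rand(rng, 210)),
        ]
        g1 = sg.group_redundant(seqs)
        g2 = sg.group_redundant(seqs[::-1])
        as_sets = lambda gs: [
            (g.group_id, g.representative, tuple(g.member_ids)) for g in gs
        ]
        assert as_sets(g1) == as_sets(g2)

    def test_duplicate_clone_id_rejected(self, rng):
        s = _rand(rng, 100)
        with pytest.raises(ValueError, match="duplicate"):
            sg.group_redundant([sg.SeqRecordSSH("X-F", s), sg.SeqRecordSSH("X-F", s)])

    def test_planted_partition_recovered(self, small_bundle):
        from subscreen.synthetic import partition_scores

        seqs = sg.load_fasta(small_bundle.fasta_file)
        trimmed = [sg.trim_vector(s) for s in seqs]
        kept = [s for s in trimmed if not s.rejected]
        assert len(kept) >= 0.9 * len(seqs)
        groups = sg.group_redundant(kept)
        scores = partition_scores(groups, small_bundle.truth)
        assert scores["precision"] >= 0.99
        assert scores["recall"] >= 0.99


class TestExports:
    def _groups(self, rng):
        t = _rand(rng, 300)
        a = sg.SeqRecordSSH("46D03-F", t[:240], trimmed_range=(0, 240))
        b = sg.SeqRecordSSH("46D07-F", t[:180], trimmed_range=(0, 180))
        c = sg.SeqRecordSSH("12A01-F", _rand(rng, 200), trimmed_range=(0, 200))
        return sg.group_redundant([a, b, c])

    def _toptable(self):
        return pd.DataFrame(
            {
                "ID": ["46D03-F", "46D07-F", "12A01-F", "99Z99-F"],
                "logFC(ER3)": [2.91, 2.60, 0.2, 0.0],
                "AveExpr": [10.89, 10.2, 8.0, 7.0],
                "t": [34.37, 20.0, 1.0, 0.1],
                "P.Value": [5.4e-12, 1e-9, 0.3, 0.9],
                "adj.P.Val": [1.1e-8, 1e-6, 0.5, 0.95],
                "B": [19.51, 12.0, -5.0, -6.0],
                "invER2": [-2.77, -2.5, 0.4, 0.1],
                "quadrant": ["Up.Rare", "Up.Rare", "Up.Abundant", "Up.Abundant"],
                "library": ["forward"] * 4,
            }
        )

    def test_summary_carries_representative_stats_and_count(self, rng, tmp_path):
        groups = self._groups(rng)
        written = sg.merge_annotations_export(
            groups, self._toptable(), tmp_path, what=("summary",)
        )
        summ = pd.read_csv(written["summary"], sep="\t")
        row = summ[summ["representative"] == "46D03-F"].iloc[0]
        assert row["member_count"] == 2
        assert row["er3"] == pytest.approx(2.91)
        assert row["priority_annotation"] == "none"

    def test_annotation_import_and_curation_override(self, rng, tmp_path):
        groups = self._groups(rng)
        ann = pd.DataFrame(
            {
                "clone_id": ["46D07-F", "12A01-F"],
                "hit_id": ["sp|P12345", "sp|Q99999"],
                "description": ["late embryogenesis abundant protein", "weak hit"],
                "evalue": [1e-40, 1e-3],
                "source": ["blastx", "blastx"],
            }
        )
        sg.merge_annotations_export(
            groups, self._toptable(), tmp_path, annotations=ann,
            curation={"12A01-F": "curated thaumatin"}, what=("summary", "toptable"),
        )
        summ = pd.read_csv(tmp_path / "group_summary.tsv", sep="\t")
        by_rep = summ.set_index("representative")
        # best member hit below the cutoff becomes the group annotation
        assert by_rep.loc["46D03-F", "priority_annotation"] == (
            "late embryogenesis abundant protein"
        )
        assert by_rep.loc["46D03-F", "annotation_source"] == "imported_blastx"
        # the weak (above-cutoff) hit is overridden... and curation wins anyway
        assert by_rep.loc["12A01-F", "priority_annotation"] == "curated thaumatin"
        assert by_rep.loc["12A01-F", "annotation_source"] == "manual"
        tt = pd.read_csv(tmp_path / "toptable_annotated.tsv", sep="\t")
        assert tt.set_index("ID").loc["99Z99-F", "annotation"] == "unsequenced"

    def test_fasta_export_headers(self, rng, tmp_path):
        from Bio import SeqIO

        groups = self._groups(rng)
        written = sg.merge_annotations_export(groups, None, tmp_path, what=("fasta",))
        recs = list(SeqIO.parse(str(written["fasta"]), "fasta"))
        assert {r.id for r in recs} == {"46D03-F", "12A01-F"}
        assert any("annotation=" in r.description for r in recs)
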