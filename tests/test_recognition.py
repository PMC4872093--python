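"""Recognition-code derivation, anchor mapping and target prediction."""

import pytest

from ispkit import recognition as R
from ispkit import synthetic as syn
from ispkit.msa import Msa
from ispkit.recognition import (CodeError, EnzymeTargetEntry,
                                RecognitionAnchors, derive_code,
                                map_anchor_residues, predict_target)


class TestAnchors:
    def test_default_anchors_each_in_one_element(self):
        anchors = RecognitionAnchors()
        assert anchors.element_of(1131) == "Loop III"
        assert anchors.element_of(1286) == "Helix H"
        assert anchors.element_of(1318) == "Loop V"

    def test_misplaced_anchor_rejected(self):
        with pytest.raises(CodeError):
            RecognitionAnchors(elements={"Loop I": (1017, 1027)},
                               anchors=(1131,))


class TestAnchorMapping:
    @staticmethod
    def toy_msa():
        # reference ungapped; second row has an insertion-induced gap
        rows = ["KQWRN", "K-WRN", "RQWDN"]
        msa = Msa(ids=["LlaGI", "homB", "homC"], rows=rows)
        msa.build_ref_map("LlaGI", ref_start=1130)
        return msa

    def test_reference_maps_to_itself(self):
        msa = self.toy_msa()
        anchors = RecognitionAnchors(elements={"Loop III": (1115, 1138)},
                                     anchors=(1130, 1131, 1134))
        out = map_anchor_residues(msa, anchors, "LlaGI")
        assert out["LlaGI"] == {1130: "K", 1131: "Q", 1134: "N"}

    def test_gap_reported_absent(self):
        msa = self.toy_msa()
        anchors = RecognitionAnchors(elements={"Loop III": (1115, 1138)},
                                     anchors=(1131,))
        out = map_anchor_residues(msa, anchors, "LlaGI")
        assert out["homB"] == {1131: None}
        assert out["homC"] == {1131: "Q"}

    def test_alignment_with_reference_gap_still_maps(self):
        rows = ["KQ-WR", "KQEWR"]
        msa = Msa(ids=["LlaGI", "homB"], rows=rows)
        msa.build_ref_map("LlaGI", ref_start=1130)
        anchors = RecognitionAnchors(elements={"Loop III": (1115, 1138)},
                                     anchors=(1132, 1133))
        out = map_anchor_residues(msa, anchors, "LlaGI")
        assert out["LlaGI"] == {1132: "W", 1133: "R"}
        assert out["homB"] == {1132: "W", 1133: "R"}

    def test_missing_reference_rejected(self):
        msa = self.toy_msa()
        with pytest.raises(CodeError):
            map_anchor_residues(msa, RecognitionAnchors(), "nope")


def six_perfect_entries():
    entries = []
    for i in range(6):
        entries.append(EnzymeTargetEntry(
            name=f"E{i}", target={-1: "C:G", 1: "T:A"},
            residues={1131: "K", 1118: "Q", 1226: "T"}))
    return entries


class TestDeriveCode:
    def test_perfect_association_scores_one(self):
        table = derive_code(six_perfect_entries())
        hits = [e for e in table.at(-1, "C:G") if e.anchor == 1131]
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(1.0)
        assert hits[0].support == 6

    def test_constant_residue_not_reported(self):
        # anchor 1226 is T in every enzyme while -1 varies: purity breaks
        entries = six_perfect_entries()
        for i in (0, 1, 2):
            entries[i].target[-1] = "G:C"
        table = derive_code(entries)
        assert all(e.anchor != 1226 for e in table.at(-1))

    def test_entry_order_invariance(self):
        entries, _ = syn.make_recognition_entries(n_enzymes=11, seed=3)
        a = derive_code(entries)
        b = derive_code(list(reversed(entries)))
        assert [(e.position, e.base_pair, e.anchor, e.residue, e.score)
                for e in a.entries] == \
            [(e.position, e.base_pair, e.anchor, e.residue, e.score)
             for e in b.entries]

    def test_consistent_enzyme_never_decreases_score(self):
        entries, _ = syn.make_recognition_entries(n_enzymes=11, seed=4)
        base = {(e.position, e.base_pair, e.anchor, e.residue): e.score
                for e in derive_code(entries).entries}
        extra = EnzymeTargetEntry(name="new", target=dict(entries[0].target),
                                  residues=dict(entries[0].residues))
        grown = {(e.position, e.base_pair, e.anchor, e.residue): e.score
                 for e in derive_code(entries + [extra]).entries}
        for key, score in base.items():
            if key[0] in extra.target and grown.get(key) is not None:
                if extra.target.get(key[0]) == key[1] and \
                        extra.residues.get(key[2]) == key[3]:
                    assert grown[key] >= score - 1e-12

    def test_degenerate_letters_split_weight(self):
        # y at +5 contributes half weight to T:A and C:G
        entries = [EnzymeTargetEntry(f"E{i}", {5: "Y", 1: "T:A"},
                                     {1326: "N"}) for i in range(4)]
        table = derive_code(entries, threshold=0.2)
        pairs = {e.base_pair for e in table.entries if e.position == 5}
        assert pairs == {"T:A", "C:G"}

    def test_too_few_entries_rejected(self):
        with pytest.raises(CodeError):
            derive_code(six_perfect_entries()[:2])

    def test_noise_robustness_at_panel_scale(self):
        for seed in range(10):
            entries, code = syn.make_recognition_entries(
                n_enzymes=500, seed=seed, relabel_fraction=0.10)
            found = {(e.position, e.base_pair, e.anchor, e.residue)
                     for e in derive_code(entries).entries}
            planted = {(p, bp, a, r) for (p, bp), m in code.items()
                       for a, r in m.items()}
            assert planted <= found


class TestPrediction:
    def test_lysine_1131_predicts_cg_at_minus_one(self):
        entries, _ = syn.make_recognition_entries(n_enzymes=11, seed=0)
        table = derive_code(entries)
        pred = predict_target({1131: "K"}, table)
        assert pred[-1][0] == "C:G"

    def test_training_enzyme_self_consistency(self):
        entries, _ = syn.make_recognition_entries(n_enzymes=11, seed=1)
        table = derive_code(entries)
        enzyme = entries[0]
        pred = predict_target(enzyme.residues, table)
        for pos, (bp, conf) in pred.items():
            if pos in enzyme.target and ":" in enzyme.target[pos] and bp:
                assert bp == enzyme.target[pos]

    def test_unmatched_residues_unspecified(self):
        table = derive_code(six_perfect_entries())
        pred = predict_target({1131: "W"}, table)
        assert pred[-1] == (None, 0.0)

    def test_predicted_entries_flagged_and_excluded_from_training(self):
        table = derive_code(six_perfect_entries())
        table.add_predicted(-1, "G:C", 1125, "R")
        flagged = [e for e in table.entries if e.predicted]
        assert len(flagged) == 1 and flagged[0].support == 0
        pred = predict_target({1125: "R"}, table)
        assert pred[-1] == (None, 0.0)

    def test_empty_code_rejected(self):
        with pytest.raises(CodeError):
            predict_target({1131: "K"}, R.CodeTable())


class TestEntriesIO:
    def test_tsv_round_trip(self, tmp_path):
        entries, _ = syn.make_recognition_entries(n_enzymes=5, seed=7)
        path = tmp_path / "entries.tsv"
        R.entries_to_tsv(entries, path)
        back = R.entries_from_tsv(path)
        assert [e.name for e in back] == [e.name for e in entries]
        assert all(a.target == b.target for a, b in zip(back, entries))
        assert all(a.residues == b.residues for a, b in zip(back, entries))

    def test_target_string_constructor(self):
        e = EnzymeTargetEntry.from_target_string("LlaGI", "CTNGAYG",
                                                 {1131: "K"})
        assert e.target[-1] == "C"
        assert 2 not in e.target          # the n position is unspecified
        assert e.weighted_pairs(5) == [("C:G", 0.5), ("T:A", 0.5)]
        assert e.weighted_pairs(-1) == [("C:G", 1.0)]
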