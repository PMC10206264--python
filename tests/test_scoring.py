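"""Ensemble scoring: aggregation, surrogate, table scorer and ranking."""

import numpy as np
import pytest

import bindsight as bs
from bindsight.design import CompoundSpec
from bindsight.scoring import (ReceptorEnsemble, ScoreRecord, TableScorer,
                               load_score_table, write_score_table)


def _compound(name="X", smiles="CCO"):
    return CompoundSpec(name=name, group_choice={}, smiles=smiles)


def _ensemble(structure, n=2):
    return ReceptorEnsemble(members=[(f"Cluster{i + 1}", structure)
                                     for i in range(n)])


class TestScoreCompound:
    def test_aggregate_is_minimum(self, small_complex):
        structure, _ = small_complex
        values = {"Cluster1": -9.2, "Cluster2": -10.1}
        scorer = lambda c, lbl, r: values[lbl]  # noqa: E731
        rec = bs.score_compound(_compound(), _ensemble(structure), scorer)
        assert rec.aggregate == -10.1

    def test_single_member_aggregate(self, small_complex):
        structure, _ = small_complex
        rec = bs.score_compound(_compound(), _ensemble(structure, 1),
                                lambda c, l, r: -8.5)
        assert rec.aggregate == -8.5

    def test_failures_recorded_and_all_fail_raises(self, small_complex):
        structure, _ = small_complex
        scorer = lambda c, lbl, r: None if lbl == "Cluster1" else -7.0  # noqa
        rec = bs.score_compound(_compound(), _ensemble(structure), scorer)
        assert rec.failed_members == ["Cluster1"]
        with pytest.raises(RuntimeError, match="all ensemble members"):
            bs.score_compound(_compound(), _ensemble(structure),
                              lambda c, l, r: None)

    def test_member_order_never_changes_aggregate(self, small_complex):
        structure, _ = small_complex
        rng = np.random.default_rng(0)
        labels = [f"M{i}" for i in range(6)]
        values = dict(zip(labels, rng.normal(-9, 1, 6)))
        for seed in range(20):
            order = list(labels)
            np.random.default_rng(seed).shuffle(order)
            ens = ReceptorEnsemble(members=[(l, structure) for l in order])
            rec = bs.score_compound(_compound(), ens,
                                    lambda c, l, r: values[l])
            assert rec.aggregate == min(values.values())

    def test_adding_member_never_raises_aggregate(self, small_complex):
        structure, _ = small_complex
        values = {"M1": -8.0, "M2": -9.5, "M3": -7.0}
        scorer = lambda c, l, r: values[l]  # noqa: E731
        agg = None
        for n in (1, 2, 3):
            ens = ReceptorEnsemble(
                members=[(f"M{i + 1}", structure) for i in range(n)])
            rec = bs.score_compound(_compound(), ens, scorer)
            if agg is not None:
                assert rec.aggregate <= agg
            agg = rec.aggregate


class TestSurrogate:
    def test_separated_pose_scores_near_zero(self, small_complex):
        structure, _ = small_complex
        rec_struct = structure.subset(structure.group_indices("receptor"))
        pose = bs.pose_from_smiles("CCO", center=[500.0, 0.0, 0.0], seed=1)
        score = bs.surrogate_score(pose, rec_struct)
        assert score == pytest.approx(0.0, abs=1e-3)

    def test_deterministic(self, small_complex):
        structure, _ = small_complex
        rec_struct = structure.subset(structure.group_indices("receptor"))
        pose = bs.pose_from_smiles("CCO", center=[0.0, -10.0, 0.0], seed=1)
        a = bs.surrogate_score(pose, rec_struct)
        b = bs.surrogate_score(pose, rec_struct)
        assert a == b

    def test_contact_pose_beats_displaced_poses(self, small_complex):
        """A pose at favorable contact scores lower than any pose pushed
        2 A further out along the same axis."""
        structure, _ = small_complex
        rec_struct = structure.subset(structure.group_indices("receptor"))
        pose = bs.pose_from_smiles("c1ccccc1", center=[17.0, -6.0, 0.5],
                                   seed=3)
        best = bs.surrogate_score(pose, rec_struct)
        assert best is not None and best < 0
        for direction in ([0, -2.0, 0], [0, 2.0, 0], [0, 0, 2.5]):
            moved = pose.copy()
            moved.set_coords(pose.coords + np.array(direction))
            displaced = bs.surrogate_score(moved, rec_struct)
            assert displaced is None or best < displaced

    def test_clash_declares_failure_not_exception(self, small_complex):
        structure, _ = small_complex
        rec_struct = structure.subset(structure.group_indices("receptor"))
        pose = bs.pose_from_smiles("CCO", center=rec_struct.coords[0], seed=1)
        assert bs.surrogate_score(pose, rec_struct) is None


class TestTableScorer:
    def test_lookup_and_missing_pair(self, small_complex, tmp_path):
        structure, _ = small_complex
        path = tmp_path / "scores.tsv"
        path.write_text("compound\tmember\tscore\n"
                        "Abe\tCluster1\t-9.31\nAbe\tCluster2\t-9.46\n")
        scorer = load_score_table(path)
        rec = bs.score_compound(_compound("Abe"), _ensemble(structure),
                                scorer)
        assert rec.aggregate == pytest.approx(-9.46)
        assert scorer(_compound("Nope"), "Cluster1", structure) is None

    def test_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("A\tM\t-1.0\nA\tM\t-2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_score_table(path)

    def test_malformed_row_cites_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tM\t-1.0\nB\tM\n")
        with pytest.raises(ValueError, match=":2"):
            load_score_table(path)

    def test_round_trip(self, tmp_path):
        table = {("A", "M1"): -9.1, ("B", "M2"): -10.5}
        path = tmp_path / "t.tsv"
        write_score_table(table, path)
        back = load_score_table(path)
        assert back.table == table


class TestRanking:
    def _records(self, scores):
        return [ScoreRecord(name=n, per_member={"M": s}, aggregate=s)
                for n, s in scores.items()]

    def test_shortlist_at_threshold(self):
        ranked, shortlist = bs.rank_and_shortlist(
            self._records({"a": -10.03, "b": -9.78, "c": -9.46}),
            threshold=-10.0)
        assert [r.name for r in shortlist] == ["a"]
        assert [r.aggregate for r in ranked] == [-10.03, -9.78, -9.46]

    def test_empty_records(self):
        ranked, shortlist = bs.rank_and_shortlist([])
        assert ranked == [] and shortlist == []

    def test_ties_resolve_lexically_and_stably(self):
        records = self._records({"z": -9.0, "a": -9.0, "m": -9.0})
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = list(records)
            rng.shuffle(shuffled)
            ranked, _ = bs.rank_and_shortlist(shuffled, threshold=-100.0)
            assert [r.name for r in ranked] == ["a", "m", "z"]
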