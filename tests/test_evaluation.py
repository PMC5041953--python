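import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ilncsim import (
    AssocGenParams,
    DagGenParams,
    Pipeline,
    build_dag_from_edges,
    generate_associations,
    generate_dag,
    global_loocv,
    kfold_cv,
    rank_candidates,
    read_associations,
    roc_auc,
    to_matrix,
)
from ilncsim.exceptions import IlncsimError

from oracles import auc_pair_counting


class TestRocAuc:
    def test_perfect_separation(self):
        auc, points = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_tie_gets_half_credit(self):
        # 6-point toy vector with one positive/negative tie at 0.5
        scores = [0.9, 0.5, 0.5, 0.4, 0.3, 0.1]
        labels = [1, 1, 0, 0, 1, 0]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pair_counting(scores, labels))

    def test_single_class_is_error(self):
        with pytest.raises(IlncsimError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(int)
        _, points = roc_auc(scores, labels)
        fprs = [p[0] for p in points]
        tprs = [p[1] for p in points]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.booleans()),
                    min_size=4, max_size=40).filter(
               lambda v: 0 < sum(l for _, l in v) < len(v)))
    def test_auc_equals_pair_counting_oracle(self, pairs):
        scores = [s / 5 for s, _ in pairs]
        labels = [int(l) for _, l in pairs]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_random_scores_average_half(self):
        rng = np.random.default_rng(123)
        labels = np.array([1] * 30 + [0] * 300)
        aucs = [roc_auc(rng.random(labels.size), labels)[0] for _ in range(300)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)


def _toy_pipeline():
    dag = build_dag_from_edges([("R", "A"), ("R", "B"), ("A", "C"), ("A", "D"), ("B", "E")])
    return Pipeline(dag=dag)


class TestGlobalLoocv:
    def test_fold_bookkeeping_on_two_by_two(self):
        table = read_associations(io.StringIO("l1\tC\nl2\tD\n"))
        result = global_loocv(table, _toy_pipeline())
        # two associations -> two folds; candidate pool = the 2 unknown pairs
        assert len(result.auc_values) == 2
        assert result.method == "global_loocv"
        assert 0.0 <= result.mean_auc <= 1.0

    def test_needs_two_associations(self):
        table = read_associations(io.StringIO("l1\tC\nl2\tC\n"))
        # the two records share disease C -> two associations, fine;
        # a single-record table must fail
        single = read_associations(io.StringIO("l1\tC\n"))
        with pytest.raises(IlncsimError):
            global_loocv(single, _toy_pipeline())

    def test_loocv_invariant_to_order_preserving_rename(self):
        """Pure renaming (same sort order) leaves every fold untouched."""
        base = "l1\tC\nl1\tD\nl2\tD\nl2\tE\nl3\tC\n"
        renamed = base.replace("l1", "a1").replace("l2", "b2").replace("l3", "c3")
        r1 = global_loocv(read_associations(io.StringIO(base)), _toy_pipeline())
        r2 = global_loocv(read_associations(io.StringIO(renamed)), _toy_pipeline())
        assert r1.auc_values == r2.auc_values

    def test_loocv_invariant_to_reordering_relabel(self):
        """Renames that reshuffle the row order only move folds around;
        the pooled AUC is unchanged (up to floating-point tie jitter)."""
        dag = generate_dag(DagGenParams(seed=2))
        synth = generate_associations(dag, AssocGenParams(
            n_lncrnas=8, n_modules=2, diseases_per_module=4, seed=2))
        r1 = global_loocv(synth.table, Pipeline(dag=dag))
        from ilncsim import AssociationRecord, AssociationTable

        rename = {lnc: f"z{-int(lnc[1:]) + 99:02d}" for lnc in synth.table.lncrna_index}
        flipped = AssociationTable(records=[
            AssociationRecord(rename[r.lncrna], r.disease)
            for r in synth.table.records])
        r2 = global_loocv(flipped, Pipeline(dag=dag))
        assert r2.mean_auc == pytest.approx(r1.mean_auc, abs=1e-9)
        assert sorted(r2.auc_values) == pytest.approx(sorted(r1.auc_values), abs=1e-9)

    def test_planted_signal_recovered(self):
        """Modules planted under shared ancestors must be recoverable:
        mean LOOCV AUC clearly above chance on default generator settings."""
        aucs = []
        for seed in range(3):
            dag = generate_dag(DagGenParams(seed=seed))
            synth = generate_associations(dag, AssocGenParams(seed=seed))
            aucs.append(global_loocv(synth.table, Pipeline(dag=dag)).mean_auc)
        assert np.mean(aucs) > 0.65


class TestKfold:
    def _table(self, n=10):
        rows = [f"l{i}\t{'CDE'[i % 3]}" for i in range(n)]
        return read_associations(io.StringIO("\n".join(rows)))

    def test_partition_validity(self):
        """Every association held out exactly once per repetition."""
        table = self._table(10)
        result = kfold_cv(table, _toy_pipeline(), k=5, repetitions=1, seed=0)
        assert len(result.auc_values) == 5

    def test_same_seed_identical_results(self):
        table = self._table(10)
        r1 = kfold_cv(table, _toy_pipeline(), k=5, repetitions=2, seed=7)
        r2 = kfold_cv(table, _toy_pipeline(), k=5, repetitions=2, seed=7)
        assert r1.auc_values == r2.auc_values

    def test_different_seed_different_partition(self):
        table = self._table(12)
        r1 = kfold_cv(table, _toy_pipeline(), k=4, repetitions=1, seed=1)
        r2 = kfold_cv(table, _toy_pipeline(), k=4, repetitions=1, seed=2)
        assert r1.auc_values != r2.auc_values

    def test_fewer_associations_than_k_is_error(self):
        table = self._table(3)
        with pytest.raises(IlncsimError):
            kfold_cv(table, _toy_pipeline(), k=5)

    def test_std_shrinks_with_more_repetitions(self):
        """Standard error of the mean AUC decreases as repetitions grow."""
        dag = generate_dag(DagGenParams(n_terms=25, seed=0))
        synth = generate_associations(dag, AssocGenParams(
            n_lncrnas=10, n_modules=2, diseases_per_module=4, seed=0))
        r_few = kfold_cv(synth.table, Pipeline(dag=dag), k=3, repetitions=2, seed=0)
        r_many = kfold_cv(synth.table, Pipeline(dag=dag), k=3, repetitions=8, seed=0)
        sem_few = r_few.std_auc / np.sqrt(len(r_few.auc_values))
        sem_many = r_many.std_auc / np.sqrt(len(r_many.auc_values))
        assert sem_many < sem_few

    def test_planted_beats_shuffled(self):
        from ilncsim import shuffle_associations

        dag = generate_dag(DagGenParams(seed=4))
        synth = generate_associations(dag, AssocGenParams(seed=4))
        planted = kfold_cv(synth.table, Pipeline(dag=dag), k=5, repetitions=2, seed=0)
        null = kfold_cv(shuffle_associations(synth.table, 99), Pipeline(dag=dag),
                        k=5, repetitions=2, seed=0)
        assert planted.mean_auc > null.mean_auc + 0.1


class TestRankCandidates:
    def test_all_known_gives_empty_list(self, toy6):
        table = read_associations(io.StringIO("l1\tC\nl2\tC\n"))
        pipe = Pipeline(dag=toy6)
        pipe.prepare(table)
        scores = pipe.scores()
        assert rank_candidates(scores, pipe.adjacency, "c" if "c" in scores.col_labels
                               else "C") == []

    def test_order_matches_scores(self):
        from ilncsim import ScoreMatrix, AdjacencyMatrix

        scores = ScoreMatrix(row_labels=["l1", "l2", "l3"], col_labels=["d"],
                             values=np.array([[0.2], [0.9], [0.5]]))
        adj = AdjacencyMatrix(lncrna_ids=["l1", "l2", "l3"], disease_ids=["d"],
                              values=np.zeros((3, 1), dtype=int))
        ranked = rank_candidates(scores, adj, "d", top_k=3)
        assert [r[1] for r in ranked] == ["l2", "l3", "l1"]
        assert [r[0] for r in ranked] == [1, 2, 3]

    def test_tie_broken_lexicographically(self):
        from ilncsim import ScoreMatrix, AdjacencyMatrix

        scores = ScoreMatrix(row_labels=["lb", "la"], col_labels=["d"],
                             values=np.array([[0.5], [0.5]]))
        adj = AdjacencyMatrix(lncrna_ids=["la", "lb"], disease_ids=["d"],
                              values=np.zeros((2, 1), dtype=int))
        ranked = rank_candidates(scores, adj, "d")
        assert [r[1] for r in ranked] == ["la", "lb"]

    def test_planted_partner_outranks_outsiders(self):
        """Held-out within-module association should beat most cross-module
        candidates in the ranking for its disease."""
        wins = []
        for seed in range(7):
            dag = generate_dag(DagGenParams(seed=seed))
            synth = generate_associations(dag, AssocGenParams(seed=seed))
            pipe = Pipeline(dag=dag)
            adj = pipe.prepare(synth.table)
            Y = adj.values.copy()
            # hold out the first within-module pair whose lncRNA keeps at
            # least one other association (otherwise its disease group is
            # empty and there is nothing left to generalize from)
            i, j = next(
                (int(a), int(b)) for a, b in np.argwhere(Y == 1)
                if Y[a].sum() >= 2
                and adj.disease_ids[b] in synth.module_diseases[
                    synth.lncrna_modules[adj.lncrna_ids[a]]])
            lnc, dis = adj.lncrna_ids[i], adj.disease_ids[j]
            Y[i, j] = 0
            scores = pipe.scores(Y)
            from ilncsim import AdjacencyMatrix
            fold_adj = AdjacencyMatrix(lncrna_ids=adj.lncrna_ids,
                                       disease_ids=adj.disease_ids, values=Y)
            ranked = rank_candidates(scores, fold_adj, dis, top_k=len(adj.lncrna_ids))
            ranked = [r for r in ranked if r[1] == lnc or
                      synth.lncrna_modules[r[1]] != synth.lncrna_modules[lnc]]
            pos = [idx for idx, r in enumerate(ranked) if r[1] == lnc][0]
            wins.append(1 - pos / max(len(ranked) - 1, 1))
        assert np.median(wins) >= 0.8

    def test_unknown_disease_is_error(self):
        from ilncsim import ScoreMatrix, AdjacencyMatrix
        from ilncsim.exceptions import UnknownTermError

        scores = ScoreMatrix(row_labels=["l1"], col_labels=["d"],
                             values=np.array([[0.1]]))
        adj = AdjacencyMatrix(lncrna_ids=["l1"], disease_ids=["d"],
                              values=np.zeros((1, 1), dtype=int))
        with pytest.raises(UnknownTermError):
            rank_candidates(scores, adj, "nope")
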