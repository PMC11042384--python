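"""Fold construction, metrics, model comparison, ranking and association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from guidescreen.evaluation import (
    auc,
    bh_adjust,
    compare_models,
    cross_cell_evaluate,
    fitness_expression_association,
    make_grouped_folds,
    rank_within_dhs,
)


def brute_force_auc(scores, labels):
    """All positive-negative pair enumeration with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestGroupedFolds:
    def _records(self, groups):
        return pd.DataFrame({
            "guide_id": [f"g{i}" for i in range(len(groups))],
            "dhs_id": groups,
        })

    def test_balanced_construction(self):
        groups = np.repeat([f"d{i}" for i in range(10)], 10)
        fa = make_grouped_folds(self._records(groups), "dhs_id", k=5, seed=0)
        counts = fa.folds.value_counts()
        assert (counts == 20).all()
        per_fold_groups = {f: set(fa.folds.index[fa.folds == f]) for f in range(1, 6)}
        assert sum(len(v) for v in per_fold_groups.values()) == 100

    def test_five_chromosomes_one_each(self):
        rec = pd.DataFrame({
            "guide_id": [f"g{i}" for i in range(25)],
            "chrom": np.repeat([f"chr{i}" for i in range(5)], 5),
        })
        fa = make_grouped_folds(rec, "chrom", k=5, seed=1)
        chrom_folds = rec.assign(fold=fa.folds.to_numpy()).groupby("chrom")["fold"].nunique()
        assert (chrom_folds == 1).all()
        assert rec.assign(fold=fa.folds.to_numpy())["fold"].nunique() == 5

    def test_fewer_groups_than_folds_errors(self):
        with pytest.raises(ValueError, match="groups"):
            make_grouped_folds(self._records(["a", "b", "a"]), "dhs_id", k=5)

    def test_pairwise_group_disjointness_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_groups = int(rng.integers(5, 40))
            sizes = rng.integers(1, 12, size=n_groups)
            groups = np.repeat([f"d{i}" for i in range(n_groups)], sizes)
            rec = self._records(groups)
            fa = make_grouped_folds(rec, "dhs_id", k=5, seed=int(rng.integers(1 << 30)))
            assigned = rec.assign(fold=fa.folds.to_numpy())
            group_sets = [set(assigned.loc[assigned["fold"] == f, "dhs_id"]) for f in range(1, 6)]
            for a, b in itertools.combinations(group_sets, 2):
                assert not (a & b)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_six_point_hand_case(self):
        # 9 positive-negative pairs, 8 correctly ordered
        value = auc([0.9, 0.8, 0.7, 0.4, 0.3, 0.2], [1, 1, 0, 1, 0, 0])
        assert value == pytest.approx(8 / 9)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(20000)
        labels = rng.integers(0, 2, 20000)
        assert abs(auc(scores, labels) - 0.5) < 0.02

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(6, 200))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


class TestCompareModels:
    def test_identical_vectors(self):
        metrics = pd.DataFrame({"m1": [0.7] * 5, "m2": [0.7] * 5})
        row = compare_models(metrics).iloc[0]
        assert row["t_statistic"] == 0.0
        assert row["p_value"] == 1.0

    def test_zero_variance_difference_warns(self):
        metrics = pd.DataFrame({"m1": [0.7, 0.8, 0.9], "m2": [0.6, 0.7, 0.8]})
        with pytest.warns(UserWarning, match="zero-variance"):
            row = compare_models(metrics).iloc[0]
        assert row["p_value"] == 0.0

    def test_three_models_bh_hand_computation(self):
        rng = np.random.default_rng(3)
        metrics = pd.DataFrame(rng.random((5, 3)), columns=["a", "b", "c"])
        table = compare_models(metrics)
        assert len(table) == 3
        raw = table["p_value"].to_numpy()
        m = 3
        order = np.argsort(raw)
        hand = np.empty(m)
        prev = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            prev = min(prev, raw[idx] * m / rank)
            hand[idx] = prev
        np.testing.assert_allclose(table["adj_p"].to_numpy(), hand)

    def test_unequal_fold_counts_rejected(self):
        metrics = pd.DataFrame({"a": [0.1, 0.2, np.nan], "b": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="missing"):
            compare_models(metrics)


class TestBhProperties:
    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20))
    def test_monotone_and_bounded(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(pvals)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


class TestRankWithinDhs:
    def _tables(self, probs, adj_p, lfc, dhs="d1", labels=None):
        n = len(probs)
        ids = [f"g{i}" for i in range(n)]
        preds = pd.DataFrame({"guide_id": ids, "score": probs})
        if labels is None:
            labels = ["significant" if p < 0.05 else "insignificant" for p in adj_p]
        outs = pd.DataFrame({"guide_id": ids, "dhs_id": dhs, "adj_p": adj_p,
                             "log2FC": lfc, "label": labels})
        return preds, outs

    def test_top1_is_argmax(self):
        preds, outs = self._tables([0.9, 0.5, 0.1], [0.01, 0.01, 0.01], [1.0, 0.5, 0.2],
                                   labels=["significant"] * 3)
        table, _ = rank_within_dhs(preds, outs, min_sig=3, k=1)
        assert table.loc[table["is_top"], "guide_id"].tolist() == ["g0"]

    def test_min_sig_filter_drops_dhs(self):
        preds, outs = self._tables([0.9, 0.5, 0.1], [0.01, 0.5, 0.5], [1.0, 0.1, 0.1])
        with pytest.raises(ValueError, match="significant"):
            rank_within_dhs(preds, outs, min_sig=3, k=1)

    def test_tie_break_deterministic(self):
        preds, outs = self._tables([0.5, 0.5, 0.5], [0.01] * 3, [0.3, 0.9, 0.3],
                                   labels=["significant"] * 3)
        t1, _ = rank_within_dhs(preds, outs, min_sig=3, k=1)
        t2, _ = rank_within_dhs(preds, outs, min_sig=3, k=1)
        top1 = t1.loc[t1["is_top"], "guide_id"].tolist()
        assert top1 == t2.loc[t2["is_top"], "guide_id"].tolist()
        assert top1 == ["g1"]  # largest |log2FC| among tied scores

    def test_oracle_predictions_enrich_top1(self):
        rng = np.random.default_rng(5)
        rows = []
        for d in range(40):
            for g in range(6):
                effect = rng.random() < 0.5
                rows.append({
                    "guide_id": f"d{d}g{g}", "dhs_id": f"d{d}",
                    "score": 0.9 if effect else 0.1,
                    "adj_p": rng.uniform(0, 0.05) if effect else rng.uniform(0.2, 1),
                    "log2FC": rng.normal(1.0 if effect else 0.0, 0.1),
                    "label": "significant" if effect else "insignificant",
                })
        df = pd.DataFrame(rows)
        preds = df[["guide_id", "score"]]
        outs = df.drop(columns="score")
        _, stats = rank_within_dhs(preds, outs, min_sig=3, k=1)
        assert stats["top_prop_sig"] > stats["rest_prop_sig"]
        assert stats["top_q3_abs_log2fc"] > stats["rest_q3_abs_log2fc"]


class TestAssociation:
    def _from_table(self, a, b, c, d):
        """Build guide-level fitness + single-gene pair tables realizing [[a,b],[c,d]]."""
        rows_fit, rows_expr = [], []
        i = 0
        for count, fit_sig, expr_sig in [(a, True, True), (b, True, False),
                                         (c, False, True), (d, False, False)]:
            for _ in range(count):
                gid = f"g{i}"; i += 1
                rows_fit.append({"guide_id": gid,
                                 "label": "significant" if fit_sig else "insignificant"})
                rows_expr.append({"guide_id": gid, "gene_id": "x",
                                  "adj_p": 0.01 if expr_sig else 0.9})
        return pd.DataFrame(rows_fit), pd.DataFrame(rows_expr)

    def test_balanced_table_or_one(self):
        fit, expr = self._from_table(10, 10, 10, 10)
        res = fitness_expression_association(fit, expr)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_hand_case_or_sixteen(self):
        fit, expr = self._from_table(20, 5, 5, 20)
        res = fitness_expression_association(fit, expr)
        assert res["odds_ratio"] == pytest.approx(16.0)
        np.testing.assert_array_equal(res["table"], [[20, 5], [5, 20]])

    def test_zero_cell_haldane_flagged(self):
        fit, expr = self._from_table(10, 0, 5, 20)
        res = fitness_expression_association(fit, expr)
        assert res["haldane_corrected"]
        assert np.isfinite(res["odds_ratio"])

    def test_empty_intersection_errors(self):
        fit = pd.DataFrame({"guide_id": ["a"], "label": ["significant"]})
        expr = pd.DataFrame({"guide_id": ["b"], "gene_id": ["x"], "adj_p": [0.01]})
        with pytest.raises(ValueError, match="shared"):
            fitness_expression_association(fit, expr)

    def test_multi_gene_enrichment_table_present(self):
        rng = np.random.default_rng(0)
        rows_fit, rows_expr = [], []
        for i in range(120):
            sig = i < 60
            rows_fit.append({"guide_id": f"g{i}", "label": "significant" if sig else "insignificant"})
            for j in range(6):
                p_sig = rng.random() < (0.7 if sig else 0.2)
                rows_expr.append({"guide_id": f"g{i}", "gene_id": f"gene{j}",
                                  "adj_p": 0.05 if p_sig else 0.9})
        res = fitness_expression_association(pd.DataFrame(rows_fit), pd.DataFrame(rows_expr))
        assert res["multi_gene"]["odds_ratio"] > 1
        assert set(res["per_guide_sig_gene_counts"].columns) == {"guide_id", "fit_sig", "n_sig_genes"}


class TestCrossCell:
    @staticmethod
    def _context(seed, flip=False, n=600):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)])
        sign = -1.0 if flip else 1.0
        logits = sign * (1.5 * X["f0"] + 1.0 * X["f1"])
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float).to_numpy()
        records = pd.DataFrame({"guide_id": [f"g{i}" for i in range(n)],
                                "dhs_id": [f"d{i % 40}" for i in range(n)]})
        return {"records": records, "X": X, "y": y}

    @staticmethod
    def _fit(X, y, seed):
        from guidescreen.boost import fit_xgb
        return fit_xgb(X, y, "fitness", n_rounds=40, seed=seed)

    @staticmethod
    def _predict(model, X):
        from guidescreen.boost import predict_xgb
        return predict_xgb(model, X)

    def test_shared_mechanism_transfers(self):
        data = {"k562": self._context(1), "ipsc": self._context(2)}
        mat = cross_cell_evaluate(data, self._fit, self._predict, seed=0)
        assert mat.loc["k562", "ipsc"] > 0.75
        assert abs(mat.loc["k562", "ipsc"] - mat.loc["ipsc", "ipsc"]) < 0.1

    def test_flipped_effects_transfer_below_chance(self):
        data = {"a": self._context(3), "b": self._context(4, flip=True)}
        mat = cross_cell_evaluate(data, self._fit, self._predict, seed=0)
        assert mat.loc["a", "b"] < 0.5
        assert mat.loc["b", "b"] > 0.7

    def test_feature_mismatch_rejected(self):
        a = self._context(5)
        b = self._context(6)
        b["X"] = b["X"].rename(columns={"f0": "other"})
        with pytest.raises(ValueError, match="manifest"):
            cross_cell_evaluate({"a": a, "b": b}, self._fit, self._predict)
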