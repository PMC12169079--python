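"""Transcript rollup, clone-positive calling, bleed-through quantification,
expression summaries and differential expression."""

import numpy as np
import pandas as pd
import pytest

from clonescape import clone_calling as cc
from clonescape.clone_calling import CloneCallConfig
from clonescape.synthetic import TranscriptSimParams, generate_transcripts

from conftest import simple_cells_df


def tx_table(rows):
    """rows: (feature, cell_id or None, qv)"""
    return pd.DataFrame({
        "transcript_id": [f"t{i}" for i in range(len(rows))],
        "feature_name": [r[0] for r in rows],
        "x_um": 0.0,
        "y_um": 0.0,
        "cell_id": [r[1] for r in rows],
        "qv": [r[2] if len(r) > 2 else 30.0 for r in rows],
    })


def bh_oracle(p):
    """Step-up Benjamini-Hochberg (independent of statsmodels)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestAggregate:
    def test_no_transcripts_all_zero(self):
        cells = simple_cells_df(3)
        counts, unassigned = cc.aggregate_transcripts(tx_table([]), cells)
        assert counts.shape[0] == 3 and counts.to_numpy().sum() == 0
        assert unassigned.sum() == 0

    def test_counts_match_generator_without_bleed(self):
        cells = simple_cells_df(300, seed=1)
        cells["true_clone"] = None
        cells.loc[:30, "true_clone"] = "clone1"
        params = TranscriptSimParams(
            panel=("clone1", "CD8A"),
            mean_counts={"clone1": {"self": 4.0, "default": 0.0},
                         "CD8A": {"CD8_T": 2.0}},
            clone_probe_names=("clone1",), bleedthrough_rate=0.0, seed=1)
        tx, _ = generate_transcripts(cells, params)
        counts, _ = cc.aggregate_transcripts(tx, cells, min_qv=20.0)
        expected = tx.groupby(["source_cell_id", "feature_name"]).size().unstack(
            fill_value=0).reindex(counts.index, fill_value=0)
        assert (counts[expected.columns].to_numpy() == expected.to_numpy()).all()

    def test_min_qv_filters_counts_not_unassigned(self):
        cells = simple_cells_df(2)
        tx = tx_table([("g", "c000000", 10.0), ("g", None, 10.0)])
        counts, unassigned = cc.aggregate_transcripts(tx, cells, min_qv=50.0)
        assert counts.to_numpy().sum() == 0
        assert unassigned["g"] == 1

    def test_orphan_cell_ids_rejected(self):
        cells = simple_cells_df(2)
        with pytest.raises(ValueError, match="ghost"):
            cc.aggregate_transcripts(tx_table([("g", "ghost", 30.0)]), cells)

    def test_conservation_of_tallies(self):
        cells = simple_cells_df(5)
        rows = [("g", "c000001", 30.0)] * 7 + [("g", None, 30.0)] * 3
        counts, unassigned = cc.aggregate_transcripts(tx_table(rows), cells)
        assert counts.to_numpy().sum() + unassigned.sum() == 10


class TestCallTcrPositive:
    config = CloneCallConfig(clone_probe_names=("clone1", "clone2"),
                             eligible_cell_type="CD8_T")

    @staticmethod
    def counts_for(cells, mapping):
        counts = pd.DataFrame(0, index=pd.Index(cells["cell_id"], name="cell_id"),
                              columns=["clone1", "clone2", "CD8A"])
        for cid, (c1, c2) in mapping.items():
            counts.loc[cid, ["clone1", "clone2"]] = [c1, c2]
        return counts

    def test_simple_positive_call(self):
        cells = simple_cells_df(3)
        counts = self.counts_for(cells, {"c000000": (2, 0)})
        called, summary = cc.call_tcr_positive(cells, counts, self.config)
        assert called.loc[0, "tcr_status"] == "tcr_pos"
        assert called.loc[0, "clone"] == "clone1"
        assert summary["n_tcr_pos"] == 1
        assert summary["per_clone_frequency"]["clone1"] == pytest.approx(1 / 3)

    def test_non_eligible_cells_never_positive(self):
        cells = simple_cells_df(3, cell_type="hepatocyte")
        cells.loc[2, "cell_type"] = "CD8_T"
        counts = self.counts_for(cells, {"c000000": (5, 0)})
        called, summary = cc.call_tcr_positive(cells, counts, self.config)
        assert called.loc[0, "tcr_status"] == "tcr_neg"
        assert summary["n_tcr_pos"] == 0

    def test_tie_is_ambiguous_but_positive(self):
        cells = simple_cells_df(2)
        counts = self.counts_for(cells, {"c000000": (1, 1)})
        called, summary = cc.call_tcr_positive(cells, counts, self.config)
        assert called.loc[0, "tcr_status"] == "ambiguous"
        assert called.loc[0, "clone"] is None
        assert summary["n_tcr_pos"] == 1
        assert summary["per_clone_counts"] == {"clone1": 0, "clone2": 0}

    def test_monotone_in_min_transcripts(self):
        rng = np.random.default_rng(2)
        cells = simple_cells_df(200)
        counts = pd.DataFrame(
            rng.poisson(0.8, size=(200, 2)),
            index=pd.Index(cells["cell_id"], name="cell_id"),
            columns=["clone1", "clone2"])
        prev = None
        for mt in (1, 2, 3, 4):
            cfg = CloneCallConfig(clone_probe_names=("clone1", "clone2"),
                                  min_transcripts=mt)
            called, _ = cc.call_tcr_positive(cells, counts, cfg)
            pos = set(called.loc[called["tcr_status"] != "tcr_neg", "cell_id"])
            if prev is not None:
                assert pos <= prev
            prev = pos

    def test_no_eligible_cells_rejected(self):
        cells = simple_cells_df(3, cell_type="hepatocyte")
        counts = self.counts_for(cells, {})
        with pytest.raises(ValueError, match="eligible"):
            cc.call_tcr_positive(cells, counts, self.config)


class TestBleedthrough:
    def test_hand_counted_outside_fraction(self):
        # 45 of 100 clone transcripts land in CD8 cells -> outside = 0.55
        cells = simple_cells_df(2)
        cells.loc[1, "cell_type"] = "hepatocyte"
        rows = [("clone1", "c000000", 30.0)] * 45 + \
               [("clone1", "c000001", 30.0)] * 55
        res = cc.bleedthrough_fraction(tx_table(rows), cells, ("clone1",))
        assert res["pooled"]["eligible_share"] == pytest.approx(0.45)
        assert res["pooled"]["outside_eligible_fraction"] == pytest.approx(0.55)

    def test_zero_bleed_confined_to_eligible(self):
        cells = simple_cells_df(100, seed=4)
        cells["true_clone"] = None
        cells.loc[:20, "true_clone"] = "clone1"
        params = TranscriptSimParams(
            panel=("clone1",),
            mean_counts={"clone1": {"self": 3.0, "default": 0.0}},
            clone_probe_names=("clone1",), bleedthrough_rate=0.0, seed=4)
        tx, _ = generate_transcripts(cells, params)
        res = cc.bleedthrough_fraction(tx, cells, ("clone1",))
        assert res["pooled"]["outside_eligible_fraction"] == 0.0

    def test_unassigned_share(self):
        cells = simple_cells_df(1)
        rows = [("clone1", "c000000", 30.0)] * 8 + [("clone1", None, 30.0)] * 2
        res = cc.bleedthrough_fraction(tx_table(rows), cells, ("clone1",))
        assert res["pooled"]["unassigned_share"] == pytest.approx(0.2)
        assert res["clone1"]["n_transcripts"] == 10


class TestExpressionSummary:
    @staticmethod
    def counts(n, rates, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({g: rng.poisson(r, n) for g, r in rates.items()},
                            index=pd.Index([f"c{i}" for i in range(n)],
                                           name="cell_id"))

    def test_everyone_expressing_gives_100pct(self):
        counts = self.counts(50, {"g": 5.0})
        counts["g"] += 1  # guarantee >= 1
        df = cc.expression_summary(counts, {"grp": counts.index}, ("g",))
        assert df["pct_expressing"].iloc[0] == 100.0

    def test_identical_groups_have_zero_scaled_means(self):
        counts = self.counts(100, {"g": 2.0, "h": 1.0})
        half = counts.iloc[:50]
        both = pd.concat([half, half.set_index("x" + half.index)])
        df = cc.expression_summary(
            both, {"a": half.index, "b": "x" + half.index}, ("g", "h"))
        assert (df["scaled_mean_expression"] == 0).all()

    def test_overlapping_groups_rejected(self):
        counts = self.counts(10, {"g": 1.0})
        with pytest.raises(ValueError, match="disjoint"):
            cc.expression_summary(counts, {"a": counts.index[:5],
                                           "b": counts.index[3:]}, ("g",))

    def test_unknown_gene_rejected(self):
        counts = self.counts(10, {"g": 1.0})
        with pytest.raises(ValueError, match="panel"):
            cc.expression_summary(counts, {"a": counts.index}, ("zz",))

    def test_binomial_recovery_of_pct_expressing(self):
        # Poisson rate chosen so P(count >= 1) = 0.35
        rate = -np.log(1 - 0.35)
        counts = self.counts(2000, {"CXCR6": rate}, seed=8)
        df = cc.expression_summary(counts, {"g": counts.index}, ("CXCR6",))
        assert df["pct_expressing"].iloc[0] == pytest.approx(35.0, abs=3.0)


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        counts = TestExpressionSummary.counts(60, {"g": 2.0, "h": 0.5}, seed=3)
        deg = cc.differential_expression(counts, counts.copy())
        assert (deg["log2_fold_change"].abs() < 1e-12).all()
        assert not deg["significant"].any()

    def test_group_size_minimum(self):
        counts = TestExpressionSummary.counts(10, {"g": 1.0})
        with pytest.raises(ValueError):
            cc.differential_expression(counts.iloc[:2], counts.iloc[2:])

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(9)
        pos = TestExpressionSummary.counts(40, {f"g{i}": rng.uniform(0.2, 3)
                                                for i in range(15)}, seed=10)
        neg = TestExpressionSummary.counts(60, {f"g{i}": rng.uniform(0.2, 3)
                                                for i in range(15)}, seed=11)
        deg = cc.differential_expression(pos, neg)
        assert (deg["p_adj"] >= deg["p_value"] - 1e-12).all()
        assert ((deg["p_adj"] >= 0) & (deg["p_adj"] <= 1)).all()

    def test_bh_matches_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(multipletests(p, method="fdr_bh")[1],
                               bh_oracle(p))

    def test_known_fold_change_detected(self):
        rng = np.random.default_rng(13)
        genes = {f"g{i}": 1.0 for i in range(10)}
        pos = TestExpressionSummary.counts(150, genes | {"target": 2.4}, seed=14)
        neg = TestExpressionSummary.counts(1500, genes | {"target": 1.0}, seed=15)
        deg = cc.differential_expression(pos, neg).set_index("gene")
        assert deg.loc["target", "log2_fold_change"] == pytest.approx(
            np.log2(2.4), abs=0.3)
        assert deg.loc["target", "significant"]


class TestMaitCoexpression:
    def test_absent_gene_rejected(self):
        counts = TestExpressionSummary.counts(5, {"KLRB1": 1.0})
        with pytest.raises(ValueError):
            cc.mait_coexpression(counts)

    def test_no_trav_expression_gives_zero(self):
        counts = TestExpressionSummary.counts(50, {"KLRB1": 2.0, "TRAV1-2": 0.0})
        res = cc.mait_coexpression(counts)
        assert res["frac_coexpressing"] == 0.0

    def test_all_coexpressing_gives_one(self):
        counts = TestExpressionSummary.counts(20, {"KLRB1": 1.0, "TRAV1-2": 1.0})
        counts[:] = counts + 1
        assert cc.mait_coexpression(counts)["frac_coexpressing"] == 1.0

    def test_independent_rates_product(self):
        rng = np.random.default_rng(16)
        n = 20000
        counts = pd.DataFrame({
            "KLRB1": rng.binomial(1, 0.47, n),
            "TRAV1-2": rng.binomial(1, 0.05, n)})
        res = cc.mait_coexpression(counts)
        expect = 0.47 * 0.05
        sd = np.sqrt(expect * (1 - expect) / n)
        assert abs(res["frac_coexpressing"] - expect) <= 3 * sd
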