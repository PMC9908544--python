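"""Layer-specific calling rules: thresholds, roll-up, metabolite rules,
cluster-wise single-cell calls and dot-plot statistics."""

import numpy as np
import pandas as pd
import pytest

from permomics import (
    GroupDesign,
    PeptideProteinMap,
    RunConfig,
    SynthSpec,
    ValidationError,
    call_cluster_degs,
    call_dems,
    call_threshold,
    detection_table,
    dotplot_stats,
    gen_single_cell,
    quantified_filter,
    rollup_proteins,
)

from conftest import make_matrix


def results_frame(rows):
    """rows: (feature_id, Pt, Pf, Pcom, direction)"""
    return pd.DataFrame(rows, columns=["feature_id", "Pt", "Pf", "Pcom", "direction"])


class TestQuantifiedFilter:
    def test_targeted_panel_with_never_detected_features(self):
        """188 targeted features of which 74 are never observed leave 114."""
        rng = np.random.default_rng(0)
        vals = rng.lognormal(3, 0.3, size=(188, 9))
        never = rng.choice(188, size=74, replace=False)
        vals[never, :] = np.nan
        m = make_matrix(vals, layer="metabolite")
        kept = quantified_filter(m)
        assert len(kept) == 114
        assert kept == [f for f in m.feature_ids if f not in {f"F{i}" for i in never}]

    def test_fully_observed_keeps_all(self):
        m = make_matrix(np.ones((5, 4)), layer="metabolite")
        assert quantified_filter(m) == m.feature_ids

    def test_fully_missing_returns_empty(self):
        m = make_matrix(np.full((3, 4), np.nan), layer="metabolite")
        assert quantified_filter(m) == []


class TestThresholdRule:
    @pytest.mark.parametrize(
        "pt,pf,expected",
        [
            (0.05, 0.10, True),   # boundaries inclusive
            (0.04, 0.11, False),  # conjunction: Pf too large
            (0.06, 0.08, False),  # conjunction: Pt too large
            (0.01, 0.01, True),
        ],
    )
    def test_conjunction_with_inclusive_boundaries(self, pt, pf, expected):
        res = results_frame([("A", pt, pf, np.nan, "up")])
        calls = call_threshold(res, 0.05, 0.10, "peptide")
        assert bool(calls["significant"].iloc[0]) is expected

    def test_looser_thresholds_are_a_superset(self):
        rng = np.random.default_rng(1)
        res = results_frame(
            [(f"F{i}", rng.uniform(), rng.uniform(), np.nan, "up") for i in range(200)]
        )
        tight = set(call_threshold(res, 0.05, 0.10, "gene").query("significant")["feature_id"])
        loose = set(call_threshold(res, 0.10, 0.20, "gene").query("significant")["feature_id"])
        assert tight <= loose

    def test_missing_pvalues_never_called(self):
        res = results_frame([("A", np.nan, 0.01, np.nan, "up"),
                             ("B", 0.01, np.nan, np.nan, "down")])
        calls = call_threshold(res, 0.05, 0.10, "gene")
        assert not calls["significant"].any()


def brute_force_rollup(calls: pd.DataFrame, mapping: dict, min_depeptides: int):
    """Independent enumeration oracle for the peptide -> protein roll-up."""
    out = {}
    for prot in sorted({p for p, _ in mapping.values()}):
        peps = [
            (r.feature_id, r.direction)
            for r in calls.itertuples(index=False)
            if r.significant and mapping[r.feature_id][0] == prot
        ]
        dirs = {d for _, d in peps}
        if len(peps) >= min_depeptides and len(dirs) == 1:
            out[prot] = (next(iter(dirs)), sorted(p for p, _ in peps))
    return out


def random_peptide_table(rng, n_peptides=40, n_proteins=12):
    prots = [f"P{i}" for i in range(n_proteins)]
    rows, mrows = [], []
    for i in range(n_peptides):
        prot = rng.choice(prots)
        mrows.append((f"pep{i}", prot, prot.replace("P", "G")))
        sig = rng.random() < 0.5
        rows.append(
            {
                "feature_id": f"pep{i}",
                "layer": "peptide",
                "significant": sig,
                "direction": rng.choice(["up", "down"]) if sig else "none",
                "rule": "threshold" if sig else "",
                "support": "",
            }
        )
    calls = pd.DataFrame(rows)
    pmap = PeptideProteinMap(
        table=pd.DataFrame(mrows, columns=["peptide_id", "protein_id", "gene_symbol"])
    )
    return calls, pmap


class TestRollup:
    def test_three_up_peptides_make_an_up_protein(self):
        calls, pmap = self._fixed(["up", "up", "up"])
        out = rollup_proteins(calls, pmap, 2)
        assert len(out) == 1
        assert out["direction"].iloc[0] == "up"
        assert out["support"].iloc[0] == "pep0,pep1,pep2"

    def test_mixed_direction_protein_is_excluded(self):
        calls, pmap = self._fixed(["up", "up", "down"])
        assert rollup_proteins(calls, pmap, 2).empty

    def test_single_peptide_below_minimum(self):
        calls, pmap = self._fixed(["up"])
        assert rollup_proteins(calls, pmap, 2).empty

    def test_literal_strictly_more_than_two_reading(self):
        calls, pmap = self._fixed(["up", "up"])
        assert len(rollup_proteins(calls, pmap, 2)) == 1
        assert rollup_proteins(calls, pmap, 3).empty

    def test_unmapped_peptide_is_named_in_error(self):
        calls, _ = self._fixed(["up", "up"])
        pmap = PeptideProteinMap(
            table=pd.DataFrame(
                [("pep0", "P0", "G0")], columns=["peptide_id", "protein_id", "gene_symbol"]
            )
        )
        with pytest.raises(ValidationError, match="pep1"):
            rollup_proteins(calls, pmap, 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        calls, pmap = random_peptide_table(rng)
        out = rollup_proteins(calls, pmap, 2)
        oracle = brute_force_rollup(calls, pmap.as_dict(), 2)
        got = {
            r.feature_id: (r.direction, r.support.split(","))
            for r in out.itertuples(index=False)
        }
        assert got == oracle

    @staticmethod
    def _fixed(directions):
        rows = [
            {
                "feature_id": f"pep{i}",
                "layer": "peptide",
                "significant": True,
                "direction": d,
                "rule": "threshold",
                "support": "",
            }
            for i, d in enumerate(directions)
        ]
        pmap = PeptideProteinMap(
            table=pd.DataFrame(
                [(f"pep{i}", "P0", "G0") for i in range(len(directions))],
                columns=["peptide_id", "protein_id", "gene_symbol"],
            )
        )
        return pd.DataFrame(rows), pmap


class TestDemRule:
    @pytest.fixture
    def design(self):
        return GroupDesign(case_ids=["K1", "K2", "K3"], ctrl_ids=["C1", "C2", "C3"])

    def detection(self, rows, design):
        return pd.DataFrame(rows, index=["A", "B", "C"], columns=design.sample_ids)

    def test_case_only_metabolite_is_unique_to_group_up(self, design):
        res = results_frame([("A", np.nan, np.nan, np.nan, "none"),
                             ("B", 0.5, 0.5, 0.4, "up"),
                             ("C", 0.5, 0.5, 0.9, "down")])
        det = self.detection(
            [[True, True, True, False, False, False],
             [True] * 6,
             [True] * 6],
            design,
        )
        out = call_dems(res, det, design, 0.05)
        a = out.set_index("feature_id").loc["A"]
        assert a["significant"] and a["direction"] == "up" and a["rule"] == "unique_to_group"

    def test_pcom_branch_and_provenance_precedence(self, design):
        res = results_frame([("A", 0.01, 0.01, 0.004, "down"),
                             ("B", 0.5, 0.5, 0.2, "up"),
                             ("C", 0.01, 0.02, 0.01, "up")])
        det = self.detection(
            [[True] * 6,
             [True] * 6,
             [True, True, True, False, False, False]],  # both branches apply for C
            design,
        )
        out = call_dems(res, det, design, 0.05).set_index("feature_id")
        assert out.loc["A", "rule"] == "threshold"
        assert not out.loc["B", "significant"]
        assert out.loc["C", "rule"] == "threshold"  # threshold wins over unique

    def test_all_detected_reduces_to_pcom_branch(self, design):
        rng = np.random.default_rng(3)
        res = results_frame(
            [(f"F{i}", 0.5, 0.5, rng.uniform(), "up") for i in range(50)]
        )
        det = pd.DataFrame(True, index=res["feature_id"], columns=design.sample_ids)
        out = call_dems(res, det, design, 0.05)
        sig = out.loc[out["significant"]]
        assert (sig["rule"] == "threshold").all()
        assert set(sig["feature_id"]) == set(res.loc[res["Pcom"] <= 0.05, "feature_id"])

    def test_rules_partition_the_dem_set(self, design):
        res = results_frame([("A", np.nan, np.nan, np.nan, "none"),
                             ("B", 0.01, 0.01, 0.01, "up"),
                             ("C", 0.9, 0.9, 0.9, "up")])
        det = self.detection(
            [[False, False, False, True, True, True], [True] * 6, [True] * 6], design
        )
        out = call_dems(res, det, design, 0.05)
        sig = out.loc[out["significant"]]
        assert sorted(sig["rule"]) == ["threshold", "unique_to_group"]

    def test_missing_detection_rows_rejected(self, design):
        res = results_frame([("Z", 0.5, 0.5, 0.5, "up")])
        det = pd.DataFrame(True, index=["A"], columns=design.sample_ids)
        with pytest.raises(ValidationError):
            call_dems(res, det, design, 0.05)


@pytest.fixture(scope="module")
def planted():
    spec = SynthSpec(
        n_genes_sc=60, n_clusters=3, cells_per_cluster=40,
        frac_de=0.1, effect_log2fc=1.5, seed=7, de_clusters=("Ex",),
    )
    return gen_single_cell(spec)


class TestClusterDegs:
    def test_recall_in_planted_cluster(self, planted):
        adata, truth = planted
        cfg = RunConfig(n_perm=150, seed=1)
        calls = call_cluster_degs(adata, cfg)
        planted_genes = set(
            truth.loc[(truth["cluster"] == "Ex") & truth["is_de"], "feature_id"]
        )
        hit = set(
            calls.loc[(calls["cluster"] == "Ex") & calls["significant"], "feature_id"]
        )
        assert len(hit & planted_genes) / len(planted_genes) >= 0.7

    def test_calls_concentrate_in_planted_cluster(self, planted):
        adata, truth = planted
        cfg = RunConfig(n_perm=150, seed=1)
        calls = call_cluster_degs(adata, cfg)
        per_cluster = calls.groupby("cluster")["significant"].sum()
        assert per_cluster["Ex"] > per_cluster.drop("Ex").max()

    def test_unknown_cluster_subset_rejected(self, planted):
        adata, _ = planted
        with pytest.raises(ValidationError):
            call_cluster_degs(adata, RunConfig(n_perm=20, seed=0), clusters=["Nope"])

    def test_cluster_with_single_case_cell_skipped(self, planted):
        adata, _ = planted
        adata = adata.copy()
        mask = adata.obs["cluster"] == "In"
        cond = adata.obs["condition"].astype(str)
        in_case = mask & (cond == "case")
        drop = adata.obs_names[in_case][1:]
        adata = adata[~adata.obs_names.isin(drop)]
        calls = call_cluster_degs(adata, RunConfig(n_perm=30, seed=0), clusters=["In"])
        assert calls.empty


class TestDotplot:
    def test_worked_example(self, design_5v5):
        import anndata as ad

        X = np.array([[0.0], [0.0], [2.0], [6.0]])
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(
                {"cluster": ["c1"] * 4, "condition": ["case"] * 2 + ["control"] * 2},
                index=[f"cell{i}" for i in range(4)],
            ),
            var=pd.DataFrame(index=["G"]),
        )
        out = dotplot_stats(adata, ["G"])
        assert out["prop_expressing"].iloc[0] == 0.5
        assert out["mean_expr"].iloc[0] == 2.0

    def test_all_zero_and_all_one_genes(self):
        import anndata as ad

        X = np.column_stack([np.zeros(4), np.ones(4)])
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(
                {"cluster": ["c1"] * 4, "condition": ["case"] * 4},
                index=[f"cell{i}" for i in range(4)],
            ),
            var=pd.DataFrame(index=["Z", "O"]),
        )
        out = dotplot_stats(adata, ["Z", "O"]).set_index("gene")
        assert out.loc["Z", "prop_expressing"] == 0.0
        assert out.loc["Z", "mean_expr"] == 0.0
        assert out.loc["O", "prop_expressing"] == 1.0
        assert out.loc["O", "mean_expr"] == 1.0

    def test_missing_gene_rejected(self):
        import anndata as ad

        adata = ad.AnnData(
            X=np.ones((2, 1)),
            obs=pd.DataFrame({"cluster": ["c"] * 2, "condition": ["case"] * 2},
                             index=["a", "b"]),
            var=pd.DataFrame(index=["G"]),
        )
        with pytest.raises(ValidationError):
            dotplot_stats(adata, ["NOPE"])
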