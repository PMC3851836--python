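import numpy as np
import pandas as pd
import pytest

from tfmirnet import (
    EdgeClass,
    MPGEDataset,
    MPGEModel,
    NodeType,
    RegulationLibrary,
    build_two_layer_network,
    fit_combinatorial_model,
    gen_mpge,
    ks_degradation_test,
    prefilter_tfs,
    refine_targets,
)

from .oracles import ks_permutation_pvalue


def make_dataset(values, prefix="x", mirna="hsa-miR-1"):
    return MPGEDataset(mirna, pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))]))


class TestKSDegradation:
    def test_identical_multisets_give_null_result(self):
        values = [-1.0, 0.0, 1.0, -1.0, 0.0, 1.0]
        genes = [f"t{i}" for i in range(3)] + [f"n{i}" for i in range(3)]
        ds = MPGEDataset("hsa-miR-1", pd.Series(values, index=genes))
        lib = RegulationLibrary(EdgeClass.MIR2GENE, [("hsa-miR-1", f"t{i}") for i in range(3)])
        res = ks_degradation_test(ds, lib)
        assert res.ks_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.n_targets == 3 and res.n_nontargets == 3

    def test_downshifted_targets_are_highly_significant(self, shifted_mpge):
        ds, lib, _, _ = shifted_mpge
        res = ks_degradation_test(ds, lib)
        assert res.p_value < 1e-6
        assert 0 < res.ks_statistic <= 1

    def test_mirna_without_library_targets_errors(self):
        ds = make_dataset([0.1, -0.2, 0.3])
        lib = RegulationLibrary(EdgeClass.MIR2GENE, [("hsa-miR-99", "x0")])
        with pytest.raises(ValueError, match="no targets"):
            ks_degradation_test(ds, lib)

    def test_all_targets_errors(self):
        ds = make_dataset([0.1, -0.2])
        lib = RegulationLibrary(EdgeClass.MIR2GENE, [("hsa-miR-1", "x0"), ("hsa-miR-1", "x1")])
        with pytest.raises(ValueError, match="non-target"):
            ks_degradation_test(ds, lib)

    def test_pp_points_span_unit_square(self, shifted_mpge):
        ds, lib, _, _ = shifted_mpge
        pp = ks_degradation_test(ds, lib).pp_points
        assert pp["cdf_targets"].iloc[-1] == 1.0
        assert pp["cdf_nontargets"].iloc[-1] == 1.0
        assert (pp["cdf_targets"].diff().dropna() >= 0).all()

    @pytest.mark.parametrize("shift, seed", [(0.0, 5), (-0.25, 6), (-0.6, 7)])
    def test_p_matches_label_permutation_oracle(self, shift, seed):
        """Exact one-sided p agrees with a 1e5-shuffle Monte-Carlo oracle
        within 3 binomial SEs, across null, weak and strong shifts."""
        rng = np.random.default_rng(seed)
        n_t, n_nt = 80, 120
        targets = rng.normal(size=n_t) + shift
        nontargets = rng.normal(size=n_nt)
        genes = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_nt)]
        ds = MPGEDataset("hsa-miR-1", pd.Series(np.concatenate([targets, nontargets]), index=genes))
        lib = RegulationLibrary(EdgeClass.MIR2GENE, [("hsa-miR-1", f"t{i}") for i in range(n_t)])
        res = ks_degradation_test(ds, lib)
        n_perm = 100_000
        p_mc = ks_permutation_pvalue(targets, nontargets, n_perm, seed=seed + 1000)
        se = np.sqrt(max(p_mc * (1 - p_mc), 1e-12) / n_perm)
        assert res.p_value == pytest.approx(p_mc, abs=max(3 * se, 2e-5))


class TestRefineTargets:
    def test_rank_formula_extremes(self):
        rng = np.random.default_rng(0)
        nontargets = rng.normal(size=999)
        low = nontargets.min() - 1.0
        values = np.concatenate([[low], nontargets])
        genes = ["t0"] + [f"n{i}" for i in range(999)]
        ds = MPGEDataset("hsa-miR-1", pd.Series(values, index=genes))
        lib = RegulationLibrary(EdgeClass.MIR2GENE, [("hsa-miR-1", "t0")])
        table = refine_targets(ds, lib, alpha=0.05)
        assert table.loc["t0", "p_raw"] == pytest.approx(1 / 1000)

    def test_median_target_excluded(self):
        nontargets = np.linspace(-1, 1, 999)  # odd count, median exactly 0
        values = np.concatenate([[0.0], nontargets])
        genes = ["t0"] + [f"n{i}" for i in range(999)]
        ds = MPGEDataset("hsa-miR-1", pd.Series(values, index=genes))
        lib = RegulationLibrary(EdgeClass.MIR2GENE, [("hsa-miR-1", "t0")])
        table = refine_targets(ds, lib, alpha=0.05)
        assert table.loc["t0", "p_raw"] > 0.5
        assert not table.loc["t0", "refined"]

    def test_invalid_alpha_rejected(self, shifted_mpge):
        ds, lib, _, _ = shifted_mpge
        with pytest.raises(ValueError, match="alpha"):
            refine_targets(ds, lib, alpha=1.5)

    def test_planted_targets_recovered_with_few_decoys(self):
        rng = np.random.default_rng(11)
        sd = 0.5
        n_true, n_decoy, n_bg = 50, 50, 900
        true_vals = rng.normal(size=n_true) * sd - 2.0
        decoy_vals = rng.normal(size=n_decoy) * sd
        bg_vals = rng.normal(size=n_bg) * sd
        genes = (
            [f"T{i}" for i in range(n_true)]
            + [f"D{i}" for i in range(n_decoy)]
            + [f"B{i}" for i in range(n_bg)]
        )
        ds = MPGEDataset(
            "hsa-miR-1", pd.Series(np.concatenate([true_vals, decoy_vals, bg_vals]), index=genes)
        )
        lib = RegulationLibrary(
            EdgeClass.MIR2GENE,
            [("hsa-miR-1", g) for g in genes[: n_true + n_decoy]],
        )
        refined = set(refine_targets(ds, lib, alpha=0.05).query("refined").index)
        assert sum(g.startswith("T") for g in refined) >= 45
        assert sum(g.startswith("D") for g in refined) <= 5

    def test_invariant_under_monotone_transform(self, shifted_mpge):
        ds, lib, _, _ = shifted_mpge
        base = refine_targets(ds, lib, alpha=0.05)
        warped = MPGEDataset(ds.perturbed_mirna, np.tanh(ds.ratios) * 3.0 + 1.0)
        trans = refine_targets(warped, lib, alpha=0.05)
        assert list(base.index) == list(trans.index)
        assert np.allclose(base["p_raw"], trans["p_raw"])
        assert (base["refined"] == trans["refined"]).all()


class TestPrefilterTFs:
    def _dataset_with_tf(self, tf_vals, bg_vals):
        genes = [f"t{i}" for i in range(len(tf_vals))] + [f"b{i}" for i in range(len(bg_vals))]
        ds = MPGEDataset("hsa-miR-1", pd.Series(np.concatenate([tf_vals, bg_vals]), index=genes))
        lib = RegulationLibrary(
            EdgeClass.TF2GENE, [("TF1", f"t{i}") for i in range(len(tf_vals))]
        )
        return ds, lib

    def test_perfect_separation_retained(self):
        ds, lib = self._dataset_with_tf(np.full(10, -3.0), np.zeros(40))
        out = prefilter_tfs(ds, lib, p_threshold=0.01)
        assert "TF1" in out.index
        assert out.loc["TF1", "p_value"] < 1e-20

    def test_null_slope_excluded(self):
        # targets symmetric around the background mean
        ds, lib = self._dataset_with_tf(
            np.array([-1.0, 1.0, -0.5, 0.5]), np.array([-1.0, 1.0, -0.5, 0.5, 0.0])
        )
        out = prefilter_tfs(ds, lib, p_threshold=0.01)
        assert "TF1" not in out.index

    def test_effective_tfs_head_the_list(self):
        """10 planted TFs, 3 effective: the effective ones lead the ranking,
        cross-checked against a per-TF two-sample t-test oracle."""
        from scipy import stats

        rng = np.random.default_rng(21)
        n_genes = 2000
        genes = [f"g{i}" for i in range(n_genes)]
        effects = {"TF01": 1.0, "TF02": -1.0, "TF03": 1.0}
        tf_targets = {}
        values = rng.normal(0, 0.5, size=n_genes)
        for tf in [f"TF{i + 1:02d}" for i in range(10)]:
            idx = rng.choice(n_genes, size=80, replace=False)
            tf_targets[tf] = idx
            values[idx] += effects.get(tf, 0.0)
        ds = MPGEDataset("hsa-miR-1", pd.Series(values, index=genes))
        lib = RegulationLibrary(
            EdgeClass.TF2GENE,
            [(tf, genes[i]) for tf, idx in tf_targets.items() for i in idx],
        )
        out = prefilter_tfs(ds, lib, p_threshold=0.01)
        assert set(out.index[:3]) == set(effects)
        # oracle: pooled two-sample t-test p equals the regression slope p
        for tf in out.index:
            mask = np.zeros(n_genes, dtype=bool)
            mask[tf_targets[tf]] = True
            t_p = stats.ttest_ind(values[mask], values[~mask], equal_var=True).pvalue
            assert out.loc[tf, "p_value"] == pytest.approx(t_p, rel=1e-9)

    def test_constant_indicator_skipped(self, caplog):
        ds = make_dataset([1.0, 2.0, 3.0])
        lib = RegulationLibrary(
            EdgeClass.TF2GENE, [("TF1", "x0"), ("TF1", "x1"), ("TF1", "x2")]
        )
        with caplog.at_level("WARNING"):
            with pytest.raises(ValueError, match="non-constant"):
                prefilter_tfs(ds, lib)
        assert any("constant indicator" in r.message for r in caplog.records)


class TestCombinatorialModel:
    def test_noiseless_identity_recovered_exactly(self):
        rng = np.random.default_rng(4)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        b_m = (rng.random(n) < 0.2).astype(float)
        b_tf1 = (rng.random(n) < 0.2).astype(float)
        b_tf2 = (rng.random(n) < 0.2).astype(float)
        y = -2.0 * b_m + 1.5 * b_tf1
        ds = MPGEDataset("hsa-miR-1", pd.Series(y, index=genes))
        lib = RegulationLibrary(
            EdgeClass.TF2GENE,
            [("TF1", genes[i]) for i in np.flatnonzero(b_tf1)]
            + [("TF2", genes[i]) for i in np.flatnonzero(b_tf2)],
        )
        indicator = pd.Series(b_m, index=genes)
        model = fit_combinatorial_model(ds, indicator, ["TF1", "TF2"], lib)
        assert model.a_m == pytest.approx(-2.0, abs=1e-9)
        assert model.retained_tfs == ("TF1",)
        assert model.tf_coefficients["TF1"] == pytest.approx(1.5, abs=1e-9)

    def test_all_zero_response_keeps_nothing(self):
        n = 100
        genes = [f"g{i}" for i in range(n)]
        ds = MPGEDataset("hsa-miR-1", pd.Series(np.zeros(n), index=genes))
        lib = RegulationLibrary(EdgeClass.TF2GENE, [("TF1", g) for g in genes[:20]])
        indicator = pd.Series([1.0] * 30 + [0.0] * 70, index=genes)
        model = fit_combinatorial_model(ds, indicator, ["TF1"], lib)
        assert model.a_m == pytest.approx(0.0, abs=1e-12)
        assert model.retained_tfs == ()

    def test_planted_mediators_recovered_within_tolerance(self):
        """Noise sd 0.3, 3000 genes: planted TF coefficients recovered
        sign-correct within +-0.2 and matching OLS on the true support."""
        from tfmirnet.simulate import TFSpec
        from tfmirnet.stepwise import ols_fit

        ds, mir2gene, tf2gene, truth = gen_mpge(
            n_genes=3000,
            n_mir_targets=60,
            n_decoy_targets=60,
            mir_effect=-1.5,
            tf_spec=(
                TFSpec(1.0, 70, True),
                TFSpec(-1.0, 70, True),
                TFSpec(0.8, 70, True),
            )
            + tuple(TFSpec(0.0, 70, False) for _ in range(5)),
            noise_sd=0.3,
            seed=17,
        )
        model = MPGEModel(ds, mir2gene, tf2gene)
        res = model.fit()
        lm = res.linear_model
        for tf, coef in truth.true_mediator_tfs.items():
            assert tf in lm.retained_tfs
            est = lm.tf_coefficients[tf]
            assert np.sign(est) == np.sign(coef)
            assert est == pytest.approx(coef, abs=0.2)
        # oracle: plain OLS on the true support
        gene_pos = {g: i for i, g in enumerate(ds.genes)}
        X = {}
        X["b_m"] = np.array([1.0 if g in truth.true_direct_targets or g in truth.true_mediator_tfs else 0.0 for g in ds.genes])
        for tf in truth.true_mediator_tfs:
            col = np.zeros(len(ds.genes))
            col[[gene_pos[g] for g in tf2gene.targets_of(tf)]] = 1.0
            X[tf] = col
        fit = ols_fit(ds.ratios.to_numpy(), pd.DataFrame(X, index=ds.genes))
        for tf in truth.true_mediator_tfs:
            assert lm.tf_coefficients[tf] == pytest.approx(fit.params[tf], abs=0.1)


class TestTwoLayerNetwork:
    def test_mediator_cascade_structure(self):
        ds, mir2gene, tf2gene, truth = gen_mpge(seed=1)
        res = MPGEModel(ds, mir2gene, tf2gene).fit()
        net = res.network
        net.validate()
        mir = ds.perturbed_mirna
        for tf in truth.true_mediator_tfs:
            assert tf in res.mediating_tfs
            assert net.graph.has_edge(mir, tf)
            assert net.graph.out_degree(tf) > 0  # cascade: miRNA -> TF -> genes
        # only miRNA->TF/gene and TF->TF/gene edges in this module
        for e in net.edges():
            assert net.node_type(e.source) is not NodeType.GENE
            assert not (
                net.node_type(e.source) is NodeType.TF
                and net.node_type(e.target) is NodeType.MIRNA
            )

    def test_no_tfs_retained_gives_star_network(self):
        rng = np.random.default_rng(9)
        n = 200
        genes = [f"g{i}" for i in range(n)]
        vals = rng.normal(size=n)
        vals[:30] -= 3.0
        ds = MPGEDataset("hsa-miR-1", pd.Series(vals, index=genes))
        mir2gene = RegulationLibrary(EdgeClass.MIR2GENE, [("hsa-miR-1", g) for g in genes[:30]])
        lm_like = fit_combinatorial_model(
            ds,
            pd.Series([1.0] * 30 + [0.0] * (n - 30), index=genes),
            [],
            RegulationLibrary(EdgeClass.TF2GENE, []),
        )
        net = build_two_layer_network(
            lm_like, set(genes[:30]), mir2gene, RegulationLibrary(EdgeClass.TF2GENE, []), ds.genes
        )
        assert net.number_of_nodes == 31
        assert net.number_of_edges == 30
        assert all(e.source == "hsa-miR-1" for e in net.edges())

    def test_overlap_merging_counts(self):
        # 1 mediating TF with 2 library targets, 3 refined direct targets
        genes = [f"g{i}" for i in range(20)]
        vals = pd.Series(np.linspace(-1, 1, 20), index=genes)
        ds = MPGEDataset("hsa-miR-1", vals)
        mir2gene = RegulationLibrary(
            EdgeClass.MIR2GENE,
            [("hsa-miR-1", g) for g in ["g0", "g1", "g2"]] + [("hsa-miR-1", "TF1")],
        )
        tf2gene = RegulationLibrary(EdgeClass.TF2GENE, [("TF1", "g3"), ("TF1", "g4")])
        indicator = pd.Series([1.0 if g in {"g0", "g1", "g2"} else 0.0 for g in genes], index=genes)
        model = fit_combinatorial_model(ds, indicator, ["TF1"], tf2gene)
        if "TF1" not in model.retained_tfs:  # keep the fixture honest
            import dataclasses

            model = dataclasses.replace(
                model,
                tf_coefficients=pd.Series({"TF1": 0.5}),
                tf_pvalues=pd.Series({"TF1": 0.01}),
            )
        net = build_two_layer_network(model, {"g0", "g1", "g2"}, mir2gene, tf2gene, ds.genes)
        # nodes: miRNA, TF1, g0-g4 -> 7; edges: 3 direct + miR->TF1 + 2 TF edges
        assert net.number_of_nodes <= 7
        assert net.number_of_edges == 6
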