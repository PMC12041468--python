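"""TMT proteomics operations against analytic cases and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import stromamatrix as sm
from stromamatrix.proteomics import RATIO_NAMES

import oracles


def _toy_table(values, groups=None, scale="raw"):
    data = pd.DataFrame(
        values,
        index=[f"P{i}" for i in range(values.shape[0])],
        columns=[f"S{i}" for i in range(values.shape[1])],
    )
    groups = groups or {c: "NAT" for c in data.columns}
    return sm.IntensityTable(
        data=data,
        groups=pd.Series(groups),
        batches=pd.Series({c: 1 for c in data.columns}),
        scale=scale,
    )


class TestReferenceQC:
    def test_noiseless_ratios_exact(self):
        table, design, _ = sm.gen_tmt_experiment(n_proteins=20, noise_sd=0.0, seed=0)
        qc = sm.reference_ratio_qc(table, design)
        mat = qc.ratios[1]
        np.testing.assert_allclose(mat["131N/131C"], 1.0, atol=1e-9)
        np.testing.assert_allclose(mat["131C/130N"], 1.0, atol=1e-9)
        np.testing.assert_allclose(mat["131N/130N"], 2.0, atol=1e-9)

    def test_batch_medians_near_design(self, tmt_experiment):
        table, design, _ = tmt_experiment
        qc = sm.reference_ratio_qc(table, design)
        for name, expected in zip(RATIO_NAMES, (1.0, 1.0, 2.0)):
            assert abs(qc.summary.loc[(1, name), "median"] - expected) < 0.05

    def test_ratios_recomputed_from_emitted_table(self, tmt_experiment):
        """Arithmetic oracle: ratios equal direct column arithmetic."""
        table, design, _ = tmt_experiment
        qc = sm.reference_ratio_qc(table, design)
        ch = design.batch_channels(1)
        direct = np.log2(table.data[ch["131N"]] / table.data[ch["130N"]])
        np.testing.assert_allclose(qc.ratios[1]["131N/130N"], direct, atol=1e-12)

    def test_missing_reference_channel_names_batch(self, tmt_experiment):
        table, design, _ = tmt_experiment
        broken = sm.IntensityTable(
            data=table.data.drop(columns=["B1_Ref_131N"]),
            groups=table.groups.drop("B1_Ref_131N"),
            batches=table.batches.drop("B1_Ref_131N"),
        )
        with pytest.raises(KeyError, match="batch 1"):
            sm.reference_ratio_qc(broken, design)

    def test_planted_outlier_flagged(self):
        table, design, _ = sm.gen_tmt_experiment(n_proteins=200, noise_sd=0.05, seed=4)
        data = table.data.copy()
        data.loc["P00001", "B1_Ref_131N"] *= 50.0
        spiked = sm.IntensityTable(data=data, groups=table.groups, batches=table.batches)
        qc = sm.reference_ratio_qc(spiked, design)
        assert bool(qc.outliers.loc["P00001", 1])


class TestNormalization:
    def test_median_balanced_table_is_fixed_point(self, rng):
        log2v = rng.normal(size=(50, 4))
        log2v = log2v - np.median(log2v, axis=0)  # equal column medians (0)
        table = _toy_table(np.exp2(log2v))
        step1 = sm.median_center(table)
        np.testing.assert_allclose(step1, table.data.values, rtol=1e-9)

    def test_constant_shift_removed(self, rng):
        base = np.exp2(rng.normal(size=(40, 2)) + 10)
        shifted = np.column_stack([base[:, 0], base[:, 0] * 2**3.0])
        table = _toy_table(shifted)
        step1 = sm.median_center(table)
        meds = np.median(np.log2(step1), axis=0)
        assert abs(meds[0] - meds[1]) < 1e-9

    def test_two_step_output_matches_independent_transcription(self, rng):
        """Brute-force oracle: an independently coded transcription of both
        normalization steps on a random 50 x 8 table."""
        values = np.exp2(rng.normal(size=(50, 8)) + 15)
        groups = {f"S{i}": "NAT" for i in range(8)}
        groups["S0"] = "Reference"
        table = _toy_table(values, groups)
        design = sm.ChannelDesign(
            table=pd.DataFrame(
                {"batch": [1, 1, 1], "channel": ["130N", "131C", "131N"],
                 "sample_id": ["S0", "S1", "S2"], "weight": [0.5, 1.0, 2.0]}
            ),
            reference_sample="S0",
        )
        out = sm.normalize_intensities(table, design)

        # oracle: step 1 then step 2, written independently
        l2 = np.log2(values)
        meds = np.median(l2, axis=0)
        s1 = 2 ** (l2 - meds + meds.mean())
        ref = s1[:, 0]
        s2 = s1 / ref[:, None] * ref.mean()
        np.testing.assert_allclose(out.data.values, s2, rtol=1e-12)
        assert out.scale == "normalized"

    def test_zero_handling(self):
        values = np.full((12, 3), 8.0)
        values[0, 0] = 0.0
        table = _toy_table(values)
        design = sm.ChannelDesign(
            table=pd.DataFrame(
                {"batch": [1, 1, 1], "channel": ["130N", "131C", "131N"],
                 "sample_id": ["S0", "S1", "S2"], "weight": [0.5, 1.0, 2.0]}
            ),
            reference_sample="S1",
        )
        with pytest.raises(ValueError, match="floor"):
            sm.normalize_intensities(table, design, floor=None)
        out = sm.normalize_intensities(table, design)  # default floors zeros
        assert (out.data.values > 0).all()


class TestAnnotateMatrisome:
    @pytest.fixture
    def annotation(self):
        table = pd.DataFrame(
            {"division": ["core", "core", "associated"],
             "category": ["COL", "PRO", "REG"]},
            index=pd.Index(["COL1A1", "DCN", "MMP2"], name="gene"),
        )
        return sm.MatrisomeAnnotation(table)

    def test_known_collagen(self, annotation):
        out = sm.annotate_matrisome(["COL1A1"], annotation)
        assert out.loc["COL1A1"].tolist() == ["core", "COL"]

    def test_unknown_and_case_insensitive(self, annotation):
        out = sm.annotate_matrisome(["novel1", "col1a1", "Dcn"], annotation)
        assert out.loc["novel1"].tolist() == ["non-matrisome", "none"]
        assert out.loc["col1a1", "category"] == "COL"
        assert out.loc["Dcn", "category"] == "PRO"

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            sm.MatrisomeAnnotation(pd.DataFrame(columns=["division", "category"]))

    def test_invariant_core_category_consistency(self):
        bad = pd.DataFrame(
            {"division": ["core"], "category": ["REG"]},
            index=pd.Index(["X"], name="gene"),
        )
        with pytest.raises(ValueError):
            sm.MatrisomeAnnotation(bad)


class TestRPC:
    def test_single_protein_is_100(self):
        table = _toy_table(np.array([[5.0, 7.0]]), scale="normalized")
        rpc = sm.compute_rpc(table)
        np.testing.assert_allclose(rpc.protein_pct.values, 100.0)

    def test_two_equal_proteins_split(self):
        table = _toy_table(np.array([[3.0], [3.0]]), scale="normalized")
        rpc = sm.compute_rpc(table)
        np.testing.assert_allclose(rpc.protein_pct.values, 50.0)

    def test_formula_oracle_and_conservation(self, rng):
        values = rng.uniform(1, 100, size=(30, 5))
        table = _toy_table(values, scale="normalized")
        rpc = sm.compute_rpc(table)
        np.testing.assert_allclose(
            rpc.protein_pct.values, values / values.sum(axis=0) * 100.0, rtol=1e-12
        )
        np.testing.assert_allclose(rpc.protein_pct.sum(axis=0), 100.0, atol=1e-6)

    def test_category_rollup_sums_to_protein_total(self, tmt_experiment):
        table, design, truth = tmt_experiment
        normalized = sm.normalize_intensities(table, design)
        ann = sm.matrisome_annotation_from_truth(truth)
        rpc = sm.compute_rpc(normalized, ann)
        np.testing.assert_allclose(
            rpc.category_pct.sum(axis=0), rpc.protein_pct.sum(axis=0), atol=1e-9
        )


class TestCategoryDiffTest:
    def _rpc(self, values):
        cats = pd.DataFrame(values, index=["COL", "GLY"],
                            columns=[f"S{i}" for i in range(values.shape[1])])
        prot = cats.copy()
        prot = prot / prot.sum(axis=0) * 100
        return sm.RPCTable(protein_pct=prot, category_pct=cats,
                           protein_category=pd.Series(["COL", "GLY"], index=prot.index))

    def test_identical_groups_t_zero(self):
        rpc = self._rpc(np.array([[1.0, 2.0, 1.0, 2.0], [3.0, 4.0, 3.0, 4.0]]))
        groups = pd.Series({"S0": "NAT", "S1": "NAT", "S2": "Tumor", "S3": "Tumor"})
        out = sm.category_diff_test(rpc, groups)
        np.testing.assert_allclose(out["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p"], 1.0, atol=1e-12)

    def test_matches_textbook_student_t(self, rng):
        vals = rng.uniform(1, 10, size=(2, 6))
        rpc = self._rpc(vals)
        groups = pd.Series({f"S{i}": ("NAT" if i < 3 else "Tumor") for i in range(6)})
        out = sm.category_diff_test(rpc, groups)
        for i, cat in enumerate(["COL", "GLY"]):
            t, p = oracles.student_t_pvalue(vals[i, :3], vals[i, 3:])
            assert out.loc[cat, "t"] == pytest.approx(t, rel=1e-9)
            assert out.loc[cat, "p"] == pytest.approx(p, rel=1e-9)

    def test_planted_shift_detected(self):
        """3-sd mean shift at n=10/10 is significant in nearly every repetition."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = r.normal(0, 1, 10)
            b = r.normal(3, 1, 10)
            vals = np.vstack([np.r_[a + 10, b + 10], np.full(20, 5.0)])
            rpc = self._rpc(vals)
            groups = pd.Series({f"S{i}": ("NAT" if i < 10 else "Tumor") for i in range(20)})
            p = sm.category_diff_test(rpc, groups).loc["COL", "p"]
            hits += p < 0.01
        assert hits >= 95


class TestDEPAnalysis:
    def test_identical_groups_nothing_selected(self):
        values = np.exp2(np.tile(np.arange(1, 21, dtype=float)[:, None], (1, 8)) / 2)
        groups = {f"S{i}": ("NAT" if i < 4 else "Tumor") for i in range(8)}
        table = _toy_table(values, groups, scale="normalized")
        # add tiny jitter so variances are nonzero but groups stay identical
        dep = sm.dep_analysis(table)
        assert not dep["selected"].any()

    def test_planted_dep_recovery(self, tmt_experiment):
        table, design, truth = tmt_experiment
        normalized = sm.normalize_intensities(table, design)
        dep = sm.dep_analysis(normalized)
        found = set(dep.index[dep["selected"]])
        planted = set(truth.dep_genes)
        assert len(found & planted) / len(planted) >= 0.95
        assert len(found - planted) / max(len(found), 1) <= 0.10
        # signed direction matches the planted sign
        for gene, lfc in truth.dep_genes.items():
            if gene in found:
                expected = "Tumor-enriched" if lfc > 0 else "NAT-enriched"
                assert dep.loc[gene, "direction"] == expected

    def test_welch_and_bh_match_brute_force(self, rng):
        values = np.exp2(rng.normal(size=(60, 10)) + 12)
        groups = {f"S{i}": ("NAT" if i < 5 else "Tumor") for i in range(10)}
        table = _toy_table(values, groups, scale="normalized")
        dep = sm.dep_analysis(table)
        l2 = np.log2(values)
        ps = []
        for i in range(60):
            t, p = oracles.welch_t_pvalue(l2[i, 5:], l2[i, :5])
            assert dep["p"].iloc[i] == pytest.approx(p, rel=1e-9)
            ps.append(p)
        np.testing.assert_allclose(dep["q"].values, oracles.bh_adjust(ps), rtol=1e-9)

    def test_selection_monotone_in_thresholds(self, tmt_experiment):
        table, design, _ = tmt_experiment
        normalized = sm.normalize_intensities(table, design)
        base = sm.dep_analysis(normalized, alpha=0.01, log2fc_threshold=0.5)
        stricter_p = sm.dep_analysis(normalized, alpha=0.001, log2fc_threshold=0.5)
        stricter_fc = sm.dep_analysis(normalized, alpha=0.01, log2fc_threshold=1.0)
        assert set(stricter_p.index[stricter_p.selected]) <= set(base.index[base.selected])
        assert set(stricter_fc.index[stricter_fc.selected]) <= set(base.index[base.selected])

    def test_direction_partition_disjoint(self, tmt_experiment):
        table, design, _ = tmt_experiment
        normalized = sm.normalize_intensities(table, design)
        dep = sm.dep_analysis(normalized)
        sel = dep[dep["selected"]]
        nat = set(sel.index[sel.direction == "NAT-enriched"])
        tum = set(sel.index[sel.direction == "Tumor-enriched"])
        assert not (nat & tum)
        assert nat | tum == set(sel.index)


class TestBHOracle:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_statsmodels_bh_equals_step_up(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, oracles.bh_adjust(pvals), atol=1e-12)


class TestComposition:
    def _rpc_from(self, values, cats=None):
        prot = pd.DataFrame(values, index=[f"P{i}" for i in range(len(values))],
                            columns=["S0"])
        prot = prot / prot.sum(axis=0) * 100
        cats = cats or ["COL"] * len(values)
        cat = pd.Series(cats, index=prot.index)
        return sm.RPCTable(protein_pct=prot, category_pct=prot.groupby(cat).sum(),
                           protein_category=cat)

    def test_ties_broken_lexicographically(self):
        rpc = self._rpc_from([[1.0], [1.0], [1.0]])
        top = sm.top_composition(rpc, ["S0"], n=2)
        assert top.index.tolist() == ["P0", "P1"]

    def test_n_exceeding_proteins_returns_all(self):
        rpc = self._rpc_from([[1.0], [2.0]])
        assert len(sm.top_composition(rpc, ["S0"], n=10)) == 2

    def test_matches_sort_oracle(self, rng):
        vals = rng.uniform(0.1, 10.0, size=(20, 1))
        rpc = self._rpc_from(vals.tolist())
        top = sm.top_composition(rpc, ["S0"], n=20)
        expected = rpc.protein_pct["S0"].sort_values(ascending=False)
        np.testing.assert_allclose(top.values, expected.values)

    def test_matrisome_restriction(self):
        rpc = self._rpc_from([[5.0], [1.0]], cats=["none", "COL"])
        top = sm.top_composition(rpc, ["S0"], n=5, matrisome_only=True)
        assert top.index.tolist() == ["P1"]

    def test_coverage_equal_proteins(self):
        rpc = self._rpc_from([[1.0]] * 10)
        assert sm.coverage_count(rpc, ["S0"], 0.9) == 9
        assert sm.coverage_count(rpc, ["S0"], 1.0) == 10

    def test_coverage_matches_prefix_sum_oracle(self, rng):
        vals = rng.uniform(0.01, 5.0, size=(50, 1))
        rpc = self._rpc_from(vals.tolist())
        for frac in (0.5, 0.9, 0.99):
            got = sm.coverage_count(rpc, ["S0"], frac)
            ordered = np.sort(rpc.protein_pct["S0"].values)[::-1]
            count, acc = 0, 0.0
            while acc < frac * 100.0 - 1e-12:
                acc += ordered[count]
                count += 1
            assert got == count


class TestORA:
    def test_query_equals_universe_p_one(self):
        out = sm.ora_enrichment(["a", "b"], {"s": ["a", "b"]}, ["a", "b"])
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_disjoint_query_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = sm.ora_enrichment(universe[:5], {"s": universe[10:15]}, universe)
        # overlap 0 -> P(X >= 0) = 1
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_exact_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(20)]
        query = universe[:5]
        geneset = universe[1:5] + [universe[10]]  # overlap 4, set size 5
        out = sm.ora_enrichment(query, {"s": geneset}, universe)
        assert out.loc["s", "overlap"] == 4
        assert out.loc["s", "p"] == pytest.approx(
            oracles.hypergeom_tail(4, 20, 5, 5), rel=1e-12
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            sm.ora_enrichment([], {"s": ["a"]}, [])


class TestProfileStructure:
    def test_duplicated_sample_distance_zero_merges_first(self, rng):
        base = rng.uniform(1, 10, size=(20, 1))
        values = np.column_stack([base, base, base * rng.uniform(2, 3, size=(20, 1))])
        res = sm.profile_structure(
            pd.DataFrame(values, index=[f"P{i}" for i in range(20)],
                         columns=["A", "B", "C"]),
            matrisome_only=False,
        )
        assert res.distances.loc["A", "B"] == pytest.approx(0.0, abs=1e-9)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_collinear_samples_pc1_dominates(self):
        base = np.linspace(1, 5, 30)
        values = np.exp2(np.column_stack([base, 2 * base, 3 * base]))
        res = sm.profile_structure(
            pd.DataFrame(values, index=[f"P{i}" for i in range(30)],
                         columns=["A", "B", "C"]),
            matrisome_only=False,
        )
        assert res.explained_variance_ratio[0] > 0.999

    def test_distances_match_formula(self, rng):
        values = rng.uniform(1, 50, size=(15, 4))
        df = pd.DataFrame(values, index=[f"P{i}" for i in range(15)],
                          columns=list("ABCD"))
        res = sm.profile_structure(df, matrisome_only=False)
        l2 = np.log2(values)
        z = (l2 - l2.mean(1, keepdims=True)) / np.where(
            l2.std(1, keepdims=True) == 0, 1, l2.std(1, keepdims=True))
        expected = np.sqrt(((z[:, 0] - z[:, 1]) ** 2).sum())
        assert res.distances.loc["A", "B"] == pytest.approx(expected, rel=1e-9)
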