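"""Bivalent scoring, heatmap matrix, signature correlation, clocks,
deconvolution and PCA QC."""

import numpy as np
import pandas as pd
import pytest

from cdcmeth import (
    ClockModel,
    ExternalSignature,
    MethylationMatrix,
    PairSet,
    PairedDesign,
    apply_clock,
    count_bivalent,
    deconvolve_cells,
    heatmap_matrix,
    pca_qc,
    signature_correlation,
)
from cdcmeth.signatures import encode_clock_betas


class TestBivalent:
    def _db(self, rng, n=100):
        cpgs = [f"cg{i}" for i in range(n)]
        marks = ("EZH2", "SUZ12", "H3K27me3", "H3K4me2", "H3K4me3")
        db = {m: set(np.array(cpgs)[rng.random(n) < 0.4]) for m in marks}
        return cpgs, db

    def test_extreme_membership_counts(self):
        db = {m: {"cg_all"} for m in ("EZH2", "SUZ12", "H3K27me3", "H3K4me2", "H3K4me3")}
        counts, summary = count_bivalent(["cg_all", "cg_none"], db)
        assert counts["cg_all"] == 5 and counts["cg_none"] == 0
        assert summary == {"n": 2, "ge4": 1, "eq5": 1, "frac_ge4": 0.5, "frac_eq5": 0.5}

    def test_summary_matches_direct_counting_oracle(self):
        rng = np.random.default_rng(0)
        cpgs, db = self._db(rng)
        counts, summary = count_bivalent(cpgs, db)
        oracle = [sum(c in db[m] for m in db) for c in cpgs]
        assert list(counts) == oracle
        assert summary["ge4"] == sum(v >= 4 for v in oracle)
        assert summary["eq5"] == sum(v == 5 for v in oracle)

    def test_unknown_mark_errors(self):
        with pytest.raises(KeyError):
            count_bivalent(["cg1"], {"EZH2": set()}, marks=("EZH2", "NOPE"))


class TestHeatmapMatrix:
    def _inputs(self):
        cats = pd.DataFrame(
            {"leading_edge": [("g1", "g2"), ("g1", "g2"), ("g2",)]},
            index=["catA", "catB", "catC"],
        )
        prom = pd.DataFrame(
            {"leading_edge": [("cgA", "cgB"), ("cgC",)]}, index=["g1", "g2"]
        )
        stats = pd.DataFrame({"t": [-5.0, 3.0, 4.0]}, index=["cgA", "cgB", "cgC"])
        M = MethylationMatrix(
            pd.DataFrame(
                {"p1": [2.0, 1.0, 0.0], "c1": [0.5, 1.0, 1.0],
                 "p2": [1.0, 2.0, 3.0], "c2": [1.0, 0.0, 1.0]},
                index=["cgA", "cgB", "cgC"],
            ),
            "M",
        )
        design = PairedDesign([PairSet("1", ["p1"], ["c1"]), PairSet("2", ["p2"], ["c2"])])
        return cats, prom, stats, M, design

    def test_picks_largest_abs_t_cpg_and_subtracts_m_values(self):
        cats, prom, stats, M, design = self._inputs()
        mat, chosen = heatmap_matrix(cats, ["catA", "catB", "catC"], prom, stats, M, design)
        assert chosen["g1"] == "cgA"  # |t|=5 beats 3
        assert chosen["g2"] == "cgC"
        assert mat.loc["g1", "1"] == pytest.approx(1.5)  # patient 2.0 - control 0.5
        # rows ordered by decreasing |t| of the chosen CpG
        assert list(mat.index) == ["g1", "g2"]

    def test_values_match_independent_recomputation(self):
        cats, prom, stats, M, design = self._inputs()
        mat, chosen = heatmap_matrix(cats, ["catA", "catB", "catC"], prom, stats, M, design)
        for g, cpg in chosen.items():
            for ps in design.sets:
                expected = (
                    M.values.loc[cpg, ps.patients].mean()
                    - M.values.loc[cpg, ps.controls].mean()
                )
                assert mat.loc[g, ps.pair_id] == pytest.approx(expected)

    def test_membership_threshold_and_missing_category(self):
        cats, prom, stats, M, design = self._inputs()
        mat, _ = heatmap_matrix(cats, ["catA", "catB", "catC"], prom, stats, M, design,
                                min_membership=3)
        assert list(mat.index) == ["g2"]  # only g2 is in all three edges
        with pytest.raises(KeyError):
            heatmap_matrix(cats, ["catA", "nope"], prom, stats, M, design)


class TestSignatureCorrelation:
    def test_self_and_negated_signatures(self):
        rng = np.random.default_rng(1)
        own = pd.Series(rng.normal(size=50), index=[f"cg{i}" for i in range(50)])
        r, n = signature_correlation(own, ExternalSignature(own, "self"))
        assert r == pytest.approx(1.0) and n == 50
        r, _ = signature_correlation(own, ExternalSignature(-own, "anti"))
        assert r == pytest.approx(-1.0)

    def test_planted_anticorrelated_signature_detected(self):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            own = pd.Series(rng.normal(0, 1, 229), index=[f"cg{i}" for i in range(229)])
            sig = ExternalSignature(-own + rng.normal(0, 0.5, 229), "planted")
            rs.append(signature_correlation(own, sig)[0])
        assert all(r < -0.4 for r in rs)

    def test_insufficient_overlap_errors(self):
        own = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            signature_correlation(own, ExternalSignature(pd.Series({"a": 1.0})))


class TestClock:
    def _clock(self, transform="identity"):
        coefs = pd.Series({"cg1": 2.0, "cg2": -1.0, "cg3": 0.5})
        return ClockModel("toy", 0.5, coefs, transform)

    def test_single_coefficient_identity(self):
        clock = ClockModel("unit", 0.0, pd.Series({"cg1": 1.0}))
        beta = MethylationMatrix(pd.DataFrame({"s": [0.5]}, index=["cg1"]), "beta")
        assert apply_clock(beta, clock)["s"] == pytest.approx(0.5)

    def test_horvath_transform_boundary_is_adult_age(self):
        clock = ClockModel("h", 0.0, pd.Series({"cg1": 0.0}), "horvath")
        beta = MethylationMatrix(pd.DataFrame({"s": [0.3]}, index=["cg1"]), "beta")
        assert apply_clock(beta, clock)["s"] == pytest.approx(20.0)

    @pytest.mark.parametrize("transform", ["identity", "horvath"])
    def test_encoding_then_decoding_is_identity(self, transform):
        clock = self._clock(transform)
        ages = pd.Series({"s1": 7.3, "s2": 45.0, "s3": 19.99})
        betas = encode_clock_betas(clock, ages)
        est = apply_clock(MethylationMatrix(betas, "beta"), clock)
        np.testing.assert_allclose(est, ages, atol=1e-8)

    def test_low_coverage_errors_and_moderate_coverage_warns(self):
        coefs = pd.Series({f"cg{i}": 1.0 for i in range(100)})
        clock = ClockModel("big", 0.0, coefs)
        full = pd.DataFrame(0.5, index=coefs.index, columns=["s"])
        with pytest.raises(ValueError):
            apply_clock(MethylationMatrix(full.iloc[:90], "beta"), clock)
        with pytest.warns(UserWarning, match="imputing"):
            est = apply_clock(MethylationMatrix(full.iloc[:97], "beta"), clock)
        assert est["s"] == pytest.approx(50.0)  # imputed at the sample mean beta


class TestDeconvolution:
    def _reference(self, seed=2, n=200, k=5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.uniform(0, 1, (n, k)),
            index=[f"cg{i}" for i in range(n)],
            columns=[f"T{j}" for j in range(k)],
        )

    def test_pure_sample_recovers_unit_weight(self):
        ref = self._reference()
        w, resid = deconvolve_cells(ref["T2"], ref)
        assert w["T2"] == pytest.approx(1.0, abs=1e-6)
        assert w.drop("T2").abs().max() < 1e-6 and resid < 1e-6

    def test_even_mixture_recovered_exactly(self):
        ref = self._reference()
        b = 0.5 * ref["T0"] + 0.5 * ref["T1"]
        w, _ = deconvolve_cells(b, ref)
        assert w["T0"] == pytest.approx(0.5, abs=1e-6)
        assert w["T1"] == pytest.approx(0.5, abs=1e-6)

    def test_noisy_mixture_recovery_and_simplex_constraints(self):
        ref = self._reference()
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            w_true = rng.dirichlet(np.ones(5))
            b = pd.Series(ref.values @ w_true + rng.normal(0, 0.02, 200), index=ref.index)
            w, _ = deconvolve_cells(b, ref)
            assert np.abs(w.values - w_true).max() < 0.05
            assert (w.values >= 0).all() and w.sum() <= 1 + 1e-9

    def test_rank_deficient_reference_errors(self):
        ref = self._reference()
        ref["T4"] = ref["T3"]
        with pytest.raises(ValueError):
            deconvolve_cells(ref["T0"], ref)


class TestPcaQc:
    def test_duplicate_samples_coincide_and_variance_sums_to_one(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(500, 4))
        vals = pd.DataFrame(
            np.column_stack([base, base[:, 0]]),
            index=[f"cg{i}" for i in range(500)],
            columns=["a", "b", "c", "d", "a2"],
        )
        res = pca_qc(MethylationMatrix(vals, "M"), n_top=500)
        np.testing.assert_allclose(
            res["scores"].loc["a"], res["scores"].loc["a2"], atol=1e-8
        )
        assert res["variance_fraction"].sum() == pytest.approx(1.0)

    def test_planted_age_drift_dominates_pc1(self, small_cohort=None):
        from cdcmeth import SimConfig, make_annotation, simulate_cohort
        from cdcmeth.pipeline import cohort_m_values

        cfg = SimConfig(
            n_cpgs=2000, n_genes=50, n_categories=5, genes_per_category=8,
            age_drift_per_year=0.003, seed=21,
        )
        bundle = make_annotation(cfg)
        intens, design, truth = simulate_cohort(bundle, cfg)
        M, _ = cohort_m_values(intens, bundle.annotation)
        ages = truth.sample_info.set_index("sample_id")["age"]
        res = pca_qc(M, covariates=ages.to_frame(), n_top=2000)
        r = np.corrcoef(res["scores"]["PC1"], ages.loc[res["scores"].index])[0, 1]
        assert abs(r) > 0.8
        pc1_assoc = res["associations"].query("pc == 'PC1' and covariate == 'age'")
        assert abs(pc1_assoc["stat"].iloc[0]) > 0.8

    def test_constant_matrix_errors(self):
        vals = pd.DataFrame(np.ones((50, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            pca_qc(MethylationMatrix(vals, "M"), n_top=50)
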