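"""Tests of the per-SNP scan, FDR adjustment and significance calls."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from growthgwas.scan import (
    call_significant,
    fdr_adjust,
    manhattan_table,
    run_scan,
    storey_pi0,
)
from growthgwas.simulate import SimulationConfig, simulate_cohort


class TestFDR:
    def test_bh_hand_computed_example(self):
        q = fdr_adjust([0.001, 0.01, 0.02, 0.8], method="bh")
        assert np.allclose(q, [0.004, 0.02, 0.0266666667, 0.8])

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=500) ** 2
        q = fdr_adjust(p, method="bh")
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    def test_storey_with_pi0_one_equals_bh(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=300)  # uniform p -> pi0 estimate ~1, clipped to 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q_storey = fdr_adjust(p, method="storey")
        q_bh = fdr_adjust(p, method="bh")
        pi0 = min(1.0, storey_pi0(p))
        assert np.allclose(np.minimum(q_bh * pi0, 1.0), q_storey, atol=1e-12)

    def test_storey_qvalues_scale_with_pi0(self):
        # half the p-values pile near zero -> pi0 < 1 -> Storey < BH
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(size=150) * 1e-4, rng.uniform(size=150)])
        q_storey = fdr_adjust(p, method="storey")
        q_bh = fdr_adjust(p, method="bh")
        pi0 = storey_pi0(p)
        assert 0.1 < pi0 < 1.0
        assert np.allclose(q_storey, np.minimum(pi0 * q_bh / 1.0, 1.0), atol=1e-12)

    def test_all_ones_stay_ones(self):
        assert np.allclose(fdr_adjust(np.ones(10), method="bh"), 1.0)

    def test_small_panel_falls_back_to_bh_with_warning(self):
        p = np.linspace(0.01, 0.99, 50)
        with pytest.warns(UserWarning, match="unreliable"):
            q = fdr_adjust(p, method="storey")
        assert np.allclose(q, fdr_adjust(p, method="bh"))

    def test_missing_pvalues_propagate(self):
        p = np.array([0.01, np.nan, 0.5])
        q = fdr_adjust(p, method="bh")
        assert np.isnan(q[1]) and np.isfinite(q[[0, 2]]).all()

    def test_empty_input(self):
        assert fdr_adjust(np.array([]), method="bh").size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5], method="bh")
        with pytest.raises(ValueError):
            fdr_adjust([0.5], method="bonferroni")

    def test_qvalues_order_consistent_with_pvalues(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        q = fdr_adjust(p, method="bh")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallSignificant:
    def _records(self, qvals):
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(qvals))],
                "chrom": "chr1",
                "pos": np.arange(1, len(qvals) + 1) * 1000,
                "M1_q": qvals,
            }
        )

    def test_none_below_threshold_gives_empty(self):
        assert len(call_significant(self._records([0.05, 0.5, 1.0]))) == 0

    def test_threshold_is_strict(self):
        rec = call_significant(self._records([0.049999, 0.05]))
        assert list(rec["snp_id"]) == ["s0"]

    def test_threshold_one_returns_all_with_finite_q(self):
        rec = call_significant(self._records([0.2, np.nan, 0.8]), q_threshold=1.0)
        assert list(rec["snp_id"]) == ["s0", "s2"]


@pytest.fixture(scope="module")
def null_scan():
    """Scan of 60 null SNPs at n=100 (scaled-down null calibration)."""
    cfg = SimulationConfig(n_individuals=100, n_snps=60, seed=314)
    bundle = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scan(bundle.cohort, bundle.genotypes, hypotheses=("M1",), fdr_method="bh")


@pytest.fixture(scope="module")
def spiked_scan():
    """One SNP with strong effects on both A and K among 25 nulls, n=250."""
    cfg = SimulationConfig(
        n_individuals=250,
        n_snps=25,
        seed=777,
        causal_snps=((7, 150.0, 0.004),),
        maf_low=0.2,
        maf_high=0.5,
    )
    bundle = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scan(
            bundle.cohort, bundle.genotypes, hypotheses=("M1", "M2", "M3"),
            fdr_method="bh",
        )


class TestScan:
    def test_null_pvalues_look_uniform(self, null_scan):
        p = null_scan.records["M1_p"].dropna().to_numpy()
        assert len(p) == 60
        assert kstest(p, "uniform").pvalue > 0.01

    def test_spiked_snp_has_smallest_m1_pvalue_and_is_called(self, spiked_scan):
        rec = spiked_scan.records
        assert rec["M1_p"].idxmin() == 7
        sig = call_significant(rec, "M1", 0.05)
        assert "snp00007" in set(sig["snp_id"])

    def test_m1_statistic_dominates_m2_m3(self, spiked_scan):
        rec = spiked_scan.records.dropna(subset=["M1_stat"])
        slack = 1e-3
        assert (rec["M1_stat"] >= rec["M2_stat"] - slack).all()
        assert (rec["M1_stat"] >= rec["M3_stat"] - slack).all()

    def test_df_columns(self, spiked_scan):
        rec = spiked_scan.records
        assert (rec["M1_df"] == 2).all()
        assert (rec["M2_df"] == 1).all() and (rec["M3_df"] == 1).all()

    def test_scan_invariant_to_snp_order(self, null_scan):
        cfg = SimulationConfig(n_individuals=100, n_snps=60, seed=314)
        bundle = simulate_cohort(cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(60)
        # present the same dosage columns in a different order (positions are
        # rebuilt so the container's sorted-coordinate invariant holds; they
        # play no role in the per-SNP fits or the FDR adjustment)
        from growthgwas.containers import GenotypeMatrix

        permuted = GenotypeMatrix(
            bundle.genotypes.dosages[:, perm],
            pd.DataFrame(
                {
                    "snp_id": bundle.genotypes.snps["snp_id"].to_numpy()[perm],
                    "chrom": "chrP",
                    "pos": np.arange(1, 61) * 100,
                }
            ),
            bundle.genotypes.sample_ids,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shuffled = run_scan(
                bundle.cohort, permuted, hypotheses=("M1",), fdr_method="bh"
            )
        a = null_scan.records.set_index("snp_id")["M1_q"]
        b = shuffled.records.set_index("snp_id")["M1_q"]
        assert np.allclose(a.loc[b.index], b, atol=1e-9)

    def test_empty_hypotheses_give_empty_records(self, small_bundle):
        res = run_scan(small_bundle.cohort, small_bundle.genotypes, hypotheses=())
        assert res.records.empty

    def test_monomorphic_snp_skipped_with_reason(self):
        cfg = SimulationConfig(n_individuals=40, n_snps=6, seed=55)
        bundle = simulate_cohort(cfg)
        bundle.genotypes.dosages[:, 2] = 1.0  # force a monomorphic column
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_scan(bundle.cohort, bundle.genotypes, hypotheses=("M1",), fdr_method="bh")
        rec = res.records.set_index("snp_id")
        assert rec.loc["snp00002", "status"] == "monomorphic"
        assert np.isnan(rec.loc["snp00002", "M1_p"])
        assert np.isnan(rec.loc["snp00002", "M1_q"])

    def test_missing_dosage_handling(self):
        from growthgwas.scan import GWASScan

        cfg = SimulationConfig(n_individuals=50, n_snps=4, seed=88)
        bundle = simulate_cohort(cfg)
        bundle.genotypes.dosages[0:3, 1] = np.nan
        with pytest.raises(ValueError, match="impute"):
            run_scan(bundle.cohort, bundle.genotypes, hypotheses=("M1",), fdr_method="bh")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = GWASScan(
                hypotheses=("M1",), fdr_method="bh", on_missing_dosage="refit"
            ).fit(bundle.cohort, bundle.genotypes)
        rec = res.records_.set_index("snp_id")
        assert rec.loc["snp00001", "status"] == "refit_subset"
        assert np.isfinite(rec.loc["snp00001", "M1_p"])

    def test_manhattan_table_values(self, null_scan):
        man = manhattan_table(null_scan.records, ("M1",))
        p = null_scan.records["M1_p"]
        assert np.allclose(man["M1_neglog10p"], -np.log10(p), equal_nan=True)


class TestEmpiricalFDR:
    def test_fdr_controlled_with_large_true_effects(self):
        """Pooled scaled-down check: panels with 2 strong causal SNPs in 40;
        among q<0.05 calls the false-discovery proportion stays moderate and
        the causal SNPs are found."""
        false_calls, true_calls, causal_found = 0, 0, 0
        reps = 4
        for seed in range(reps):
            cfg = SimulationConfig(
                n_individuals=150,
                n_snps=40,
                seed=9000 + seed,
                causal_snps=((5, 180.0, 0.004), (23, -180.0, -0.004)),
                maf_low=0.2,
                maf_high=0.5,
            )
            bundle = simulate_cohort(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_scan(
                    bundle.cohort, bundle.genotypes, hypotheses=("M1",), fdr_method="bh"
                )
            sig = call_significant(res.records, "M1", 0.05)
            for snp in sig["snp_id"]:
                if snp in ("snp00005", "snp00023"):
                    true_calls += 1
                else:
                    false_calls += 1
            causal_found += int(len(set(sig["snp_id"]) & {"snp00005", "snp00023"}) > 0)
        assert causal_found == reps  # power: strong effects are detected
        total = true_calls + false_calls
        assert total > 0
        assert false_calls / total <= 0.25  # sampling slack around nominal 0.05
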