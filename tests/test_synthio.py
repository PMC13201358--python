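"""Generator calibration: allele frequencies, copula LD, heritability,
effect correlation, summary statistics and recombination maps."""

import numpy as np
import pytest
from scipy import stats

from prsport.accuracy import incremental_r2
from prsport.synthio import (ArchitectureSpec, PopulationSpec,
                             simulate_admixture_gradient,
                             simulate_effects_and_phenotypes,
                             simulate_genotypes, simulate_recomb_map,
                             simulate_sumstats)


def copula_genotype_corr(p1, p2, rho):
    """Independent oracle: genotype correlation implied by thresholding a
    bivariate normal with latent correlation rho at the quantiles of
    (p1, p2).  The genotype (sum of two i.i.d. haplotypes) inherits the
    haplotype correlation."""
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    p11 = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([t1, t2])
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


class TestGenotypes:
    def test_frequency_calibration(self):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.05, 0.95, 80)
        spec = PopulationSpec("A", 5000, [4] * 20, freqs, 0.5)
        panel = simulate_genotypes(spec, 1)
        emp = panel.allele_frequency()
        tol = 3 * np.sqrt(freqs * (1 - freqs) / (2 * 5000))
        assert np.all(np.abs(emp - freqs) < tol)

    def test_zero_ld_gives_independence(self):
        n = 4000
        spec = PopulationSpec("A", n, [5] * 10, np.full(50, 0.4), 0.0)
        panel = simulate_genotypes(spec, 2)
        C = np.corrcoef(panel.dosages.T)
        off = np.abs(C[np.triu_indices(50, 1)])
        assert off.mean() < 3 / np.sqrt(n)

    @pytest.mark.parametrize("p1,p2,rho", [(0.5, 0.5, 0.9), (0.2, 0.7, 0.6)])
    def test_ld_matches_bivariate_normal_oracle(self, p1, p2, rho):
        n = 5000
        spec = PopulationSpec("A", n, [2], np.array([p1, p2]), rho)
        panel = simulate_genotypes(spec, 3)
        r_emp = np.corrcoef(panel.dosages.T)[0, 1]
        r_exp = copula_genotype_corr(p1, p2, rho)
        # genotype = 2-haplotype sum, so r has ~1/sqrt(2n) sampling error
        assert abs(r_emp - r_exp) < 3 * (1 - r_exp ** 2) / np.sqrt(n)

    def test_within_block_corr_increases_with_rho(self):
        rs = []
        for rho in (0.2, 0.5, 0.8):
            spec = PopulationSpec("A", 3000, [2], np.array([0.3, 0.3]), rho)
            panel = simulate_genotypes(spec, 4)
            rs.append(np.corrcoef(panel.dosages.T)[0, 1])
        assert rs[0] < rs[1] < rs[2]

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec("A", 100, [2], np.array([0.5, 1.0]))

    def test_seed_determinism(self):
        spec = PopulationSpec("A", 200, [5] * 4, np.full(20, 0.3), 0.5)
        a = simulate_genotypes(spec, 42)
        b = simulate_genotypes(spec, 42)
        assert np.array_equal(a.dosages, b.dosages)


class TestEffectsAndPhenotypes:
    def _two_panels(self, n=3000, m=40, seed=5):
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.2, 0.8, m)
        spec = PopulationSpec("A", n, [1] * m, freqs, 0.0)
        specB = PopulationSpec("B", n, [1] * m, freqs, 0.0)
        return {"A": simulate_genotypes(spec, seed),
                "B": simulate_genotypes(specB, seed + 1)}

    def test_rho_b_one_identical_effects(self):
        panels = self._two_panels()
        arch = ArchitectureSpec(np.arange(40), rho_b=1.0)
        eff, _ = simulate_effects_and_phenotypes(panels, arch, {"A": 0.5, "B": 0.5},
                                                 None, 6)
        assert np.array_equal(eff["A"], eff["B"])

    def test_rho_b_zero_effects_uncorrelated(self):
        m = 500
        rng = np.random.default_rng(7)
        freqs = rng.uniform(0.2, 0.8, m)
        panels = {lab: simulate_genotypes(
            PopulationSpec(lab, 50, [1] * m, freqs, 0.0), i)
            for i, lab in enumerate(["A", "B"])}
        arch = ArchitectureSpec(np.arange(m), rho_b=0.0)
        eff, _ = simulate_effects_and_phenotypes(panels, arch, {"A": 0.5, "B": 0.5},
                                                 None, 8)
        r = np.corrcoef(eff["A"], eff["B"])[0, 1]
        assert abs(r) < 2 / np.sqrt(m)

    def test_heritability_calibration(self):
        panels = self._two_panels(n=10_000)
        arch = ArchitectureSpec(np.arange(40), rho_b=1.0)
        _, ph = simulate_effects_and_phenotypes(panels, arch, {"A": 0.3, "B": 0.7},
                                                None, 9)
        for lab, h2 in (("A", 0.3), ("B", 0.7)):
            g = ph[lab]["genetic_value"].to_numpy()
            y = ph[lab]["quantitative"].to_numpy()
            r2 = np.corrcoef(g, y)[0, 1] ** 2
            assert abs(r2 - h2) < 0.02

    def test_null_heritability_gives_null_prs(self):
        panels = self._two_panels(n=5000)
        arch = ArchitectureSpec(np.arange(40), rho_b=1.0)
        eff, ph = simulate_effects_and_phenotypes(panels, arch, {"A": 0.0, "B": 0.5},
                                                  None, 10)
        prs = panels["A"].dosages @ eff["A"]
        res = incremental_r2(ph["A"]["quantitative"].to_numpy(), prs)
        assert res.r2_incremental < 0.002

    def test_binary_prevalence_calibrated(self):
        panels = self._two_panels(n=10_000)
        arch = ArchitectureSpec(np.arange(40), rho_b=1.0)
        K = 0.2
        _, ph = simulate_effects_and_phenotypes(panels, arch, {"A": 0.5, "B": 0.5},
                                                {"A": K, "B": K}, 11)
        frac = ph["A"]["binary"].mean()
        assert abs(frac - K) < 3 * np.sqrt(K * (1 - K) / 10_000)

    def test_invalid_h2_rejected(self):
        panels = self._two_panels(n=50)
        arch = ArchitectureSpec(np.arange(40))
        with pytest.raises(ValueError):
            simulate_effects_and_phenotypes(panels, arch, {"A": 1.5, "B": 0.5}, None, 1)


class TestSumstats:
    def test_null_phenotype_pvalue_calibration(self):
        m = 1000
        rng = np.random.default_rng(12)
        spec = PopulationSpec("A", 800, [1] * m, rng.uniform(0.1, 0.9, m), 0.0)
        panel = simulate_genotypes(spec, 13)
        y = rng.standard_normal(800)
        ss = simulate_sumstats(panel, y)
        frac = float((ss.table["P"] < 0.05).mean())
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_effect_recovery_within_se(self):
        n = 10_000
        rng = np.random.default_rng(14)
        spec = PopulationSpec("A", n, [1], np.array([0.5]), 0.0)
        panel = simulate_genotypes(spec, 15)
        x = panel.dosages[:, 0]
        beta_true = 0.1
        y = beta_true * x + rng.standard_normal(n)
        ss = simulate_sumstats(panel, y)
        row = ss.table.iloc[0]
        assert abs(row["BETA"] - beta_true) < 3 * row["SE"]

    def test_duplicate_variant_identical_estimates(self, toy_panel):
        import pandas as pd
        from prsport.data import GenotypePanel

        dup = GenotypePanel(
            dosages=np.column_stack([toy_panel.dosages, toy_panel.dosages[:, [0]]]),
            variants=pd.concat([toy_panel.variants, pd.DataFrame({
                "chrom": ["1"], "pos": [400], "id": ["v1b"], "a1": ["A"], "a2": ["G"]})],
                ignore_index=True),
            samples=toy_panel.samples)
        y = np.array([0.1, 0.5, -0.2, 0.9])
        ss = simulate_sumstats(dup, y)
        assert ss.table["BETA"].iloc[0] == ss.table["BETA"].iloc[3]

    def test_monomorphic_excluded(self):
        import pandas as pd
        from prsport.data import GenotypePanel

        panel = GenotypePanel(
            dosages=np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 0.0], [0.0, 1.0]]),
            variants=pd.DataFrame({"chrom": "1", "pos": [1, 2], "id": ["a", "b"],
                                   "a1": "A", "a2": "G"}),
            samples=pd.DataFrame({"sample_id": list("wxyz")}))
        ss = simulate_sumstats(panel, np.array([0.1, 0.2, 0.3, 0.4]))
        assert len(ss) == 1 and ss.table["ID"].iloc[0] == "b"

    def test_phenotype_length_mismatch(self, toy_panel):
        with pytest.raises(ValueError):
            simulate_sumstats(toy_panel, np.zeros(3))


class TestAdmixture:
    def test_expected_dosage_tracks_alpha(self):
        rng = np.random.default_rng(16)
        m = 400
        pA = rng.uniform(0.1, 0.5, m)
        pB = np.clip(pA + 0.3, 0.05, 0.95)
        sA = PopulationSpec("A", 10, [1] * m, pA, 0.0)
        sB = PopulationSpec("B", 10, [1] * m, pB, 0.0)
        panel = simulate_admixture_gradient(sA, sB, 500, 17)
        alpha = panel.samples["admixture"].to_numpy()
        predicted = 2 * (np.outer(alpha, pA) + np.outer(1 - alpha, pB)).mean(axis=1)
        observed = panel.dosages.mean(axis=1)
        assert np.corrcoef(predicted, observed)[0, 1] > 0.95
        # mean dosage per individual matches the mixture mean closely
        assert np.abs(observed - predicted).mean() < 0.03

    def test_mismatched_specs_rejected(self):
        sA = PopulationSpec("A", 10, [2], np.array([0.3, 0.4]))
        sB = PopulationSpec("B", 10, [3], np.array([0.3, 0.4, 0.5]))
        with pytest.raises(ValueError):
            simulate_admixture_gradient(sA, sB, 10, 0)


class TestRecombMap:
    def test_constant_rate_integrates_linearly(self):
        rmap = simulate_recomb_map(1_000_000, [], background_rate=2.0, hotspot_rate=0.0)
        # cumulative at x is c * (x - 1)/1e6 cM
        assert rmap.interpolate_cumulative(500_001) == pytest.approx(1.0, rel=1e-9)

    def test_zero_rate_map_is_flat(self):
        rmap = simulate_recomb_map(500_000, [100_000], 0.0, 0.0)
        assert np.all(rmap.cumulative == 0)

    def test_hotspot_center_exceeds_flank(self):
        from prsport.recomb import interpolate_rate

        rmap = simulate_recomb_map(1_000_000, [500_000], 1.0, 30.0)
        assert interpolate_rate(rmap, 500_000, 2000) > interpolate_rate(rmap, 300_000, 2000)

    def test_unsorted_hotspots_rejected(self):
        with pytest.raises(ValueError):
            simulate_recomb_map(1_000_000, [600_000, 400_000], 1.0, 10.0)

    def test_monotone_cumulative(self):
        rmap = simulate_recomb_map(2_000_000, [250_000, 900_000], 1.5, 25.0,
                                   seed=3, jitter_sd=0.4)
        assert np.all(np.diff(rmap.cumulative) >= 0)
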