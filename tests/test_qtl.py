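"""QTL machinery: map function, genotype probabilities, scans, intervals."""

import numpy as np
import pandas as pd
import pytest

from phenoqtl.qtl import (
    ALLELE_A,
    ALLELE_B,
    MISSING,
    GeneticMap,
    RILGenotypes,
    QTLPeak,
    ScanResult,
    bayes_interval,
    call_peaks,
    cim_scan,
    fit_multi_qtl,
    genotype_probabilities,
    haldane_r,
    hk_scan,
    permutation_thresholds,
    scan_two,
)
from phenoqtl.simulate import (
    SimRILConfig,
    additive_effect_for_share,
    realized_qtl_positions,
    simulate_genetic_map,
    simulate_ril_genotypes,
    simulate_ril_phenotypes,
)
from .conftest import toy_map, random_genotypes


def ols_lod(x: np.ndarray, y: np.ndarray) -> float:
    """Independent least-squares LOD via statsmodels."""
    import statsmodels.api as sm

    full = sm.OLS(y, sm.add_constant(x)).fit()
    null = sm.OLS(y, np.ones_like(y)).fit()
    return (len(y) / 2.0) * np.log10(null.ssr / full.ssr)


class TestHaldane:
    def test_zero_distance(self):
        assert haldane_r(0.0) == 0.0

    def test_asymptote_half(self):
        assert haldane_r(1e6) == pytest.approx(0.5)

    def test_closed_form_at_10cm(self):
        expected = (1.0 - np.exp(-0.2)) / 2.0
        assert haldane_r(10.0) == pytest.approx(expected, abs=1e-15)
        # cross-check against the series expansion d/100 - (d/100)^2 + ...
        d = 0.01
        series = d / 100 - (d / 100) ** 2 + 2.0 / 3.0 * (d / 100) ** 3
        assert haldane_r(d) == pytest.approx(series, rel=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_r(-1.0)


class TestGenotypeProbabilities:
    def test_typed_marker_collapses_without_error(self):
        gmap = toy_map((40.0,), (5,))
        geno = random_genotypes(gmap, 30, seed=0)
        probs = genotype_probabilities(gmap, geno, step=2.0, error_rate=0.0)
        marker_cols = np.flatnonzero(probs.grid["is_marker"].to_numpy())
        for mi, gi in enumerate(marker_cols):
            obs = geno.matrix[:, mi]
            assert np.allclose(probs.p_b[obs == ALLELE_B, gi], 1.0)
            assert np.allclose(probs.p_b[obs == ALLELE_A, gi], 0.0)

    def test_probabilities_conserve_mass(self):
        gmap = simulate_genetic_map(rng_seed=1)
        geno = random_genotypes(gmap, 40, seed=1)
        probs = genotype_probabilities(gmap, geno, step=2.0, error_rate=0.01)
        assert np.all(probs.p_b >= 0) and np.all(probs.p_b <= 1)

    def test_midpoint_between_concordant_markers_matches_markov_oracle(self):
        """Pseudomarker halfway between two A-typed markers 2d apart:
        P(A) = p_AA(d)^2 / (p_AA(d)^2 + p_AB(d) p_BA(d)), hand-derived from
        the two-step chain."""
        d = 10.0
        gmap = GeneticMap(
            pd.DataFrame(
                {"marker": ["L", "R"], "chromosome": ["1", "1"], "pos_cm": [0.0, 2 * d]}
            )
        )
        geno = RILGenotypes(
            line_ids=["l1"], matrix=np.array([[ALLELE_A, ALLELE_A]], dtype=np.int8), map=gmap
        )
        probs = genotype_probabilities(gmap, geno, step=d, error_rate=0.0)
        mid = np.flatnonzero(~probs.grid["is_marker"].to_numpy())
        assert mid.size == 1
        r = haldane_r(d)
        p_aa = (1 - r) ** 2
        p_ab_ba = r * r
        expected_pa = p_aa / (p_aa + p_ab_ba)
        assert probs.p_b[0, mid[0]] == pytest.approx(1.0 - expected_pa, abs=1e-12)

    def test_untyped_line_uniform_and_flagged(self):
        gmap = toy_map((50.0,), (6,))
        matrix = np.full((12, 6), MISSING, dtype=np.int8)
        matrix[1:, :] = ALLELE_A
        matrix[0, :] = MISSING
        matrix[0, 0] = ALLELE_A  # keep the line valid overall
        two = toy_map((50.0, 50.0), (6, 6))
        m2 = np.hstack([matrix, np.full((12, 6), MISSING, dtype=np.int8)])
        m2[1:, 6:] = ALLELE_B
        geno = RILGenotypes(
            line_ids=[f"l{i}" for i in range(12)], matrix=m2, map=two
        )
        probs = genotype_probabilities(two, geno, step=5.0)
        chrom2 = probs.chromosome_slice("2")
        assert np.allclose(probs.p_b[0, chrom2], 0.5)
        assert ("l0", "2") in probs.uninformative

    def test_invalid_step_and_error_rate_rejected(self):
        gmap = toy_map()
        geno = random_genotypes(gmap, 12, seed=3)
        with pytest.raises(ValueError):
            genotype_probabilities(gmap, geno, step=0.0)
        with pytest.raises(ValueError):
            genotype_probabilities(gmap, geno, step=2.0, error_rate=0.7)


class TestHKScan:
    def test_constant_phenotype_flat_zero(self):
        gmap = toy_map()
        geno = random_genotypes(gmap, 25, seed=4)
        probs = genotype_probabilities(gmap, geno)
        phen = pd.Series(5.0, index=pd.Index(geno.line_ids))
        scan = hk_scan(probs, phen)
        assert np.allclose(scan.profile["lod"], 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_ols_oracle_at_typed_markers(self, seed):
        gmap = simulate_genetic_map(rng_seed=seed)
        cfg = SimRILConfig(n_lines=60, rng_seed=seed)
        geno = simulate_ril_genotypes(gmap, cfg)
        rng = np.random.default_rng(seed + 100)
        phen = pd.Series(rng.normal(size=60), index=pd.Index(geno.line_ids))
        probs = genotype_probabilities(gmap, geno, step=2.0)
        scan = hk_scan(probs, phen)
        marker_rows = np.flatnonzero(probs.grid["is_marker"].to_numpy())
        y = phen.to_numpy()
        for j in rng.choice(marker_rows, size=20, replace=False):
            x = probs.p_b[:, j]
            assert scan.profile["lod"].iat[j] == pytest.approx(ols_lod(x, y), abs=1e-8)

    def test_recovers_simulated_qtl_position(self):
        hits = 0
        n_rep = 40
        eff = additive_effect_for_share(0.25, 4.0, 8)
        for seed in range(n_rep):
            gmap = simulate_genetic_map(rng_seed=seed)
            cfg = SimRILConfig(n_lines=200, qtl_effects=(("3", 50.0, eff),), rng_seed=seed)
            geno = simulate_ril_genotypes(gmap, cfg)
            means, _ = simulate_ril_phenotypes(geno, gmap, cfg)
            probs = genotype_probabilities(gmap, geno, step=2.0)
            scan = hk_scan(probs, means)
            top = scan.profile.loc[scan.profile["lod"].idxmax()]
            (chrom, pos) = realized_qtl_positions(gmap, cfg)[0]
            if top["chromosome"] == chrom and abs(top["pos_cm"] - pos) <= 10.0:
                hits += 1
        assert hits >= int(0.9 * n_rep)


class TestCIM:
    def test_zero_covariates_reduces_to_hk(self):
        gmap = toy_map((80.0,), (9,))
        geno = random_genotypes(gmap, 30, seed=5)
        probs = genotype_probabilities(gmap, geno)
        rng = np.random.default_rng(6)
        phen = pd.Series(rng.normal(size=30), index=pd.Index(geno.line_ids))
        a = cim_scan(probs, phen, n_covariates=0)
        b = hk_scan(probs, phen)
        assert np.allclose(a.profile["lod"], b.profile["lod"])
        assert a.method == "cim"

    def test_covariate_count_capped_by_lines(self):
        gmap = toy_map()
        geno = random_genotypes(gmap, 15, seed=7)
        probs = genotype_probabilities(gmap, geno)
        phen = pd.Series(np.arange(15.0), index=pd.Index(geno.line_ids))
        with pytest.raises(ValueError, match="n_covariates"):
            cim_scan(probs, phen, n_covariates=15)

    def test_background_covariate_sharpens_second_qtl(self):
        """Absorbing one QTL as covariate raises expected LOD at the other."""
        eff = additive_effect_for_share(0.2, 4.0, 8)
        gains = []
        for seed in range(15):
            gmap = simulate_genetic_map(rng_seed=seed)
            cfg = SimRILConfig(
                n_lines=150,
                qtl_effects=(("1", 40.0, eff), ("4", 40.0, eff)),
                rng_seed=seed,
            )
            geno = simulate_ril_genotypes(gmap, cfg)
            means, _ = simulate_ril_phenotypes(geno, gmap, cfg)
            probs = genotype_probabilities(gmap, geno, step=2.0)
            single = hk_scan(probs, means)
            composite = cim_scan(probs, means, window=10.0, n_covariates=2)
            (chrom, pos) = realized_qtl_positions(gmap, cfg)[0]
            on_chrom = single.profile["chromosome"] == chrom
            near = on_chrom & (np.abs(single.profile["pos_cm"] - pos) < 5.0)
            gains.append(
                composite.profile.loc[near, "lod"].max()
                - single.profile.loc[near, "lod"].max()
            )
        assert np.mean(gains) > 0


class TestPermutations:
    def _setup(self, seed=0, n=60):
        gmap = simulate_genetic_map(rng_seed=seed)
        geno = random_genotypes(gmap, n, seed=seed)
        probs = genotype_probabilities(gmap, geno)
        return geno, probs

    def test_constant_phenotype_zero_thresholds(self):
        geno, probs = self._setup()
        phen = pd.Series(1.0, index=pd.Index(geno.line_ids))
        thr = permutation_thresholds(probs, phen, n_perm=100, seed=0)
        assert thr[0.05] == 0.0 and thr[0.63] == 0.0

    def test_seed_reproducibility_and_ordering(self):
        geno, probs = self._setup(seed=2)
        rng = np.random.default_rng(3)
        phen = pd.Series(rng.normal(size=60), index=pd.Index(geno.line_ids))
        a = permutation_thresholds(probs, phen, n_perm=200, seed=42)
        b = permutation_thresholds(probs, phen, n_perm=200, seed=42)
        assert a == b
        assert a[0.63] <= a[0.05]

    def test_too_few_permutations_rejected(self):
        geno, probs = self._setup()
        phen = pd.Series(np.arange(60.0), index=pd.Index(geno.line_ids))
        with pytest.raises(ValueError):
            permutation_thresholds(probs, phen, n_perm=50)


class TestBayesInterval:
    def _scan_from(self, positions, lods, chrom="1"):
        profile = pd.DataFrame(
            {
                "name": [f"p{i}" for i in range(len(positions))],
                "chromosome": chrom,
                "pos_cm": positions,
                "lod": lods,
            }
        )
        return ScanResult(profile=profile, method="hk")

    def test_two_point_hand_normalized_posterior(self):
        """LOD {0, 3}: posterior {1/1001, 1000/1001}; the high point alone
        already holds 95%."""
        scan = self._scan_from([0.0, 10.0], [0.0, 3.0])
        lo, hi, flat = bayes_interval(scan, "1", prob=0.95)
        assert (lo, hi) == (10.0, 10.0)
        assert not flat

    def test_flat_profile_spans_chromosome(self):
        pos = np.linspace(0, 100, 51)
        lo, hi, flat = bayes_interval(self._scan_from(pos, np.zeros(51)), "1")
        assert flat
        assert hi - lo >= 0.94 * 100

    def test_sharp_peak_contained(self):
        pos = np.linspace(0, 100, 101)
        lod = np.exp(-0.5 * ((pos - 40) / 3.0) ** 2) * 8
        lo, hi, _ = bayes_interval(self._scan_from(pos, lod), "1")
        assert lo <= 40 <= hi
        assert hi - lo < 30

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            bayes_interval(self._scan_from([0, 1], [0, 1]), "9")


class TestMultiQTLFit:
    def test_single_peak_drop_one_equals_single_regression(self):
        eff = additive_effect_for_share(0.25, 4.0, 8)
        gmap = simulate_genetic_map(rng_seed=3)
        cfg = SimRILConfig(n_lines=300, qtl_effects=(("2", 30.0, eff),), rng_seed=3)
        geno = simulate_ril_genotypes(gmap, cfg)
        means, _ = simulate_ril_phenotypes(geno, gmap, cfg)
        probs = genotype_probabilities(gmap, geno)
        (chrom, pos) = realized_qtl_positions(gmap, cfg)[0]
        peak = QTLPeak(chrom, pos, 10.0, "m", pos, pos, 0.0, "significant")
        fit = fit_multi_qtl(probs, means, [peak])
        drop_one = fit.loc[fit["term"] != "total", "r_squared"].iloc[0]
        total = fit.loc[fit["term"] == "total", "r_squared"].iloc[0]
        assert drop_one == pytest.approx(total, abs=1e-9)
        # independent check: plain R^2 of dosage regression
        d, _ = probs.dosage_at(chrom, pos)
        y = means.to_numpy()
        r2 = 100 * np.corrcoef(d, y)[0, 1] ** 2
        assert total == pytest.approx(r2, abs=1e-6)

    def test_null_phenotype_near_zero_shares(self):
        gmap = simulate_genetic_map(rng_seed=4)
        geno = random_genotypes(gmap, 200, seed=4)
        rng = np.random.default_rng(5)
        phen = pd.Series(rng.normal(size=200), index=pd.Index(geno.line_ids))
        probs = genotype_probabilities(gmap, geno)
        peaks = [
            QTLPeak("1", 20.0, 1.0, "m", 20.0, 20.0, 0.0, "suggestive"),
            QTLPeak("4", 50.0, 1.0, "m", 50.0, 50.0, 0.0, "suggestive"),
        ]
        fit = fit_multi_qtl(probs, phen, peaks)
        assert (fit["r_squared"].abs() < 5.0).all()

    def test_collinear_peaks_rejected_with_pair_named(self):
        gmap = simulate_genetic_map(rng_seed=6)
        geno = random_genotypes(gmap, 100, seed=6)
        probs = genotype_probabilities(gmap, geno)
        phen = pd.Series(
            np.random.default_rng(0).normal(size=100), index=pd.Index(geno.line_ids)
        )
        peaks = [
            QTLPeak("1", 20.0, 1.0, "m", 20.0, 20.0, 0.0, "suggestive"),
            QTLPeak("1", 20.5, 1.0, "m", 20.5, 20.5, 0.0, "suggestive"),
        ]
        with pytest.raises(ValueError, match="collinear"):
            fit_multi_qtl(probs, phen, peaks)


class TestScanTwo:
    def test_constant_phenotype_all_zero(self):
        gmap = simulate_genetic_map(rng_seed=7)
        geno = random_genotypes(gmap, 40, seed=7)
        probs = genotype_probabilities(gmap, geno)
        phen = pd.Series(2.0, index=pd.Index(geno.line_ids))
        res = scan_two(probs, phen, step=20.0)
        assert np.allclose(res.pairs[["lod_full", "lod_add"]], 0.0)

    def test_interaction_nonnegative_and_full_dominates(self):
        gmap = simulate_genetic_map(rng_seed=8)
        geno = random_genotypes(gmap, 80, seed=8)
        probs = genotype_probabilities(gmap, geno)
        phen = pd.Series(
            np.random.default_rng(9).normal(size=80), index=pd.Index(geno.line_ids)
        )
        res = scan_two(probs, phen, step=20.0)
        assert (res.pairs["lod_int"] >= -1e-9).all()
        assert (res.pairs["lod_full"] >= res.pairs["lod_add"] - 1e-9).all()

    def test_pure_epistasis_found_at_true_pair(self):
        """Phenotype = product of two unlinked loci (no marginal effects):
        the interaction LOD peaks at the true pair."""
        gmap = simulate_genetic_map(rng_seed=10)
        cfg = SimRILConfig(
            n_lines=300,
            qtl_effects=(("1", 40.0, 0.0), ("4", 40.0, 0.0)),
            epistatic_pairs=((0, 1, 1.0),),
            residual_sd=0.5,
            rng_seed=10,
        )
        geno = simulate_ril_genotypes(gmap, cfg)
        means, _ = simulate_ril_phenotypes(geno, gmap, cfg)
        probs = genotype_probabilities(gmap, geno)
        res = scan_two(probs, means, step=10.0)
        best = res.pairs.loc[res.pairs["lod_int"].idxmax()]
        truth = realized_qtl_positions(gmap, cfg)
        assert {best["chr1"], best["chr2"]} == {truth[0][0], truth[1][0]}
        assert abs(best["pos1"] - truth[0][1]) <= 10.0
        assert abs(best["pos2"] - truth[1][1]) <= 10.0

    def test_additive_pair_has_small_interaction(self):
        eff = additive_effect_for_share(0.2, 4.0, 8)
        ints = []
        for seed in range(10):
            gmap = simulate_genetic_map(rng_seed=seed)
            cfg = SimRILConfig(
                n_lines=200,
                qtl_effects=(("2", 30.0, eff), ("5", 60.0, eff)),
                rng_seed=seed,
            )
            geno = simulate_ril_genotypes(gmap, cfg)
            means, _ = simulate_ril_phenotypes(geno, gmap, cfg)
            probs = genotype_probabilities(gmap, geno)
            res = scan_two(probs, means, step=15.0)
            truth = realized_qtl_positions(gmap, cfg)
            near = (
                (res.pairs["chr1"] == truth[0][0])
                & (res.pairs["chr2"] == truth[1][0])
                & (np.abs(res.pairs["pos1"] - truth[0][1]) < 15)
                & (np.abs(res.pairs["pos2"] - truth[1][1]) < 15)
            )
            ints.append(res.pairs.loc[near, "lod_int"].min())
        assert np.median(ints) < 1.0

    def test_pair_budget_guard(self):
        gmap = simulate_genetic_map(rng_seed=11)
        geno = random_genotypes(gmap, 40, seed=11)
        probs = genotype_probabilities(gmap, geno)
        phen = pd.Series(
            np.random.default_rng(1).normal(size=40), index=pd.Index(geno.line_ids)
        )
        with pytest.raises(ValueError, match="step"):
            scan_two(probs, phen, step=2.0, max_pairs=100)


class TestCallPeaks:
    def _scan(self, lods, positions=None, chrom="1"):
        positions = positions if positions is not None else np.arange(len(lods), dtype=float)
        profile = pd.DataFrame(
            {
                "name": [f"g{i}" for i in range(len(lods))],
                "chromosome": chrom,
                "pos_cm": positions,
                "lod": lods,
            }
        )
        return ScanResult(profile=profile, method="hk")

    def test_below_suggestive_empty(self):
        gmap = simulate_genetic_map(rng_seed=12)
        geno = random_genotypes(gmap, 50, seed=12)
        probs = genotype_probabilities(gmap, geno)
        phen = pd.Series(1.0 + 0 * np.arange(50.0), index=pd.Index(geno.line_ids))
        scan = hk_scan(probs, phen + np.random.default_rng(2).normal(size=50))
        peaks = call_peaks(scan, {0.05: 99.0, 0.63: 98.0}, probs, phen)
        assert peaks == []

    def test_simulated_three_qtl_recovered(self):
        eff = additive_effect_for_share(0.18, 4.0, 8)
        found = 0
        n_rep = 20
        for seed in range(n_rep):
            gmap = simulate_genetic_map(rng_seed=seed)
            cfg = SimRILConfig(
                n_lines=300,
                qtl_effects=(("1", 30.0, eff), ("3", 50.0, eff), ("5", 80.0, eff)),
                rng_seed=seed,
            )
            geno = simulate_ril_genotypes(gmap, cfg)
            means, _ = simulate_ril_phenotypes(geno, gmap, cfg)
            probs = genotype_probabilities(gmap, geno)
            scan = hk_scan(probs, means)
            thr = permutation_thresholds(probs, means, n_perm=200, seed=seed)
            peaks = call_peaks(scan, thr, probs, means)
            chroms = {p.chromosome for p in peaks}
            if {"1", "3", "5"}.issubset(chroms):
                found += 1
        assert found >= int(0.8 * n_rep)
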