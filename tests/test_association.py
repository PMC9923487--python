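"""Two-factor AF model, simultaneous contrasts and SNP classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolcolor.association import (
    ContrastResult,
    classify_snp,
    encode_design,
    fit_af_glm,
    genome_scan,
    pairwise_contrasts,
    simultaneous_test,
)
from poolcolor.synthetic_data import SimulationConfig, simulate_records, study_pools
from poolcolor.variant_io import AFMatrix, PoolDefinition, apply_site_filters, build_af_matrix

from ._oracles import classify_oracle, ols_contrast_oracle

COLOR_PAIRS = ["yellow - red", "green - red", "green - yellow"]
SITE_PAIRS = [
    "Katiu - Takapoto",
    "Gambier - Takapoto",
    "Hatchery - Takapoto",
    "Gambier - Katiu",
    "Hatchery - Katiu",
    "Hatchery - Gambier",
]


class TestDesign:
    def test_study_layout_full_rank(self, pools12):
        design = encode_design(pools12)
        assert design.matrix.shape == (12, 6)
        assert np.linalg.matrix_rank(design.matrix) == 6
        assert not design.rank_warning
        assert design.column_names[0] == "(Intercept)"

    def test_single_level_factor_contributes_no_column(self, pools2):
        design = encode_design(pools2)
        assert design.matrix.shape == (2, 2)

    def test_unknown_label_rejected(self, pools12):
        with pytest.raises(ValueError, match="not in levels"):
            encode_design(pools12, color_levels=["red", "yellow", "green", "blue"][:2])

    def test_empty_cell_flags_rank_deficiency(self):
        pools = [
            PoolDefinition("a", site="S1", color="red", n_individuals=10),
            PoolDefinition("b", site="S1", color="green", n_individuals=10),
            PoolDefinition("c", site="S2", color="red", n_individuals=10),
        ]
        design = encode_design(pools, color_levels=["red", "green", "yellow"])
        assert design.rank_warning
        with pytest.raises(ValueError, match="rank"):
            fit_af_glm(np.zeros(3), design)


class TestFit:
    def test_constant_af_gives_intercept_only(self, pools12):
        design = encode_design(pools12)
        fit = fit_af_glm(np.full(12, 0.3), design)
        np.testing.assert_allclose(fit.beta, [0.3, 0, 0, 0, 0, 0], atol=1e-12)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-24)
        assert fit.df_resid == 6

    def test_noise_free_additive_construction_recovered_exactly(self, pools12):
        design = encode_design(pools12)
        beta = np.array([0.2, 0.3, 0.0, 0.1, 0.0, 0.0])  # red-baseline shift + Katiu
        y = design.matrix @ beta
        fit = fit_af_glm(y, design)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-12)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_cov_beta_symmetric_psd(self, pools12, rng):
        design = encode_design(pools12)
        fit = fit_af_glm(rng.uniform(0, 1, 12), design)
        np.testing.assert_allclose(fit.cov_beta, fit.cov_beta.T, atol=1e-10)
        assert (np.linalg.eigvalsh(fit.cov_beta) > -1e-12).all()


class TestContrasts:
    def test_pair_counts(self, pools12):
        design = encode_design(pools12)
        assert len(pairwise_contrasts("color", design).labels) == 3
        assert len(pairwise_contrasts("site", design).labels) == 6

    def test_rows_have_at_most_two_unit_entries(self, pools12):
        design = encode_design(pools12)
        for factor in ("color", "site"):
            K = pairwise_contrasts(factor, design).K
            assert set(np.unique(K)) <= {-1.0, 0.0, 1.0}
            assert ((K != 0).sum(axis=1) <= 2).all()

    def test_two_level_factor_single_row(self, pools2):
        design = encode_design(pools2)
        cs = pairwise_contrasts("color", design)
        assert cs.labels == ["green - red"]
        np.testing.assert_array_equal(cs.K, [[0.0, 1.0]])

    def test_unknown_factor(self, pools12):
        with pytest.raises(ValueError):
            pairwise_contrasts("depth", encode_design(pools12))


class TestSimultaneousTest:
    def _results(self, y, pools):
        design = encode_design(pools)
        fit = fit_af_glm(np.asarray(y, float), design)
        sets = [pairwise_contrasts("color", design), pairwise_contrasts("site", design)]
        return fit, sets, simultaneous_test(fit, sets)

    def test_constant_af_all_null(self, pools12):
        _, _, results = self._results(np.full(12, 0.4), pools12)
        assert all(r.estimate == 0 and r.p_adj == 1.0 for r in results)
        assert not any(r.degenerate for r in results)

    def test_noise_free_planted_difference_is_degenerate_exact(self, pools12):
        design = encode_design(pools12)
        y = design.matrix @ np.array([0.2, 0.3, 0.0, 0.0, 0.0, 0.0])
        fit = fit_af_glm(y, design)
        sets = [pairwise_contrasts("color", design), pairwise_contrasts("site", design)]
        results = {r.label: r for r in simultaneous_test(fit, sets)}
        assert results["yellow - red"].estimate == pytest.approx(0.3, abs=1e-12)
        assert results["yellow - red"].p_adj == 0.0
        assert results["yellow - red"].degenerate

    def test_matches_textbook_oracle(self, pools12, rng):
        design = encode_design(pools12)
        sets = [pairwise_contrasts("color", design), pairwise_contrasts("site", design)]
        K = np.vstack([s.K for s in sets])
        for _ in range(100):
            y = rng.uniform(0, 1, 12)
            fit = fit_af_glm(y, design)
            results = simultaneous_test(fit, sets)
            oracle = ols_contrast_oracle(y, design.matrix, K)
            for r, (est, se, t, p) in zip(results, oracle):
                assert r.estimate == pytest.approx(est, abs=1e-10)
                assert r.se == pytest.approx(se, abs=1e-10)
                assert r.statistic == pytest.approx(t, abs=1e-8)
                assert r.p_raw == pytest.approx(p, abs=1e-10)
                assert r.p_adj == pytest.approx(min(1.0, 9 * p), abs=1e-10)

    def test_matches_statsmodels(self, pools12, rng):
        sm = pytest.importorskip("statsmodels.api")
        design = encode_design(pools12)
        sets = [pairwise_contrasts("color", design), pairwise_contrasts("site", design)]
        K = np.vstack([s.K for s in sets])
        y = rng.uniform(0, 1, 12)
        fit = fit_af_glm(y, design)
        ours = simultaneous_test(fit, sets)
        res = sm.OLS(y, design.matrix).fit()
        tt = res.t_test(K)
        np.testing.assert_allclose([r.estimate for r in ours], tt.effect, atol=1e-10)
        np.testing.assert_allclose([r.se for r in ours], tt.sd, atol=1e-10)
        np.testing.assert_allclose([r.p_raw for r in ours], tt.pvalue, atol=1e-10)

    def test_bonferroni_never_below_raw(self, pools12, rng):
        _, _, results = self._results(rng.uniform(0, 1, 12), pools12)
        assert all(r.p_adj >= r.p_raw for r in results)


def results_from_pattern(bits):
    """Build ContrastResults from a 9-bit significance pattern (p 1e-12 / 0.5)."""
    out = []
    for lab, bit in zip(COLOR_PAIRS, bits[:3]):
        p = 1e-12 if bit else 0.5
        out.append(ContrastResult(lab, "color", 0.1, 0.01, 10.0, p / 9, p))
    for lab, bit in zip(SITE_PAIRS, bits[3:]):
        p = 1e-12 if bit else 0.5
        out.append(ContrastResult(lab, "site", 0.1, 0.01, 10.0, p / 9, p))
    return out


class TestClassification:
    COLORS = ["red", "yellow", "green"]

    def test_all_null(self):
        cls = classify_snp(results_from_pattern([0] * 9), color_levels=self.COLORS)
        assert (cls.color_associated, cls.specific_color, cls.geography_associated) == (
            False,
            None,
            False,
        )

    def test_red_specific(self):
        # both red pairs significant, third pair not, no site pair
        cls = classify_snp(
            results_from_pattern([1, 1, 0] + [0] * 6), color_levels=self.COLORS
        )
        assert cls.color_associated and cls.specific_color == "red"

    def test_geography_excludes_color(self):
        cls = classify_snp(
            results_from_pattern([0, 0, 1] + [1, 0, 0, 0, 0, 0]),
            color_levels=self.COLORS,
        )
        assert not cls.color_associated and cls.geography_associated

    def test_all_color_pairs_significant_is_ambiguous(self):
        cls = classify_snp(
            results_from_pattern([1, 1, 1] + [0] * 6), color_levels=self.COLORS
        )
        assert cls.color_associated and cls.specific_color is None
        assert cls.all_color_pairs

    def test_exhaustive_pattern_sweep_matches_brute_force(self):
        for bits in itertools.product([0, 1], repeat=9):
            cls = classify_snp(results_from_pattern(bits), color_levels=self.COLORS)
            color_sig = dict(zip(COLOR_PAIRS, map(bool, bits[:3])))
            site_sig = dict(zip(SITE_PAIRS, map(bool, bits[3:])))
            expected = classify_oracle(color_sig, site_sig, self.COLORS, COLOR_PAIRS)
            assert (
                cls.color_associated,
                cls.specific_color,
                cls.geography_associated,
                cls.all_color_pairs,
            ) == expected
            # structural invariants
            if cls.specific_color is not None:
                assert cls.color_associated
            if cls.color_associated:
                assert not cls.geography_associated

    def test_duplicate_label_rejected(self):
        results = results_from_pattern([0] * 9)
        with pytest.raises(ValueError, match="duplicate"):
            classify_snp(results + [results[0]], color_levels=self.COLORS)

    @given(st.lists(st.floats(0, 1), min_size=9, max_size=9))
    @settings(max_examples=100, deadline=None)
    def test_shrinking_alpha_never_adds_significant_pairs(self, padjs):
        results = []
        for lab, p in zip(COLOR_PAIRS + SITE_PAIRS, padjs):
            factor = "color" if lab in COLOR_PAIRS else "site"
            results.append(ContrastResult(lab, factor, 0.1, 0.01, 1.0, p, p))
        loose = classify_snp(results, alpha=1e-3, color_levels=self.COLORS)
        tight = classify_snp(results, alpha=1e-6, color_levels=self.COLORS)
        assert tight.significant_pairs <= loose.significant_pairs


class TestGenomeScan:
    def _matrix(self, Y, pools):
        loci = [("chr1", 10 * (i + 1), "A", "G") for i in range(Y.shape[1])]
        return AFMatrix(pools=pools, loci=loci, values=Y)

    def test_vectorised_scan_equals_per_locus_path(self, pools12, rng):
        Y = rng.uniform(0, 1, (12, 40))
        matrix = self._matrix(Y, pools12)
        table, _ = genome_scan(matrix, alpha=0.05)
        design = encode_design(pools12)
        sets = [pairwise_contrasts("color", design), pairwise_contrasts("site", design)]
        for i in range(40):
            fit = fit_af_glm(Y[:, i], design)
            results = simultaneous_test(fit, sets)
            cls = classify_snp(results, alpha=0.05, color_levels=design.color_levels)
            row = table.iloc[i]
            for r in results:
                assert row[f"est({r.label})"] == pytest.approx(r.estimate, abs=1e-10)
                assert row[f"p_adj({r.label})"] == pytest.approx(r.p_adj, abs=1e-10)
            assert row["color_associated"] == cls.color_associated
            assert row["specific_color"] == (cls.specific_color or None)
            assert row["geography_associated"] == cls.geography_associated

    def test_empty_matrix(self, pools12):
        table, summary = genome_scan(self._matrix(np.empty((12, 0)), pools12))
        assert len(table) == 0
        assert summary["n_color_associated"] == 0

    def test_null_matrix_no_calls_at_stringent_alpha(self, pools12, rng):
        Y = np.clip(0.4 + rng.normal(0, 0.05, (12, 1000)), 0, 1)
        _, summary = genome_scan(self._matrix(Y, pools12), alpha=1e-9)
        assert summary["n_color_associated"] == 0
        assert summary["n_geography_associated"] == 0

    def test_planted_red_shift_recovered(self):
        """Strong red-vs-rest shifts are recovered as red-specific calls."""
        config = SimulationConfig(
            seed=42,
            n_loci=250,
            fractions={"neutral": 0.8, "color": 0.2, "site": 0.0, "both": 0.0},
            color_effect=0.4,
            mean_depth=100.0,
            pools=study_pools(n_individuals=20),
            # keep headroom so the planted shift is not attenuated by clamping
            baseline_af=("uniform", 0.05, 0.55),
        )
        records, truth = simulate_records(config)
        kept, _ = apply_site_filters(records)
        matrix = build_af_matrix(kept, config.pools)
        table, _ = genome_scan(matrix, alpha=0.05)
        kept_pos = {key[1] for key in matrix.loci}
        red_pos = {
            int(p)
            for p, cls, col in zip(truth.positions, truth.locus_class, truth.affected_color)
            if cls == "color" and col == "red" and int(p) in kept_pos
        }
        called = set(table.loc[table["specific_color"] == "red", "pos"])
        assert len(red_pos) >= 15
        sensitivity = len(called & red_pos) / len(red_pos)
        assert sensitivity >= 0.9

    def test_genome_family_scope_is_stricter(self, pools12, rng):
        Y = rng.uniform(0.2, 0.8, (12, 50))
        matrix = self._matrix(Y, pools12)
        snp_table, _ = genome_scan(matrix, alpha=0.05, family_scope="snp")
        genome_table, _ = genome_scan(matrix, alpha=0.05, family_scope="genome")
        pair_cols = [c for c in snp_table.columns if c.startswith("p_adj(")]
        assert (genome_table[pair_cols].to_numpy() >= snp_table[pair_cols].to_numpy() - 1e-15).all()
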