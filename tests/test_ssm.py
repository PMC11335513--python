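import numpy as np
import pytest

from ssmmed import ssm
from ssmmed.cohort import CohortConfig, VolumeMatrix, generate_cohort


def _vm(values, log_scale=False):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return VolumeMatrix(
        values=values,
        region_names=tuple(f"r{j}" for j in range(p)),
        subject_ids=tuple(f"s{i}" for i in range(n)),
        log_scale=log_scale,
    )


class TestPreprocess:
    def test_constant_matrix_log_only(self):
        m = _vm(np.full((4, 3), 5.0))
        out = ssm.preprocess_volumes(m, np.ones(4) * 1000, mode="log_only")
        np.testing.assert_allclose(out.values, np.log(5.0))

    def test_closed_form_log_only(self):
        e = np.e
        m = _vm([[1, e], [e, 1], [e, e]])
        out = ssm.preprocess_volumes(m, np.ones(3), mode="log_only")
        np.testing.assert_allclose(out.values, [[0, 1], [1, 0], [1, 1]], atol=1e-14)

    def test_constant_tiv_falls_back_to_log_only(self, rng):
        m = _vm(np.exp(rng.normal(1, 0.2, size=(10, 4))))
        tiv = np.full(10, 1500.0)
        with pytest.warns(UserWarning, match="constant TIV"):
            resid = ssm.preprocess_volumes(m, tiv, mode="log_tiv_residual")
        plain = ssm.preprocess_volumes(m, tiv, mode="log_only")
        np.testing.assert_allclose(resid.values, plain.values, rtol=1e-12)

    def test_residual_mode_removes_tiv_association(self, rng):
        tiv = np.exp(rng.normal(7.3, 0.1, size=200))
        values = np.exp(
            np.log(tiv)[:, None] * 0.9 + rng.normal(0, 0.05, size=(200, 5))
        )
        out = ssm.preprocess_volumes(_vm(values), tiv, mode="log_tiv_residual")
        for j in range(5):
            r = np.corrcoef(out.values[:, j], np.log(tiv))[0, 1]
            assert abs(r) < 1e-10

    def test_residual_mode_preserves_column_means(self, rng):
        tiv = np.exp(rng.normal(7.3, 0.1, size=50))
        m = _vm(np.exp(rng.normal(1, 0.2, size=(50, 3))))
        out = ssm.preprocess_volumes(m, tiv, mode="log_tiv_residual")
        np.testing.assert_allclose(
            out.values.mean(axis=0), np.log(m.values).mean(axis=0), rtol=1e-12
        )

    def test_nonpositive_volume_listed(self):
        m = _vm([[1.0, 2.0], [3.0, -4.0]], log_scale=True)
        with pytest.raises(ValueError, match=r"\(s1, r1\)"):
            ssm.preprocess_volumes(m, np.ones(2), mode="log_only")


class TestDoubleCenter:
    def test_additive_model_removed(self, rng):
        u = rng.normal(size=30)
        v = rng.normal(size=8)
        srp = ssm.double_center(u[:, None] + v[None, :])
        np.testing.assert_allclose(srp, 0.0, atol=1e-12)

    def test_hand_computed_2x2(self):
        srp = ssm.double_center(np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(srp, [[-1, 1], [1, -1]], atol=1e-14)

    def test_row_and_col_means_vanish(self, rng):
        x = rng.normal(3.0, 1.0, size=(50, 14))
        srp = ssm.double_center(x)
        scale = np.abs(x).max()
        assert np.abs(srp.mean(axis=1)).max() < 1e-10 * scale
        assert np.abs(srp.mean(axis=0)).max() < 1e-10 * scale

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ssm.double_center(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestDeriveComponents:
    def test_rank_one_srp(self, rng):
        u = rng.normal(size=40)
        w = rng.normal(size=6)
        srp = ssm.double_center(np.outer(u, w))
        dec = ssm.derive_components(srp)
        assert dec.eigenvalues[0] > 0
        np.testing.assert_allclose(dec.eigenvalues[1:], 0.0, atol=1e-20)

    def test_reconstruction(self, rng):
        srp = ssm.double_center(rng.normal(size=(60, 10)))
        dec = ssm.derive_components(srp)
        np.testing.assert_allclose(dec.ssf @ dec.gis.T, srp, atol=1e-8)

    def test_orthonormal_loadings(self, rng):
        srp = ssm.double_center(rng.normal(size=(60, 10)))
        dec = ssm.derive_components(srp)
        k = dec.n_components
        np.testing.assert_allclose(dec.gis.T @ dec.gis, np.eye(k), atol=1e-8)

    def test_uncorrelated_scores(self, rng):
        srp = ssm.double_center(rng.normal(size=(80, 9)))
        dec = ssm.derive_components(srp)
        c = np.corrcoef(dec.ssf, rowvar=False)
        np.testing.assert_allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-8)

    def test_nonincreasing_eigenvalues(self, rng):
        dec = ssm.derive_components(ssm.double_center(rng.normal(size=(50, 8))))
        assert np.all(np.diff(dec.eigenvalues) <= 1e-12)

    def test_all_zero_warns_empty(self):
        with pytest.warns(UserWarning, match="all-zero"):
            dec = ssm.derive_components(np.zeros((5, 3)))
        assert dec.n_components == 0

    def test_planted_pattern_is_leading_component(self, cohort500_low_noise):
        df, vol = cohort500_low_noise
        config = CohortConfig()
        pre = ssm.preprocess_volumes(vol, df["tiv"].to_numpy())
        dec = ssm.derive_components(ssm.double_center(pre.values))
        cos = abs(float(dec.gis[:, 0] @ config.pattern_weights))
        assert cos >= 0.9


def _brute_force_aic(ssf, biomarker, max_k):
    """Independent AIC trace via explicit normal-equation fits."""
    n = len(biomarker)
    out = []
    for k in range(1, max_k + 1):
        X = np.column_stack([np.ones(n), ssf[:, :k]])
        beta = np.linalg.solve(X.T @ X, X.T @ biomarker)
        rss = float(np.sum((biomarker - X @ beta) ** 2))
        rss = max(rss, 1e-12 * float(np.var(biomarker) * n))
        out.append(n * np.log(rss / n) + 2 * (k + 2))
    return np.asarray(out)


class TestSelectComponentSet:
    def test_perfect_fit_selects_first(self, rng):
        srp = ssm.double_center(rng.normal(size=(100, 8)))
        dec = ssm.derive_components(srp)
        biomarker = dec.ssf[:, 0].copy()
        cset, coefs, aic = ssm.select_component_set(dec.ssf, biomarker, max_k=4)
        assert cset == (1,)
        assert np.isfinite(aic).all()

    def test_argmin_property(self, rng):
        srp = ssm.double_center(rng.normal(size=(200, 10)))
        dec = ssm.derive_components(srp)
        biomarker = rng.normal(size=200)
        cset, _, aic = ssm.select_component_set(dec.ssf, biomarker, max_k=6)
        assert aic[len(cset) - 1] == aic.min()

    def test_trace_matches_brute_force(self, rng):
        srp = ssm.double_center(rng.normal(size=(150, 12)))
        dec = ssm.derive_components(srp)
        biomarker = rng.normal(size=150)
        _, _, aic = ssm.select_component_set(dec.ssf, biomarker, max_k=5)
        np.testing.assert_allclose(aic, _brute_force_aic(dec.ssf, biomarker, 5), rtol=1e-10)

    def test_two_loading_components_selected(self):
        # Both informative components must be retained nearly always; the
        # exact prefix {1,2} only in the clear majority, since AIC admits a
        # spurious extra component with probability P(chi2_1 > 2) ~ 0.16.
        exact = contains = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            srp = ssm.double_center(r.normal(size=(200, 10)))
            dec = ssm.derive_components(srp)
            s1 = dec.ssf[:, 0] / dec.ssf[:, 0].std()
            s2 = dec.ssf[:, 1] / dec.ssf[:, 1].std()
            biomarker = s1 + s2 + 0.3 * r.normal(size=200)
            cset, _, _ = ssm.select_component_set(dec.ssf, biomarker, max_k=6)
            exact += cset == (1, 2)
            contains += set(cset) >= {1, 2}
        assert contains >= 0.9 * n_seeds
        assert exact >= 0.6 * n_seeds

    def test_max_k_validation(self, rng):
        dec = ssm.derive_components(ssm.double_center(rng.normal(size=(30, 5))))
        with pytest.raises(ValueError, match="max_k"):
            ssm.select_component_set(dec.ssf, rng.normal(size=30), max_k=0)

    def test_constant_biomarker_rejected(self, rng):
        dec = ssm.derive_components(ssm.double_center(rng.normal(size=(30, 5))))
        with pytest.raises(ValueError, match="zero variance"):
            ssm.select_component_set(dec.ssf, np.ones(30), max_k=2)


class TestCombineAndExpress:
    def _derive(self, cohort):
        df, vol = cohort
        return ssm.derive_pattern(
            vol, df["tiv"].to_numpy(), df["hcy"].to_numpy()
        )

    def test_unit_norm_weights(self, cohort160):
        model, _, _ = self._derive(cohort160)
        assert np.linalg.norm(model.weights) == pytest.approx(1.0, abs=1e-10)

    def test_single_component_proportional_to_gis(self, rng):
        srp = ssm.double_center(rng.normal(size=(50, 6)))
        dec = ssm.derive_components(srp)
        biomarker = dec.ssf[:, 0] + 0.1 * rng.normal(size=50)
        model = ssm.combine_pattern(dec, (1,), np.array([2.0]), biomarker)
        cos = abs(float(model.weights @ dec.gis[:, 0]))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_biomarker_sign_flip_equivariance(self, rng):
        srp = ssm.double_center(rng.normal(size=(50, 6)))
        dec = ssm.derive_components(srp)
        biomarker = dec.ssf[:, 0] + 0.1 * rng.normal(size=50)
        m_pos = ssm.combine_pattern(dec, (1,), np.array([1.0]), biomarker)
        m_neg = ssm.combine_pattern(dec, (1,), np.array([1.0]), -biomarker)
        assert m_pos.sign_convention == -m_neg.sign_convention
        np.testing.assert_allclose(np.abs(m_pos.weights), np.abs(m_neg.weights))

    def test_zero_norm_weights_rejected(self, rng):
        srp = ssm.double_center(rng.normal(size=(50, 6)))
        dec = ssm.derive_components(srp)
        with pytest.raises(ValueError, match="zero norm"):
            ssm.combine_pattern(dec, (1, 2), np.zeros(2), rng.normal(size=50))

    def test_planted_contrast_signs(self, cohort500_low_noise):
        # hippocampus/accumbens share one sign, basal ganglia the other
        model, _, _ = self._derive(cohort500_low_noise)
        w = dict(zip(model.preprocessing.region_names, model.weights))
        hip = [w[r] for r in w if r.startswith(("hippocampus", "accumbens"))]
        bg = [w[r] for r in w if r.startswith(("caudate", "putamen", "pallidum"))]
        assert len({np.sign(x) for x in hip}) == 1
        assert len({np.sign(x) for x in bg}) == 1
        assert np.sign(hip[0]) == -np.sign(bg[0])

    def test_planted_weights_recovered(self, cohort500_low_noise):
        model, _, _ = self._derive(cohort500_low_noise)
        cos = abs(float(model.weights @ CohortConfig().pattern_weights))
        assert cos >= 0.9

    def test_expression_z_scored_on_derivation_sample(self, cohort160):
        _, _, scores = self._derive(cohort160)
        assert scores.z.mean() == pytest.approx(0.0, abs=1e-10)
        assert scores.z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_expression_positively_correlates_with_biomarker(self, cohort160):
        df, _ = cohort160
        _, _, scores = self._derive(cohort160)
        assert np.corrcoef(scores.z, df["hcy"])[0, 1] >= 0

    def test_duplicated_subjects_score_identically(self, cohort160):
        df, vol = cohort160
        model, _, _ = self._derive(cohort160)
        doubled = VolumeMatrix(
            values=np.vstack([vol.values, vol.values]),
            region_names=vol.region_names,
            subject_ids=tuple(f"{s}_{t}" for t in ("a", "b") for s in vol.subject_ids),
        )
        tiv2 = np.concatenate([df["tiv"], df["tiv"]])
        scores = ssm.express_pattern(model, doubled, tiv2)
        np.testing.assert_allclose(scores.z[:160], scores.z[160:], rtol=1e-12)

    def test_expression_recovers_hidden_truth(self, cohort500_low_noise):
        df, _ = cohort500_low_noise
        _, _, scores = self._derive(cohort500_low_noise)
        r = abs(np.corrcoef(scores.z, df["true_expression"])[0, 1])
        assert r >= 0.8

    def test_region_mismatch_errors(self, cohort160):
        df, vol = cohort160
        model, _, _ = self._derive(cohort160)
        truncated = VolumeMatrix(
            values=vol.values[:, :13],
            region_names=vol.region_names[:13],
            subject_ids=vol.subject_ids,
        )
        with pytest.raises(ValueError, match="region mismatch"):
            ssm.express_pattern(model, truncated, df["tiv"].to_numpy())

    def test_region_reordering_invariance(self, cohort160):
        df, vol = cohort160
        model, _, scores = self._derive(cohort160)
        perm = np.random.default_rng(0).permutation(14)
        shuffled = VolumeMatrix(
            values=vol.values[:, perm],
            region_names=tuple(vol.region_names[j] for j in perm),
            subject_ids=vol.subject_ids,
        )
        scores2 = ssm.express_pattern(model, shuffled, df["tiv"].to_numpy())
        np.testing.assert_allclose(scores2.z, scores.z, rtol=1e-10)

    def test_scale_equivariance(self, cohort160):
        # multiplying all volumes by c > 0 leaves expression z unchanged
        df, vol = cohort160
        tiv = df["tiv"].to_numpy()
        hcy = df["hcy"].to_numpy()
        m1, d1, s1 = ssm.derive_pattern(vol, tiv, hcy, mode="log_only")
        scaled = VolumeMatrix(
            values=vol.values * 3.7,
            region_names=vol.region_names,
            subject_ids=vol.subject_ids,
        )
        m2, d2, s2 = ssm.derive_pattern(scaled, tiv, hcy, mode="log_only")
        np.testing.assert_allclose(d2.srp, d1.srp, atol=1e-10)
        np.testing.assert_allclose(s2.z, s1.z, atol=1e-8)

    def test_model_json_round_trip(self, cohort160):
        df, vol = cohort160
        model, _, scores = self._derive(cohort160)
        back = ssm.PatternModel.from_dict(model.to_dict())
        scores2 = ssm.express_pattern(back, vol, df["tiv"].to_numpy())
        np.testing.assert_allclose(scores2.z, scores.z, rtol=1e-12)


class TestBootstrapPattern:
    def test_determinism(self, cohort160):
        df, vol = cohort160
        args = (vol, df["tiv"].to_numpy(), df["hcy"].to_numpy(), 100, 21)
        r1 = ssm.bootstrap_pattern(*args)
        r2 = ssm.bootstrap_pattern(*args)
        np.testing.assert_array_equal(r1.weight_sd, r2.weight_sd)
        np.testing.assert_array_equal(r1.ci_lower, r2.ci_lower)

    def test_minimum_iterations_enforced(self, cohort160):
        df, vol = cohort160
        with pytest.raises(ValueError, match="n_iterations"):
            ssm.bootstrap_pattern(vol, df["tiv"].to_numpy(), df["hcy"].to_numpy(), 50, 0)

    def test_planted_pattern_reliable_regions(self):
        # strongly planted regions should show |Z| > 2 in nearly all seeds
        config = CohortConfig()
        strong = np.abs(config.pattern_weights) > 0.3
        hits = total = 0
        for seed in range(20):
            df, vol = generate_cohort(
                CohortConfig(n_subjects=300, seed=seed, region_noise_sd=0.01,
                             hcy_loading=0.8)
            )
            rel = ssm.bootstrap_pattern(
                vol, df["tiv"].to_numpy(), df["hcy"].to_numpy(), 100, seed
            )
            hits += int(np.sum(np.abs(rel.weight_z[strong]) > 2))
            total += int(strong.sum())
        assert hits >= 0.9 * total

    def test_null_biomarker_few_reliable_regions(self):
        # with a pure-noise biomarker the pattern is noise; few regions
        # should look reliable
        fractions = []
        for seed in range(5):
            df, vol = generate_cohort(CohortConfig(n_subjects=200, seed=seed))
            noise = np.random.default_rng(seed + 1000).normal(size=200)
            rel = ssm.bootstrap_pattern(vol, df["tiv"].to_numpy(), noise, 100, seed)
            fractions.append(np.mean(np.abs(rel.weight_z) > 2))
        assert np.mean(fractions) < 0.25

    def test_ci_contains_point_for_most_regions(self, cohort160):
        df, vol = cohort160
        rel = ssm.bootstrap_pattern(
            vol, df["tiv"].to_numpy(), df["hcy"].to_numpy(), 200, 3
        )
        inside = (rel.ci_lower <= rel.point_weights) & (
            rel.point_weights <= rel.ci_upper
        )
        assert inside.mean() >= 0.95
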