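import numpy as np
import pytest

from qbdspace import (
    CQASpec,
    MonteCarloDesignSpace,
    SimulationConfig,
    estimate_noise,
    verify_point,
)
from qbdspace.datasets import default_synthetic_spec, generate_synthetic
from qbdspace.mc import design_space, map_to_frame
from qbdspace.rsm import TERMS, term_matrix


@pytest.fixture(scope="module")
def small_ensemble(design, limits):
    est = MonteCarloDesignSpace(
        n_sims=50, step_length=0.2, alpha=0.35, random_state=123
    ).fit(design, limits)
    return est


class TestEnsemble:
    def test_same_seed_identical(self, design, limits):
        a = MonteCarloDesignSpace(n_sims=20, random_state=7).fit(design, limits)
        b = MonteCarloDesignSpace(n_sims=20, random_state=7).fit(design, limits)
        np.testing.assert_array_equal(a.coefs_, b.coefs_)
        np.testing.assert_array_equal(a.masks_, b.masks_)

    def test_zero_noise_single_sim_equals_point_fit(self, factors):
        spec = default_synthetic_spec(seed=5, noise_rsd=0.0)
        table = generate_synthetic(spec)
        wide = [CQASpec(n, "", 1e-6, 1e6) for n in table.cqa_names]
        est = MonteCarloDesignSpace(n_sims=1, random_state=0).fit(table, wide)
        for qi, name in enumerate(table.cqa_names):
            point = est.point_models_[name]
            sim_intercept = est.coefs_[qi, 0, 0]
            assert sim_intercept == pytest.approx(point.intercept_, abs=1e-10)

    def test_ensemble_mean_intercept_unbiased(self, design, limits):
        """Under symmetric noise the ensemble-mean intercept stays within
        3 SE of the point-estimate intercept."""
        est = MonteCarloDesignSpace(n_sims=1000, random_state=31).fit(design, limits)
        qi = design.cqa_names.index("danshensu")
        draws = est.coefs_[qi, :, 0]
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        point = est.point_models_["danshensu"].intercept_
        assert abs(draws.mean() - point) < 3 * se

    def test_parameter_recovery_on_synthetic_truth(self):
        """Ensemble-mean coefficients of always-selected terms recover the
        generating coefficients within 3 Monte-Carlo SE."""
        spec = default_synthetic_spec(seed=17, noise_rsd=0.05)
        table = generate_synthetic(spec)
        wide = [CQASpec(n, "", 1e-6, 1e6) for n in table.cqa_names]
        est = MonteCarloDesignSpace(n_sims=2000, random_state=17).fit(table, wide)
        for qi, name in enumerate(table.cqa_names):
            truth = np.asarray(spec.true_coefficients[name])
            always = np.ones(len(TERMS), dtype=bool)
            for t in range(len(TERMS)):
                always[t] = np.all((est.masks_[qi] >> t) & 1)
            for t in np.flatnonzero(always):
                draws = est.coefs_[qi, :, 1 + t]
                # the ensemble is centred on one measured realization, so the
                # relevant Monte-Carlo SE is the per-fit coefficient spread
                se = draws.std(ddof=1)
                assert abs(draws.mean() - truth[1 + t]) < 3 * se + 1e-12, (name, TERMS[t])


class TestProbabilityMap:
    def test_infinite_limits_give_probability_one(self, small_ensemble, design):
        wide = [CQASpec(n, "", -np.inf, np.inf) for n in design.cqa_names]
        pmap = small_ensemble.probability_map(wide, slice_value=0.0)
        assert np.all(pmap.prob == 1.0)

    def test_cells_match_brute_force_counting(self, small_ensemble, design, limits):
        """Every map cell is the exact empirical fraction over the stored
        ensemble, reproduced bit-for-bit by an explicit per-entry loop."""
        pmap = small_ensemble.probability_map(limits, slice_value=0.0)
        lower = np.array([l.lower for l in limits])
        upper = np.array([l.upper for l in limits])
        rng = np.random.default_rng(0)
        cells = [(0, 0), (5, 5), (10, 3)] + [
            tuple(rng.integers(0, len(pmap.x1), 2)) for _ in range(5)
        ]
        for i, j in cells:
            pt = np.zeros(3)
            pt[0], pt[1] = pmap.x1[i], pmap.x2[j]
            pt[2] = pmap.slice_value
            basis = np.concatenate([[1.0], term_matrix(pt[None])[0]])
            count = 0
            for s in range(small_ensemble.coefs_.shape[1]):
                ok = True
                for qi in range(len(limits)):
                    pred = float(small_ensemble.coefs_[qi, s] @ basis)
                    if not (lower[qi] <= pred <= upper[qi]):
                        ok = False
                        break
                count += ok
            assert pmap.prob[i, j] == count / small_ensemble.coefs_.shape[1]

    def test_zero_noise_map_is_indicator_of_point_models(self, limits, factors):
        spec = default_synthetic_spec(seed=5, noise_rsd=0.0)
        table = generate_synthetic(spec)
        lims = [
            CQASpec("resp_a", "", 2.0, 3.8),
            CQASpec("resp_b", "", 400.0, 550.0),
        ]
        est = MonteCarloDesignSpace(n_sims=5, step_length=0.25, random_state=3).fit(
            table, lims
        )
        pmap = est.probability_map(lims, slice_value=0.0)
        assert set(np.unique(pmap.prob)) <= {0.0, 1.0}
        # indicator agrees with the point-estimate models
        A, B = np.meshgrid(pmap.x1, pmap.x2, indexing="ij")
        pts = np.column_stack([A.ravel(), B.ravel(), np.zeros(A.size)])
        ok = np.ones(A.size, dtype=bool)
        for l in lims:
            pred = est.point_models_[l.name].predict(pts)
            ok &= (pred >= l.lower) & (pred <= l.upper)
        np.testing.assert_array_equal(pmap.prob.ravel() == 1.0, ok)

    def test_mask_monotone_in_threshold(self, small_ensemble, limits):
        pmap = small_ensemble.probability_map(limits, slice_value=0.0)
        high = pmap.mask(0.99)
        low = pmap.mask(0.90)
        assert np.all(low[high])  # high-threshold mask is a subset
        assert pmap.mask(1.01).sum() == 0  # unattainable threshold -> empty

    def test_dss_of_saturated_map(self, small_ensemble, design):
        wide = [CQASpec(n, "", -np.inf, np.inf) for n in design.cqa_names]
        pmap = small_ensemble.probability_map(wide, slice_value=0.0)
        assert pmap.dss(0.95) == 1.0
        res = design_space(pmap, SimulationConfig(n_sims=50, threshold=0.95))
        assert res.dss == 1.0

    def test_map_frame_layout(self, small_ensemble, design, limits):
        pmap = small_ensemble.probability_map(limits, slice_value=0.0)
        frame = map_to_frame(pmap, design, 0.95)
        assert len(frame) == len(pmap.x1) ** 2
        assert {"probability", "in_design_space"} <= set(frame.columns)
        # uncoded axes decode the coded ones
        assert frame["extraction_time_uncoded"].min() == pytest.approx(0.5)
        assert frame["wm_ratio_uncoded"].max() == pytest.approx(10.0)


class TestVerifyPoint:
    def test_center_point_zero_noise_prediction_is_direct_evaluation(self, factors):
        spec = default_synthetic_spec(seed=5, noise_rsd=0.0)
        table = generate_synthetic(spec)
        wide = [CQASpec(n, "", 1e-6, 1e6) for n in table.cqa_names]
        cfg = SimulationConfig(n_sims=1, seed=0)
        center = [f.center for f in table.factors]
        report = verify_point(table, wide, cfg, center)
        for name in table.cqa_names:
            truth = np.asarray(spec.true_coefficients[name])
            # coded zeros kill every term: prediction = selected intercept
            direct = report["point_estimate"][name]
            assert report["ensemble_mean"][name] == pytest.approx(direct, abs=1e-9)
        assert report["joint_probability"] == 1.0
        assert not report["extrapolated"]

    def test_out_of_range_point_flagged(self, design, limits):
        cfg = SimulationConfig(n_sims=5, seed=1)
        report = verify_point(design, limits, cfg, [2.5, 8.0, 2.0])
        assert report["extrapolated"]
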