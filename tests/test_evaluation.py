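"""Hierarchical treatment sampling, discrete mapping and dose accumulation."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from bhrobust.evaluation import (EvaluationImageProvider, ScenarioDoseCache,
                                 accumulate_treatment_dose, evaluate_plan,
                                 map_to_discrete, sample_treatment)
from bhrobust.metrics import dvh_metrics
from bhrobust.planning import RobustPlanner
from bhrobust.scenarios import (UncertaintyModel, ci90_radius,
                                evaluation_shift_grid, setup_shift_samples,
                                spr_scenarios)

ZERO3 = (0.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def photon_plan(phantom5, deformer5, engine):
    planner = RobustPlanner(phantom5, "photon3D-PS", engine=engine,
                            deformer=deformer5, seed=0)
    return planner.normalize(planner.optimize(maxiter=40))


class TestSampling:
    def test_empirical_sds_match_model_within_three_standard_errors(self):
        model = UncertaintyModel()
        rng = np.random.default_rng(123)
        n = 10000
        sys_bh = np.array([sample_treatment(model, "A", 2, rng).systematic_bh
                           for _ in range(n)])
        for axis in range(3):
            sd = model.Sigma_BH_A[axis]
            se = sd / np.sqrt(2 * n)
            assert abs(sys_bh[:, axis].std(ddof=1) - sd) < 3 * se

    def test_set_b_produces_larger_cc_spread(self):
        model = UncertaintyModel()
        rng_a, rng_b = np.random.default_rng(1), np.random.default_rng(1)
        n = 4000
        cc = {s: np.array([sample_treatment(model, s, 1, r).fractions[0].bh_shifts[0, 2]
                           for _ in range(n)])
              for s, r in (("A", rng_a), ("B", rng_b))}
        assert cc["B"].std() > cc["A"].std()

    def test_all_sds_zero_gives_nominal_scenario(self):
        model = UncertaintyModel(Sigma_PS=ZERO3, sigma_PS=ZERO3,
                                 Sigma_BH_A=ZERO3, sigma_BH_A=ZERO3, Sigma_SPR=0.0)
        s = sample_treatment(model, "A", 3, np.random.default_rng(0),
                             modality="proton")
        assert s.spr_delta == 0.0
        assert not s.systematic_patient.any() and not s.systematic_bh.any()
        for f in s.fractions:
            assert not f.patient_shift.any() and not f.bh_shifts.any()

    def test_photon_treatments_have_no_spr_perturbation(self):
        model = UncertaintyModel()
        rng = np.random.default_rng(5)
        deltas = {sample_treatment(model, "A", 2, rng, modality="photon").spr_delta
                  for _ in range(50)}
        assert deltas == {0.0}

    def test_proton_delta_distribution_weighted_by_gaussian_density(self):
        model = UncertaintyModel()
        rng = np.random.default_rng(7)
        n = 8000
        deltas = np.array([sample_treatment(model, "A", 1, rng,
                                            modality="proton").spr_delta
                           for _ in range(n)])
        w = np.exp(-0.5 * (np.array([-4.7, 0.0, 4.7]) / model.Sigma_SPR) ** 2)
        p = w / w.sum()
        frac0 = (deltas == 0.0).mean()
        assert frac0 == pytest.approx(p[1], abs=4 * np.sqrt(p[1] * (1 - p[1]) / n))


@pytest.fixture(scope="module")
def grid_a():
    m = UncertaintyModel()
    return m, evaluation_shift_grid(m.Sigma_BH_A, m.sigma_BH_A, label="evalA_105")


class TestDiscreteMapping:

    def test_zero_draw_maps_to_nominal(self, grid_a):
        m, g = grid_a
        assert map_to_discrete(np.zeros(3), np.zeros(3), g,
                               m.Sigma_BH_A, m.sigma_BH_A) == 0

    def test_grid_points_map_to_themselves(self, grid_a):
        m, g = grid_a
        for i in (0, 3, 17, 52, 104):
            s = g.samples[i]
            assert map_to_discrete(np.array(s.systematic_shift),
                                   np.array(s.per_bh_shift), g,
                                   m.Sigma_BH_A, m.sigma_BH_A) == i

    @staticmethod
    def _orbit_labels(sys_pts, bh_pts):
        """Symmetry-orbit label per grid cell: the +-axis pairs and the eight
        vertices have identical true probabilities, so ranks within an orbit
        are meaningless; frequencies are compared orbit-aggregated."""
        def kind(points):
            out = []
            for p in points:
                nz = np.nonzero(np.abs(p) > 1e-9)[0]
                out.append(0 if len(nz) == 0 else (4 if len(nz) == 3 else 1 + nz[0]))
            return np.array(out)
        return (kind(sys_pts)[:, None] * 10 + kind(bh_pts)[None, :]).ravel()

    def test_assignment_frequencies_track_cell_probabilities(self, grid_a):
        m, g = grid_a
        rng = np.random.default_rng(11)
        n = 10000
        sys = rng.normal(0.0, m.Sigma_BH_A, size=(n, 3))
        bh = rng.normal(0.0, m.sigma_BH_A, size=(n, 3))
        assigned = np.array([map_to_discrete(s, b, g, m.Sigma_BH_A, m.sigma_BH_A)
                             for s, b in zip(sys, bh)])
        freq = np.bincount(assigned, minlength=105) / n

        # independent Monte-Carlo oracle for the Voronoi cell probabilities:
        # brute-force nearest neighbor (cdist) on a separate large sample
        n2 = 200000
        rng2 = np.random.default_rng(99)
        sys2 = rng2.normal(0.0, m.Sigma_BH_A, size=(n2, 3))
        bh2 = rng2.normal(0.0, m.sigma_BH_A, size=(n2, 3))
        sys_pts = np.array([g.samples[i * 7].systematic_shift for i in range(15)])
        bh_pts = np.array([g.samples[i].per_bh_shift for i in range(7)])
        si = np.argmin(cdist(sys2 / m.Sigma_BH_A, sys_pts / m.Sigma_BH_A), axis=1)
        bi = np.argmin(cdist(bh2 / m.sigma_BH_A, bh_pts / m.sigma_BH_A), axis=1)
        prob = np.bincount(si * 7 + bi, minlength=105) / n2

        orbit = self._orbit_labels(sys_pts, bh_pts)
        labels = np.unique(orbit)
        agg = lambda v: np.array([v[orbit == l].sum() for l in labels])
        rho, _ = spearmanr(agg(freq), agg(prob))
        assert rho > 0.9
        # and the raw per-cell frequencies are proportional to the
        # probabilities (linear correlation is tie-insensitive)
        assert np.corrcoef(freq, prob)[0, 1] > 0.99


class TestAccumulation:
    def test_nominal_sample_reproduces_plan_dose(self, photon_plan, phantom5,
                                                 deformer5, engine):
        model = UncertaintyModel(Sigma_PS=ZERO3, sigma_PS=ZERO3,
                                 Sigma_BH_A=ZERO3, sigma_BH_A=ZERO3, Sigma_SPR=0.0)
        grid = evaluation_shift_grid(*model.bh("A"), label="evalA_105")
        provider = EvaluationImageProvider(deformer5, grid, "evalA0")
        setup = setup_shift_samples(ci90_radius(0.0, 0.0))
        cache = ScenarioDoseCache(photon_plan, engine, provider, setup,
                                  spr_scenarios("photon"))
        s = sample_treatment(model, "A", len(photon_plan.units),
                             np.random.default_rng(0), modality="photon")
        dose = accumulate_treatment_dose(s, cache, photon_plan, model, "A")
        nominal = engine.plan_dose(photon_plan, phantom5, "nominal")
        assert np.allclose(dose, nominal, atol=1e-5)

    def test_three_identical_fractions_sum_to_three_times_one(self, photon_plan,
                                                              phantom5, deformer5,
                                                              engine):
        model = UncertaintyModel()
        grid = evaluation_shift_grid(*model.bh("A"), label="evalA_105")
        provider = EvaluationImageProvider(deformer5, grid, "evalA1")
        setup = setup_shift_samples(ci90_radius(max(model.Sigma_PS),
                                                max(model.sigma_PS)))
        cache = ScenarioDoseCache(photon_plan, engine, provider, setup,
                                  spr_scenarios("photon"))
        s = sample_treatment(model, "A", len(photon_plan.units),
                             np.random.default_rng(3), modality="photon")
        # force the three fractions to be identical
        s.fractions = [s.fractions[0]] * 3
        total = accumulate_treatment_dose(s, cache, photon_plan, model, "A")
        one = accumulate_treatment_dose(
            type(s)(s.spr_delta, s.systematic_patient, s.systematic_bh,
                    [s.fractions[0]]), cache, photon_plan, model, "A")
        assert np.allclose(total, one, atol=1e-6)  # per-fraction share normalized

    def test_cache_combination_counts(self, photon_plan, deformer5, engine):
        model = UncertaintyModel()
        grid = evaluation_shift_grid(*model.bh("A"), label="evalA_105")
        provider = EvaluationImageProvider(deformer5, grid, "evalA2")
        setup = setup_shift_samples(5.7)
        photon_cache = ScenarioDoseCache(photon_plan, engine, provider, setup,
                                         spr_scenarios("photon"))
        assert photon_cache.n_scenario_combinations == 105 * 15 * 1
        proton_cache = ScenarioDoseCache(photon_plan, engine, provider, setup,
                                         spr_scenarios("proton"))
        assert proton_cache.n_scenario_combinations == 105 * 15 * 3
        with pytest.raises(KeyError):
            photon_cache.spr_index(4.7)


class TestEvaluatePlan:
    def test_zero_error_evaluation_collapses_to_nominal(self, photon_plan,
                                                        phantom5, deformer5, engine):
        model = UncertaintyModel(Sigma_PS=ZERO3, sigma_PS=ZERO3,
                                 Sigma_BH_A=ZERO3, sigma_BH_A=ZERO3, Sigma_SPR=0.0)
        res = evaluate_plan(photon_plan, phantom5, deformer5, engine, model, "A",
                            n_samples=3, seed=1)
        nominal = dvh_metrics(engine.plan_dose(photon_plan, phantom5, "nominal"),
                              phantom5.structures,
                              voxel_volume_mm3=phantom5.grid.voxel_volume_mm3)
        for name, val in nominal.items():
            # cached doses are float32; agreement to single precision
            assert res.summary.loc[name, "Avg"] == pytest.approx(val, rel=1e-5,
                                                                 abs=1e-4)
            assert res.summary.loc[name, "SD"] == pytest.approx(0.0, abs=1e-4)

    def test_deterministic_given_seed(self, photon_plan, phantom5, deformer5, engine):
        model = UncertaintyModel()
        a = evaluate_plan(photon_plan, phantom5, deformer5, engine, model, "A",
                          n_samples=8, seed=42)
        b = evaluate_plan(photon_plan, phantom5, deformer5, engine, model, "A",
                          n_samples=8, seed=42)
        assert a.samples.equals(b.samples)
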