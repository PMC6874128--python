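"""Phantom generator: AIF, forward Tofts model, rendering, cohort simulator."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from hnqi.param_maps import compute_adc
from hnqi.phantom import (
    AIFParams,
    CohortSpec,
    PhantomSpec,
    forward_tofts,
    generate_covariates,
    render_phantom,
    simulate_aif,
    simulate_cohort,
)
from hnqi.survival import CoxSpec, build_itffr, fit_cox, logrank_groups

from conftest import make_tumor


class TestAIF:
    def test_zero_before_bolus_arrival(self):
        times = np.linspace(0, 9, 10)  # all before the 10 s arrival
        assert np.all(simulate_aif(AIFParams(), times) == 0)

    def test_amplitude_linearity(self, dce_times):
        p = AIFParams()
        doubled = replace(p, amp1_mM=2 * p.amp1_mM, amp2_mM=2 * p.amp2_mM)
        np.testing.assert_allclose(
            simulate_aif(doubled, dce_times), 2 * simulate_aif(p, dce_times)
        )

    def test_closed_form_value_at_60s(self, dce_times):
        # by hand: s = 60 - 10 - 8 = 42 s after the peak,
        # Cp = 4 exp(-0.01*42) + 1 exp(-2e-4*42)
        expected = 4 * np.exp(-0.01 * 42) + np.exp(-2e-4 * 42)
        curve = simulate_aif(AIFParams(), dce_times)
        assert curve[10] == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_everywhere(self, dce_times):
        assert np.all(simulate_aif(AIFParams(), dce_times) >= 0)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate_aif(AIFParams(), np.array([0.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match="nonempty"):
            simulate_aif(AIFParams(), np.array([]))


class TestForwardTofts:
    def test_vascular_only_limit(self, aif_curve, dce_times):
        ct = forward_tofts(0.0, 0.5, 0.1, aif_curve, dce_times)
        np.testing.assert_allclose(ct, 0.1 * aif_curve)

    def test_zero_parameters_give_zero_curve(self, aif_curve, dce_times):
        assert np.all(forward_tofts(0.0, 0.5, 0.0, aif_curve, dce_times) == 0)

    def test_matches_bruteforce_quadrature_on_boxcar(self, dce_times):
        # independent oracle: direct trapezoidal quadrature of the written-out
        # convolution integral at every frame
        cp = np.where((dce_times >= 30) & (dce_times <= 120), 2.0, 0.0)
        kt, ke, vp = 0.2, 0.5, 0.05
        expected = []
        for i, t in enumerate(dce_times):
            tau = dce_times[: i + 1]
            integ = np.trapezoid(cp[: i + 1] * np.exp(-(ke / 60) * (t - tau)), tau)
            expected.append(vp * cp[i] + (kt / 60) * integ)
        ct = forward_tofts(kt, ke, vp, cp, dce_times)
        np.testing.assert_allclose(ct, expected, atol=1e-8)

    def test_negative_parameters_rejected(self, aif_curve, dce_times):
        with pytest.raises(ValueError):
            forward_tofts(-0.1, 0.5, 0.05, aif_curve, dce_times)
        with pytest.raises(ValueError):
            forward_tofts(0.1, -0.5, 0.05, aif_curve, dce_times)
        with pytest.raises(ValueError):
            forward_tofts(0.1, 0.5, 1.0, aif_curve, dce_times)


class TestRenderPhantom:
    def test_noiseless_adc_round_trip(self, noiseless_case, noiseless_spec):
        b1, b2 = noiseless_spec.b_values
        for tp in ("pre", "mid"):
            data = noiseless_case.timepoint(tp)
            res = compute_adc(data.dwi[b1], data.dwi[b2], b1, b2)
            rel = np.abs(res.adc.data - data.truth.adc.data) / data.truth.adc.data
            assert np.nanmax(rel) < 1e-12
            assert res.n_invalid == 0

    def test_gtv_voxelization_matches_sphere_volume(self):
        # 10 mm sphere on 1 mm isotropic voxels: count within a one-voxel
        # surface shell of (4/3) pi 10^3
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            voxel_size=(1.0, 1.0, 1.0),
            tumors=[make_tumor(center=(16.0, 16.0, 16.0), radius_pre=10.0,
                               radius_mid=9.0, necrotic_core_radius=0.0,
                               lowbv_blob=None, lowadc_blob=None)],
            noise_sd_dwi=0.0, noise_sd_dce=0.0, noise_sd_suv=0.0,
        )
        case = render_phantom(spec)
        count = int(case.pre.gtv_masks[0].data.sum())
        analytic = 4 / 3 * np.pi * 10**3
        shell = 4 * np.pi * 10**2 * 1.0  # surface area x one voxel
        assert abs(count - analytic) < shell

    def test_same_seed_bit_identical(self, noiseless_spec):
        spec = replace(noiseless_spec, noise_sd_dwi=3.0, noise_sd_dce=0.02)
        a, b = render_phantom(spec), render_phantom(spec)
        assert np.array_equal(a.pre.dce, b.pre.dce)
        for bv in spec.b_values:
            assert np.array_equal(a.pre.dwi[bv].data, b.pre.dwi[bv].data)
        assert np.array_equal(a.mid.suv.data, b.mid.suv.data)

    def test_tumor_outside_grid_rejected(self):
        spec = PhantomSpec(tumors=[make_tumor(center=(2.0, 36.0, 48.0),
                                              necrotic_core_radius=0.0,
                                              lowbv_blob=None, lowadc_blob=None)])
        with pytest.raises(ValueError, match="outside"):
            render_phantom(spec)

    def test_adc_recovery_rmse_monotone_in_noise(self, noiseless_spec):
        # same seed -> same unit noise field scaled by the SD, so the
        # map-recovery RMSE is non-decreasing across noise levels
        rmses = []
        for sd in (0.0, 2.0, 8.0):
            spec = replace(noiseless_spec, noise_sd_dwi=sd)
            case = render_phantom(spec)
            b1, b2 = spec.b_values
            res = compute_adc(case.pre.dwi[b1], case.pre.dwi[b2], b1, b2)
            err = res.adc.data - case.pre.truth.adc.data
            rmses.append(float(np.sqrt(np.nanmean(err**2))))
        assert rmses[0] <= rmses[1] <= rmses[2]


class TestSimulateCohort:
    def test_unknown_covariate_rejected(self):
        spec = CohortSpec(n_patients=10, betas={"nope": 1.0}, seed=0)
        with pytest.raises(ValueError, match="nope"):
            simulate_cohort(spec, generate_covariates(CohortSpec(n_patients=10, seed=0)))

    def test_null_model_groups_equivalent(self):
        # all betas zero: p16+ and p16- survival differ only by sampling
        # noise, so logrank p-values over replicates are not concentrated low
        pvals = []
        for rep in range(30):
            spec = CohortSpec(n_patients=80, betas={"p16": 0.0}, seed=900 + rep)
            sim = simulate_cohort(spec)
            tab = build_itffr(sim).merge(
                sim[["tumor_id", "p16"]], left_on="unit_id", right_on="tumor_id"
            )
            _, p = logrank_groups(tab["time"], tab["event"], tab["p16"])
            pvals.append(p)
        assert np.mean(np.array(pvals) < 0.05) < 0.25
        assert np.mean(pvals) > 0.3  # roughly uniform, mean ~0.5

    def test_degenerate_censoring_not_identifiable(self):
        spec = CohortSpec(n_patients=20, betas={"p16": 0.0},
                          censor_time_range=(0.0, 1e-9), seed=1)
        sim = simulate_cohort(spec)
        tab = build_itffr(sim).merge(
            sim[["tumor_id", "p16"]], left_on="unit_id", right_on="tumor_id"
        )
        assert tab["event"].sum() == 0
        with pytest.raises(ValueError, match="at least 2 events"):
            fit_cox(tab, CoxSpec(covariates=["p16"]))

    def test_tumors_cluster_within_patients(self):
        spec = CohortSpec(n_patients=25, betas={}, seed=3)
        sim = simulate_cohort(spec)
        assert sim["patient_id"].nunique() == 25
        # patient-level quantities are constant within a patient
        for col in ("p16", "last_followup"):
            assert (sim.groupby("patient_id")[col].nunique() == 1).all()
        # every patient has exactly one primary tumor
        assert (sim[sim["kind"] == "primary"].groupby("patient_id").size() == 1).all()

    def test_event_times_exponential_scale(self):
        # with a constant hazard h0 and no covariates, observed event times
        # stay consistent with the generating exponential rate
        spec = CohortSpec(n_patients=400, betas={}, baseline_hazard=0.05,
                          df_hazard=1e-9, death_hazard=1e-9,
                          censor_time_range=(1000.0, 1001.0), seed=11)
        sim = simulate_cohort(spec)
        assert sim["event"].mean() > 0.99  # essentially no censoring
        assert sim["time"].mean() == pytest.approx(1 / 0.05, rel=0.1)
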