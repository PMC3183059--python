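"""Generator correctness: physics against an independent ODE oracle,
determinism, conservation identities, and the auxiliary simulators."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fluxdeconv import (
    ChamberPhysics,
    buffer_capacity,
    clark_ocr,
    default_stage_table,
    estimate_ocr,
    linearity_r2,
    simulate_buffer_titration,
    simulate_clark_run,
    simulate_plate,
    simulate_titration,
)
from fluxdeconv.assay_model import ASSAYED_STAGES, ConfigError, ScheduleError, InjectionPort, InjectionSchedule
from fluxdeconv.synthetic_assay import MEASURE_OFFSETS
from fluxdeconv._chamber import chamber_o2


class TestStageTable:
    def test_printed_leak_fractions(self):
        table = default_stage_table()
        assert table[12].f_leak == 0.27
        assert table[24].f_leak == 0.27
        assert table[30].f_leak == 0.18
        assert table[48].f_leak == 0.094
        assert table[3].f_leak == 0.0 and table[7].f_leak == 0.0

    def test_basal_ramp_anchored_at_30_hpf(self):
        table = default_stage_table()
        assert table[30].basal_ocr_pmol_min == pytest.approx(91.0)
        # linear in hpf
        hpf = np.array(ASSAYED_STAGES, float)
        ocr = np.array([table[h].basal_ocr_pmol_min for h in ASSAYED_STAGES])
        resid = np.polyval(np.polyfit(hpf, ocr, 1), hpf) - ocr
        assert np.abs(resid).max() < 1e-9

    def test_fractions_sum_to_one_every_stage(self):
        for p in default_stage_table().values():
            assert p.f_nonmito + p.f_leak + p.f_atp == pytest.approx(1.0, abs=1e-12)
            # conservation of the generator's phase rates
            total = p.phase_ocr("basal")
            assert p.phase_ocr("sodium_azide") / total == pytest.approx(p.f_nonmito)
            assert p.phase_ocr("oligomycin") / total == pytest.approx(p.f_nonmito + p.f_leak)

    def test_overrides_apply(self):
        table = default_stage_table(well_cv=0.0, clutch_cv=0.0)
        assert all(p.well_cv == 0 and p.clutch_cv == 0 for p in table.values())


class TestChamberPhysicsModel:
    def test_measure_phase_matches_independent_ode_integration(self):
        """Exact propagator solution vs brute-force fine-step integration."""
        phys = ChamberPhysics().noiseless()
        ocr, o0 = 148.0, 152.0
        inv_vk = 1.0 / (phys.v_ch_uL * phys.k_o2)

        def rhs(t, x):
            o_ch, o_w = x
            return [
                -ocr * inv_vk + phys.k_w * (o_w - o_ch) + phys.k_a * (phys.o_atm_mmHg - o_ch),
                phys.k_w_wall * (o_ch - o_w),
            ]

        offsets = tuple(round(o - 3.0, 6) for o in MEASURE_OFFSETS)
        sol = solve_ivp(rhs, (0, offsets[-1]), [o0, o0], t_eval=offsets, rtol=1e-11, atol=1e-11)
        ours = chamber_o2(phys, offsets, ocr, o0)
        np.testing.assert_allclose(ours, sol.y[0], rtol=1e-8)

    def test_zero_leak_constants_give_exact_line(self, simulate_noiseless):
        phys = ChamberPhysics(k_w=0.0, k_w_wall=0.0, k_a=0.0).noiseless()
        params = default_stage_table()[24].noiseless()
        run, _ = simulate_plate(24, physics=phys, seed=0, stage_params=params)
        trace = run.traces["A2"]
        for cyc in (1, 6, 10, 20):
            assert linearity_r2(trace, cyc) == pytest.approx(1.0, abs=1e-12)

    def test_non_positive_physics_constant_rejected(self):
        with pytest.raises(ConfigError):
            ChamberPhysics(v_ch_uL=0.0)
        with pytest.raises(ConfigError):
            ChamberPhysics(k_o2=-1.0)


class TestSimulatePlate:
    def test_same_seed_is_bit_identical(self):
        r1, t1 = simulate_plate(24, seed=11)
        r2, t2 = simulate_plate(24, seed=11)
        for w in r1.traces:
            np.testing.assert_array_equal(r1.traces[w].o2_mmHg, r2.traces[w].o2_mmHg)
            np.testing.assert_array_equal(r1.traces[w].ph, r2.traces[w].ph)
        assert t1.equals(t2)

    def test_azide_over_basal_truth_is_nonmito_fraction(self):
        _, truth = simulate_plate(30, seed=4)
        sample = truth[truth.role == "sample"]
        piv = sample.pivot(index="well", columns="window", values="true_ocr_pmol_min")
        np.testing.assert_allclose(
            piv["sodium_azide"] / piv["basal"], default_stage_table()[30].f_nonmito
        )

    def test_truth_conserves_components(self):
        _, truth = simulate_plate(24, seed=2)
        p = default_stage_table()[24]
        sample = truth[(truth.role == "sample") & (truth.window == "basal")]
        # nonmito + leak + ATP shares reconstruct the basal rate identically
        recon = sample.true_ocr_pmol_min * (p.f_nonmito + p.f_leak + p.f_atp)
        np.testing.assert_allclose(recon, sample.true_ocr_pmol_min)

    def test_noiseless_measure_slope_matches_truth_with_leak_correction(
        self, simulate_noiseless, noiseless_physics
    ):
        """Compartment-corrected estimate hits generator truth; bare slope is low."""
        run, truth = simulate_noiseless(30)
        t = truth[truth.well == "B2"].set_index("window")["true_ocr_pmol_min"]
        est = estimate_ocr(run.traces["B2"], noiseless_physics, method="compartment")
        assert est.ocr_pmol_min[4] == pytest.approx(t["basal"], rel=1e-9)
        slope_est = estimate_ocr(run.traces["B2"], noiseless_physics, method="slope")
        assert slope_est.ocr_pmol_min[4] < t["basal"]  # diffusion/leak refill bias

    def test_o2_stays_above_hypoxia_floor_at_default_conditions(self):
        for hpf in ASSAYED_STAGES:
            run, _ = simulate_plate(hpf, seed=20 + hpf)
            for w in run.layout.sample_wells:
                t = run.traces[w]
                o2 = t.o2_mmHg[t.phase == "measure"]
                assert o2.min() > 100.0, f"{hpf} hpf well {w} went hypoxic"

    def test_injection_before_cycle_seven_rejected(self):
        with pytest.raises(ScheduleError):
            simulate_plate(
                24,
                schedule=InjectionSchedule(ports=(InjectionPort("oligomycin", 9.4, "uM", 5),)),
                seed=0,
            )

    def test_temperature_control_wells_carry_no_respiration(self):
        _, truth = simulate_plate(24, seed=1)
        ctrl = truth[truth.role == "temperature_control"]
        assert (ctrl.true_ocr_pmol_min == 0).all()


class TestClarkSimulator:
    def test_noiseless_slope_is_ocr_over_volume(self):
        tr = simulate_clark_run(91.0, 1, 1.5, seed=0, noise_sd_nmol_mL=0.0)
        slope = np.polyfit(tr.time_min, tr.o2_nmol_per_mL, 1)[0]
        assert slope == pytest.approx(-0.0607, abs=1e-4)  # 91 pmol/min / 1.5 mL

    def test_doubling_embryos_doubles_slope(self):
        t1 = simulate_clark_run(91.0, 1, 1.5, seed=0, noise_sd_nmol_mL=0.0)
        t2 = simulate_clark_run(91.0, 2, 1.5, seed=0, noise_sd_nmol_mL=0.0)
        s1 = np.polyfit(t1.time_min, t1.o2_nmol_per_mL, 1)[0]
        s2 = np.polyfit(t2.time_min, t2.o2_nmol_per_mL, 1)[0]
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_noisy_recovery_within_three_se(self):
        noise = 0.05
        tr = simulate_clark_run(91.0, 1, 1.5, seed=8, noise_sd_nmol_mL=noise)
        t = tr.time_min
        se_slope = noise / np.sqrt(((t - t.mean()) ** 2).sum())
        se_ocr = se_slope * tr.volume_mL  # nmol/min
        assert clark_ocr(tr) == pytest.approx(0.091, abs=3 * se_ocr)

    def test_bad_volume_rejected(self):
        with pytest.raises(ConfigError):
            simulate_clark_run(91.0, 1, 0.0, seed=0)


class TestTitrationSimulator:
    def test_response_is_monotone_below_saturation(self):
        curve = simulate_titration("fccp", 7, [0.1, 0.2, 0.3, 0.4, 0.5], seed=0, noise_cv=0.0)
        assert np.all(np.diff(curve.responses) > 0)

    def test_zero_dose_gives_zero_response(self):
        curve = simulate_titration("oligomycin", 24, [1e-12, 1.0], seed=0, noise_cv=0.0)
        assert curve.responses[0] == pytest.approx(0.0, abs=1e-6)

    def test_empty_dose_list_rejected(self):
        with pytest.raises(ConfigError):
            simulate_titration("fccp", 7, [], seed=0)

    def test_death_flag_above_threshold(self):
        curve = simulate_titration("fccp", 7, [1.0, 1.875, 2.5], seed=0)
        assert list(curve.dead) == [False, False, True]
        late = simulate_titration("fccp", 24, [1.875, 2.5, 5.0], seed=0)
        assert list(late.dead) == [False, False, True]


class TestBufferTitrationSimulator:
    def test_noiseless_delta_ph_per_addition(self):
        table = simulate_buffer_titration(1.0, 700.0, 5, 10.0, seed=0, noise_sd_pH=0.0)
        dph = np.diff(table["pH"].to_numpy())
        np.testing.assert_allclose(dph, -0.01, atol=1e-12)

    def test_default_table_has_baseline_plus_five_rows(self):
        table = simulate_buffer_titration(0.1, seed=0)
        assert table.shape[0] == 6

    def test_recovery_within_two_percent_at_default_noise(self):
        bc_true = 0.1  # mpH/nmol in the 700 uL well
        errs = []
        for seed in range(200):
            table = simulate_buffer_titration(bc_true, 700.0, seed=seed)
            bc = buffer_capacity(table, 700.0, 7.0)
            errs.append(abs(bc.raw_slope / bc_true - 1.0))
        assert max(errs) < 0.02

    def test_fewer_than_two_additions_rejected(self):
        with pytest.raises(ConfigError):
            simulate_buffer_titration(0.1, n_additions=1, seed=0)
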