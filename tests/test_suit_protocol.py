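"""SUIT interpretation: window assignment, corrections, blank fit, cytc QC."""

from __future__ import annotations

import numpy as np
import pytest

from suitflux.flux_engine import FluxSeries, PlateauEstimate, PlateauParams
from suitflux.suit_protocol import (
    ProtocolError,
    RespState,
    StateFluxes,
    apply_corrections,
    assign_states,
    cytc_quality_check,
    extract_from_trace,
    extract_state_fluxes,
    fit_autoxidation,
)
from suitflux.synthetic_cohort import SimConfig, simulate_blank
from suitflux.trace_model import ChamberTrace, TitrationEvent


def _pe(mean: float, stable: bool = True) -> PlateauEstimate:
    return PlateauEstimate(0.0, 60.0, mean, 0.0, 0.0, stable, 31)


def _state_fluxes(raw_means: dict[RespState, float], **kw) -> StateFluxes:
    return StateFluxes(
        sample_id="s",
        replicate=1,
        raw={s: _pe(v) for s, v in raw_means.items()},
        **kw,
    )


RAW_EXAMPLE = {
    RespState.LEAK: 10.0,
    RespState.CI_OXPHOS: 48.0,
    RespState.CI_OXPHOS_CYTC: 48.2,
    RespState.CI_CII_OXPHOS: 58.0,
    RespState.CI_CII_ETS: 84.0,
    RespState.CII_ETS: 32.0,
    RespState.ROX: 4.0,
    RespState.CIV_MAX: 160.0,
}


class TestAssignStates:
    def test_canonical_events_give_eight_ordered_disjoint_windows(
        self, default_sample
    ):
        trace = default_sample.traces[0]
        windows = assign_states(trace.events, float(trace.time_s[-1]))
        assert set(windows) == set(RespState)
        flat = sorted(
            (w for ws in windows.values() for w in ws), key=lambda w: w[0]
        )
        for (s0, e0), (s1, e1) in zip(flat, flat[1:]):
            assert e0 <= s1  # pairwise disjoint, temporal order
        assert len(windows[RespState.CI_CII_ETS]) == 3

    def test_missing_adp_names_the_violation(self, default_sample):
        events = [
            e for e in default_sample.traces[0].events if e.agent != "adp"
        ]
        with pytest.raises(ProtocolError, match="adp expected after CI substrates"):
            assign_states(events, 6200.0)

    def test_out_of_order_uncoupler_rejected(self):
        events = [
            TitrationEvent(10, "malate"),
            TitrationEvent(20, "pyruvate"),
            TitrationEvent(30, "glutamate"),
            TitrationEvent(40, "adp"),
            TitrationEvent(50, "fccp"),
        ]
        with pytest.raises(ProtocolError, match="cytochrome_c expected"):
            assign_states(events, 100.0)

    def test_fccp_steps_map_to_subwindows(self):
        events = (
            [TitrationEvent(10, "malate"), TitrationEvent(20, "pyruvate"),
             TitrationEvent(30, "glutamate"), TitrationEvent(240, "adp"),
             TitrationEvent(480, "cytochrome_c"), TitrationEvent(720, "succinate")]
            + [TitrationEvent(960 + 240 * k, "fccp", step_index=k + 1)
               for k in range(3)]
            + [TitrationEvent(1680, "rotenone"), TitrationEvent(1920, "antimycin_a"),
               TitrationEvent(2160, "tmpd"), TitrationEvent(2180, "ascorbate")]
        )
        windows = assign_states(events, 2600.0)
        assert windows[RespState.CI_CII_ETS] == [
            (960.0, 1200.0), (1200.0, 1440.0), (1440.0, 1680.0)
        ]
        assert windows[RespState.CIV_MAX] == [(2180.0, 2600.0)]

    def test_windows_depend_only_on_events_not_samples(self, default_sample):
        trace = default_sample.traces[0]
        end = float(trace.time_s[-1])
        assert assign_states(trace.events, end) == assign_states(
            list(trace.events), end
        )

    def test_reoxygenation_truncates_the_containing_window(self):
        events = [
            TitrationEvent(10, "malate"), TitrationEvent(20, "pyruvate"),
            TitrationEvent(30, "glutamate"), TitrationEvent(240, "adp"),
            TitrationEvent(480, "cytochrome_c"), TitrationEvent(720, "succinate"),
            TitrationEvent(960, "fccp"),
            TitrationEvent(1200, "rotenone"),
            TitrationEvent(1300, "reoxygenation"),
            TitrationEvent(1680, "antimycin_a"),
            TitrationEvent(1920, "tmpd"), TitrationEvent(1940, "ascorbate"),
        ]
        windows = assign_states(events, 2400.0)
        # reox at 1300 splits CII_ETS (1200-1680); the longer part survives
        assert windows[RespState.CII_ETS] == [(1300.0, 1680.0)]


class TestExtraction:
    def _flux(self, jv, dt=2.0, halfwidth=10.0):
        return FluxSeries(np.arange(len(jv)) * dt, np.asarray(jv, float), halfwidth)

    def test_ets_flux_is_max_over_fccp_steps(self):
        jv = np.concatenate(
            [np.full(150, 90.0), np.full(150, 100.0), np.full(150, 97.0)]
        )
        windows = {
            RespState.CI_CII_ETS: [(0.0, 300.0), (300.0, 600.0), (600.0, 898.0)]
        }
        sf = extract_state_fluxes(
            self._flux(jv), windows, PlateauParams(settle_s=40, lag_s=2)
        )
        assert sf.raw_flux(RespState.CI_CII_ETS) == pytest.approx(100.0)
        assert len(sf.ets_step_estimates) == 3
        means = [e.mean_flux for e in sf.ets_step_estimates]
        assert means == pytest.approx([90.0, 100.0, 97.0])

    def test_all_zero_flux_gives_zero_states(self):
        jv = np.zeros(1000)
        windows = {
            s: [(200.0 * i, 200.0 * (i + 1))] for i, s in enumerate(RespState)
        }
        windows[RespState.CI_CII_ETS] = [windows[RespState.CI_CII_ETS][0]]
        sf = extract_state_fluxes(
            self._flux(jv), windows, PlateauParams(settle_s=40, lag_s=2)
        )
        sf = apply_corrections(sf)
        assert sf.rox_flux == 0.0
        for s in RespState:
            assert sf.corrected[s] == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_extraction_matches_ground_truth(self, noise_free_sample):
        """End-to-end state fluxes within 0.1% of the generator's values."""
        cfg = SimConfig()
        truth = noise_free_sample.truth
        for replicate, trace in zip((1, 2), noise_free_sample.traces):
            sf = extract_from_trace(trace)
            for state in RespState:
                if state is RespState.CIV_MAX:
                    continue  # raw CIV carries the autoxidation background
                expected = truth.true_raw_flux[replicate][state]
                got = sf.raw_flux(state)
                assert got == pytest.approx(expected, rel=1e-3, abs=0.02), state
            assert sf.all_stable()
            # after both corrections the mitochondrial CIV flux is recovered
            sf = apply_corrections(
                sf, autox_a0=cfg.autox_a0, autox_a1=cfg.autox_a1
            )
            assert sf.corrected[RespState.CIV_MAX] == pytest.approx(
                truth.true_state_flux[replicate][RespState.CIV_MAX], rel=1e-3
            )


class TestCorrections:
    def test_rox_subtraction_arithmetic(self):
        sf = apply_corrections(_state_fluxes(RAW_EXAMPLE))
        assert sf.corrected[RespState.LEAK] == pytest.approx(6.0)
        assert sf.corrected[RespState.ROX] == 0.0
        assert sf.corrected[RespState.CI_CII_ETS] == pytest.approx(80.0)

    def test_civ_stacks_rox_and_autoxidation(self):
        sf = apply_corrections(
            _state_fluxes(RAW_EXAMPLE),
            autox_a0=10.0,
            autox_a1=0.05,
            mean_o2_civ_window=100.0,
        )
        # 160 - 4 - (10 + 0.05*100) = 141
        assert sf.corrected[RespState.CIV_MAX] == pytest.approx(141.0)
        assert sf.autox_params_used == (10.0, 0.05)

    def test_civ_rox_subtraction_can_be_switched_off(self):
        sf = apply_corrections(
            _state_fluxes(RAW_EXAMPLE),
            autox_a0=10.0,
            autox_a1=0.05,
            mean_o2_civ_window=100.0,
            civ_subtract_rox=False,
        )
        assert sf.corrected[RespState.CIV_MAX] == pytest.approx(145.0)

    def test_rox_subtraction_preserves_pairwise_differences(self):
        sf = apply_corrections(_state_fluxes(RAW_EXAMPLE))
        plain = [s for s in RespState if s not in (RespState.ROX, RespState.CIV_MAX)]
        for s1 in plain:
            for s2 in plain:
                assert sf.corrected[s1] - sf.corrected[s2] == pytest.approx(
                    RAW_EXAMPLE[s1] - RAW_EXAMPLE[s2]
                )

    def test_negative_corrected_flux_flags_qc(self):
        raw = dict(RAW_EXAMPLE)
        raw[RespState.LEAK] = 2.0   # below ROX -> negative after subtraction
        with pytest.warns(UserWarning, match="negative corrected flux"):
            sf = apply_corrections(_state_fluxes(raw))
        assert sf.qc_pass is False

    def test_unstable_plateau_fails_qc(self):
        sf = _state_fluxes(RAW_EXAMPLE)
        sf.raw[RespState.LEAK] = _pe(10.0, stable=False)
        sf = apply_corrections(sf)
        assert sf.qc_pass is False
        assert any("unstable" in n for n in sf.qc_notes)


class TestAutoxidationFit:
    def test_recovery_from_simulated_blank(self, default_blank):
        cfg = SimConfig()
        a0, a1 = fit_autoxidation(default_blank)
        assert a0 == pytest.approx(cfg.autox_a0, rel=0.05)
        assert a1 == pytest.approx(cfg.autox_a1, rel=0.05)

    def test_zero_flux_blank_gives_zero_parameters(self):
        blank = simulate_blank(
            SimConfig(autox_a0=0.0, autox_a1=0.0, sigma_o2_uM=0.0, seed=2)
        )
        a0, a1 = fit_autoxidation(blank)
        assert a0 == pytest.approx(0.0, abs=1e-9)
        assert a1 == 0.0

    def test_blank_without_tmpd_rejected(self):
        t = np.arange(0, 600, 2.0)
        blank = ChamberTrace(
            sample_id="blank", group="blank", replicate=1,
            time_s=t, o2_conc_uM=np.full(len(t), 180.0),
        )
        with pytest.raises(ProtocolError, match="no tmpd event"):
            fit_autoxidation(blank)

    def test_too_few_post_tmpd_samples_rejected(self):
        t = np.arange(0, 1000, 2.0)
        blank = ChamberTrace(
            sample_id="blank", group="blank", replicate=1,
            time_s=t, o2_conc_uM=np.full(len(t), 180.0),
            events=[TitrationEvent(940.0, "tmpd", 0.5, "mM")],
        )
        with pytest.raises(ValueError, match="after TMPD"):
            fit_autoxidation(blank)


class TestCytcCheck:
    def _with_corrected(self, j_ci: float, j_cytc: float) -> StateFluxes:
        raw = dict(RAW_EXAMPLE)
        raw[RespState.CI_OXPHOS] = j_ci + 4.0
        raw[RespState.CI_OXPHOS_CYTC] = j_cytc + 4.0
        return apply_corrections(_state_fluxes(raw))

    def test_small_increase_passes(self):
        increase, ok = cytc_quality_check(self._with_corrected(100.0, 100.56))
        assert increase == pytest.approx(0.56)
        assert ok

    def test_identical_fluxes_give_zero_increase(self):
        increase, ok = cytc_quality_check(self._with_corrected(100.0, 100.0))
        assert increase == 0.0
        assert ok

    def test_large_increase_fails_default_threshold(self):
        sf = self._with_corrected(100.0, 125.0)
        increase, ok = cytc_quality_check(sf)
        assert increase == pytest.approx(25.0)
        assert not ok
        assert sf.qc_pass is False

    def test_nonpositive_reference_flux_fails_with_reason(self):
        sf = self._with_corrected(0.0, 10.0)
        increase, ok = cytc_quality_check(sf)
        assert np.isnan(increase)
        assert not ok
        assert any("CI_OXPHOS flux <= 0" in n for n in sf.qc_notes)
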