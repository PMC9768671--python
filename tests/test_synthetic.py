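"""Synthetic cells, traces, datasets and toy trajectories."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from asicca.mdcontacts import contact_occupancy
from asicca.synthetic import (ConditionParams, ConstructSpec, construct_like,
                              gen_activation_dataset, gen_cell, gen_cells,
                              gen_trace, gen_trajectory, non_injected_cell,
                              wt_asic3)
from asicca.traces import ProtocolStep, extract_features


class TestGenCell:
    def test_zero_variance_gives_constant_ph50(self):
        spec = ConstructSpec("flat", {"80nM": ConditionParams(
            ca_free_m=80e-9, ph50_mean=7.48, ph50_sd=0.0, nh_sd=0.0,
            imax_sd_ua=0.0)})
        cells = gen_cells(spec, 20, seed=1)
        assert all(c.params["80nM"]["ph50"] == 7.48 for c in cells)

    def test_wt_sample_means_match_printed_group_means(self, wt_spec):
        cells = gen_cells(wt_spec, 1000, seed=2)
        p80 = np.array([c.params["80nM"]["ph50"] for c in cells])
        p2 = np.array([c.params["2mM"]["ph50"] for c in cells])
        assert abs(p80.mean() - 7.48) < 0.02
        assert abs(p2.mean() - 6.14) < 0.02
        assert p80.std(ddof=1) == pytest.approx(0.14, abs=0.02)

    def test_same_seed_is_deterministic(self, wt_spec):
        c1, c2 = gen_cell(wt_spec, 77), gen_cell(wt_spec, 77)
        assert dataclasses.asdict(c1) == dataclasses.asdict(c2)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            ConditionParams(ca_free_m=80e-9, ph50_mean=7.48, ph50_sd=-0.1)

    def test_ph50_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[3, 9\]"):
            ConditionParams(ca_free_m=80e-9, ph50_mean=10.5, ph50_sd=0.1)

    def test_sustained_fraction_bounds(self):
        with pytest.raises(ValueError, match="sustained"):
            construct_like("bad", 7.0, sustained_fraction=1.5)


class TestGenTrace:
    def test_peak_matches_analytic_form(self, wt_spec):
        # noise-free, no endogenous, no sustained component: the peak of
        # (1-exp(-t/ta))*exp(-t/td) is found independently by 1-D optimization
        cell = gen_cell(wt_spec, 5, noise_sd_na=0.0)
        cell.endo_amp_na = 0.0
        step = ProtocolStep(stimulation_ph=5.0, stimulation_ca_m=2e-3)
        tr = gen_trace(cell, step, sampling_s=0.002)
        feats = extract_features(tr)

        ta, td = cell.tau_act_s, cell.tau_des_s
        res = minimize_scalar(
            lambda t: -(1 - np.exp(-t / ta)) * np.exp(-t / td),
            bounds=(0, 5), method="bounded")
        kin_peak = -res.fun
        p = cell.for_ca(2e-3)
        from asicca.doseresponse import hill_activation
        drive = (hill_activation(5.0, p["ph50"], p["nh"])
                 - hill_activation(7.4, p["ph50"], p["nh"]))
        expected = -p["imax_ua"] * 1000 * drive * kin_peak
        assert feats.peak_na == pytest.approx(expected, rel=1e-4)
        assert feats.time_to_peak_s == pytest.approx(res.x, abs=0.005)
        assert feats.time_to_peak_s < 1.0   # peak within the first second

    def test_no_stimulus_change_gives_zero_current(self, wt_spec):
        cell = gen_cell(wt_spec, 5, noise_sd_na=0.0)
        cell.endo_amp_na = 0.0
        step = ProtocolStep(conditioning_ph=7.4, conditioning_ca_m=2e-3,
                            stimulation_ph=7.4, stimulation_ca_m=2e-3)
        tr = gen_trace(cell, step)
        assert np.allclose(tr.current_na, 0.0)

    def test_endogenous_only_trace_still_rises_at_10s(self):
        cell = non_injected_cell(3)
        step = ProtocolStep(stimulation_ph=7.4, stimulation_ca_m=100e-9,
                            duration_s=10.0)
        tr = gen_trace(cell, step)
        i = tr.current_na[tr.time_s >= 0]
        assert np.all(np.diff(i) <= 1e-9)          # inward magnitude grows
        f = extract_features(tr)
        assert abs(f.current_at_3p5s_na) < abs(i[-1])

    def test_endogenous_suppressed_at_high_ca(self):
        cell = non_injected_cell(3)
        low = gen_trace(cell, ProtocolStep(stimulation_ph=7.4,
                                           stimulation_ca_m=100e-9))
        high = gen_trace(cell, ProtocolStep(stimulation_ph=7.4,
                                            stimulation_ca_m=2e-3))
        assert abs(low.current_na.min()) > 10 * abs(high.current_na.min())

    def test_bad_sampling_interval(self, wt_spec):
        cell = gen_cell(wt_spec, 5)
        with pytest.raises(ValueError, match="sampling"):
            gen_trace(cell, ProtocolStep(), sampling_s=0.0)

    def test_determinism(self, wt_spec):
        cell = gen_cell(wt_spec, 5)
        t1 = gen_trace(cell, ProtocolStep(), seed=9)
        t2 = gen_trace(cell, ProtocolStep(), seed=9)
        assert np.array_equal(t1.current_na, t2.current_na)


class TestActivationDataset:
    def test_zero_noise_round_trip_recovers_generative_params(self, wt_spec,
                                                              ph_grid):
        from asicca.pipeline import fit_dataset

        df = gen_activation_dataset(wt_spec, "80nM", ph_grid, 5, seed=11,
                                    noise_sd=0.0)
        fits = fit_dataset(df).sort_values("cell_id")
        cells = gen_cells(wt_spec, 5, seed=11)
        gen_ph50 = np.array([c.params["80nM"]["ph50"] for c in cells])
        gen_nh = np.array([c.params["80nM"]["nh"] for c in cells])
        assert np.max(np.abs(fits["ph50"].to_numpy() - gen_ph50)) < 0.01
        assert np.max(np.abs(fits["nh"].to_numpy() - gen_nh)) < 0.01

    def test_group_mean_ph50_at_2mm(self, wt_spec, ph_grid):
        from asicca.pipeline import fit_dataset

        df = gen_activation_dataset(wt_spec, "2mM", ph_grid, 40, seed=21,
                                    noise_sd=0.02)
        fits = fit_dataset(df)
        assert fits["ph50"].mean() == pytest.approx(6.14, abs=0.06)

    def test_normalized_and_monotone_when_noise_free(self, wt_spec, ph_grid):
        df = gen_activation_dataset(wt_spec, "80nM", ph_grid, 3, seed=4,
                                    noise_sd=0.0)
        assert df["response"].between(0, 1).all()
        for _, g in df.groupby("cell_id"):
            resp = g.sort_values("ph", ascending=False)["response"].to_numpy()
            assert np.all(np.diff(resp) >= -1e-12)

    def test_empty_ph_list_raises(self, wt_spec):
        with pytest.raises(ValueError, match="empty"):
            gen_activation_dataset(wt_spec, "80nM", [], 3, seed=0)

    def test_zero_cells_raises(self, wt_spec, ph_grid):
        with pytest.raises(ValueError, match="n_cells"):
            gen_activation_dataset(wt_spec, "80nM", ph_grid, 0, seed=0)

    def test_seed_reproducibility(self, wt_spec, ph_grid):
        a = gen_activation_dataset(wt_spec, "80nM", ph_grid, 4, seed=8)
        b = gen_activation_dataset(wt_spec, "80nM", ph_grid, 4, seed=8)
        assert a.equals(b)

    def test_via_traces_mode_agrees_with_direct_mode(self, wt_spec):
        from asicca.pipeline import fit_dataset

        grid = np.round(np.arange(8.0, 5.0 - 1e-9, -0.4), 10)
        df = gen_activation_dataset(wt_spec, "80nM", grid, 3, seed=13,
                                    noise_sd=0.0, via_traces=True)
        fits = fit_dataset(df).sort_values("cell_id")
        cells = gen_cells(wt_spec, 3, seed=13)
        gen_ph50 = np.array([c.params["80nM"]["ph50"] for c in cells])
        # trace-derived peaks include the (small) conditioning offset, so the
        # agreement is looser than the direct-response round trip
        assert np.max(np.abs(fits["ph50"].to_numpy() - gen_ph50)) < 0.05


class TestToyTrajectories:
    def test_full_occupancy_is_exact(self):
        traj = gen_trajectory({"E81": 1.0}, 200, seed=1)
        occ = contact_occupancy(traj)
        assert occ.fraction(81) == 1.0

    def test_planted_half_occupancy_within_binomial_error(self):
        traj = gen_trajectory({"E81": 0.5}, 10_000, seed=2)
        occ = contact_occupancy(traj)
        assert occ.fraction(81) == pytest.approx(0.5, abs=0.02)

    def test_empty_plan_gives_zero_occupancy(self):
        traj = gen_trajectory({}, 50, seed=3, residues=["E81", "D282"])
        occ = contact_occupancy(traj)
        assert (occ.table["fraction"] == 0.0).all()

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            gen_trajectory({"E81": 0.5, ("GLU", 81, "A"): 0.7}, 10, seed=0)

    def test_occupancy_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            gen_trajectory({"E81": 1.2}, 10, seed=0)

    def test_determinism(self):
        t1 = gen_trajectory({"E81": 0.4, "N370:B": 0.9}, 100, seed=6)
        t2 = gen_trajectory({"E81": 0.4, "N370:B": 0.9}, 100, seed=6)
        assert np.array_equal(t1.coords, t2.coords)
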