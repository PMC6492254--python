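"""Study drivers: protocols, Monte Carlo, CW validation, sweeps, phantom."""

import math

import numpy as np
import pytest

from csmt import (
    Despot1,
    JSR,
    b1rms_sweep_t1,
    compare_pulsed_vs_cw,
    fig_s1_protocol,
    generate_phantom,
    paper_protocol,
    r1_csmt,
    run_monte_carlo,
    simulate_protocol,
    sweep_protocol,
)
from csmt.experiments import ProtocolEntry, ProtocolSpec, add_noise
from csmt.tissue import TwoPoolParameters


class TestProtocols:
    def test_paper_protocol_contents(self):
        prot = paper_protocol()
        spgr = [e for e in prot.entries if e.seq_type == "SPGR"]
        bssfp = [e for e in prot.entries if e.seq_type == "bSSFP"]
        assert [round(math.degrees(e.flip)) for e in spgr] == [6, 8, 10, 12, 14, 16]
        assert [round(math.degrees(e.flip)) for e in bssfp] == [
            15, 25, 35, 45, 55, 65, 25, 55,
        ]
        assert [e.phase_increment for e in bssfp] == [math.pi] * 6 + [0.0] * 2
        assert prot.tr == 7e-3
        assert prot.tau_rf == 0.614e-3
        assert prot.alpha_ref == math.radians(65.0)

    def test_sweep_protocol_contents(self):
        prot = sweep_protocol()
        assert [round(math.degrees(e.flip)) for e in prot.entries] == [6, 12, 18]
        assert prot.tr == 15e-3

    def test_csmt_protocol_rejects_flip_above_reference(self):
        with pytest.raises(ValueError, match="alpha_ref"):
            ProtocolSpec(
                entries=(ProtocolEntry("SPGR", math.radians(80)),),
                mode="csmt",
            )

    def test_csmt_b1rms_operating_point(self):
        assert paper_protocol().b1rms() * 1e6 == pytest.approx(2.0455, abs=1e-3)


class TestSimulateProtocol:
    def test_csmt_saturation_independent_of_flip(self, wm):
        ms = simulate_protocol(wm, paper_protocol("csmt"))
        b1 = ms.frame["b1rms_T"].to_numpy()
        assert np.allclose(b1, b1[0], rtol=1e-12)

    def test_non_csmt_power_scales_with_flip(self, wm):
        ms = simulate_protocol(wm, paper_protocol("non-csmt"))
        f = ms.frame
        ratio = f["b1rms_T"] / np.degrees(f["flip_rad"])
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_seeded_noise_reproducible(self, wm):
        base = simulate_protocol(wm, paper_protocol("csmt"))
        a = add_noise(base, 0.002, np.random.default_rng(42))
        b = add_noise(base, 0.002, np.random.default_rng(42))
        assert np.array_equal(
            a.frame["signal"].to_numpy(), b.frame["signal"].to_numpy()
        )


class TestDespot1FlipConsistency:
    """Fixed-energy sampling makes every SPGR flip pair report the same T1;
    conventional sampling does not."""

    @staticmethod
    def _pair_spread(ms):
        t1s = []
        spgr = ms.spgr
        for i in range(0, 6, 2):
            sub = spgr.subset(spgr.frame.index.isin([i, i + 1]))
            t1s.append(Despot1(sub).fit().t1)
        t1s = np.asarray(t1s)
        return (t1s.max() - t1s.min()) / t1s.mean()

    def test_csmt_pairs_agree_non_csmt_pairs_disagree(self, wm):
        spread_csmt = self._pair_spread(
            simulate_protocol(wm, paper_protocol("csmt"))
        )
        spread_non = self._pair_spread(
            simulate_protocol(wm, paper_protocol("non-csmt"))
        )
        assert spread_csmt < 1e-6
        assert spread_non > 5e-3
        assert spread_non > 100 * max(spread_csmt, 1e-12)


class TestMonteCarlo:
    def test_noiseless_trials_have_zero_spread(self, wm):
        mc = run_monte_carlo(
            wm, paper_protocol("csmt"), n_trials=3, noise_sd=0.0, seed=0
        )
        s = mc.summary().set_index(["method", "param"])
        assert s["sd_s"].max() < 1e-12
        # noiseless CSMT JSR recovers the ground-truth T2 and theory T1
        assert s.loc[("JSR", "t2"), "mean_s"] == pytest.approx(
            wm.t2_f, rel=0.02
        )
        assert s.loc[("JSR", "t1"), "mean_s"] == pytest.approx(
            mc.expected_t1_csmt, rel=0.02
        )

    def test_seed_reproducibility(self, wm):
        kw = dict(n_trials=5, seed=123)
        a = run_monte_carlo(wm, paper_protocol("csmt"), **kw)
        b = run_monte_carlo(wm, paper_protocol("csmt"), **kw)
        assert np.array_equal(a.t1_jsr, b.t1_jsr)
        assert np.array_equal(a.t2_despot, b.t2_despot)

    def test_summary_recomputable_from_arrays(self, wm):
        mc = run_monte_carlo(wm, paper_protocol("csmt"), n_trials=8, seed=3)
        s = mc.summary().set_index(["method", "param"])
        ok = mc.t1_jsr[np.isfinite(mc.t1_jsr)]
        assert s.loc[("JSR", "t1"), "mean_s"] == pytest.approx(ok.mean())
        assert len(mc.t1_despot) == 8

    def test_non_csmt_t2_bias_small_n(self, wm):
        mc = run_monte_carlo(wm, paper_protocol("non-csmt"), n_trials=25, seed=9)
        s = mc.summary().set_index(["method", "param"])
        assert s.loc[("JSR", "t2"), "mean_s"] < wm.t2_f
        assert s.loc[("DESPOT", "t2"), "mean_s"] < wm.t2_f


class TestSubsetConsistency:
    """JSR means across disjoint measurement subsets: consistent under CSMT,
    inconsistent under conventional sampling (Monte Carlo, n=200/subset)."""

    IDX_A = (0, 2, 4, 6, 8, 10, 12)
    IDX_B = (1, 3, 5, 7, 9, 11, 13)

    @classmethod
    def _subset_means(cls, wm, mode, n=200):
        base = simulate_protocol(wm, paper_protocol(mode))
        rng = np.random.default_rng(11)
        out = []
        for idx in (cls.IDX_A, cls.IDX_B):
            vals = []
            for _ in range(n):
                noisy = add_noise(base, 0.002, rng)
                sub = noisy.subset(noisy.frame.index.isin(idx))
                r = JSR(sub).fit()
                if r.converged:
                    vals.append(r.t1)
            vals = np.asarray(vals)
            out.append((vals.mean(), vals.std(ddof=1) / math.sqrt(vals.size)))
        return out

    def test_subset_means_consistent_only_under_csmt(self, wm):
        (ma, sa), (mb, sb) = self._subset_means(wm, "csmt")
        diff_csmt = abs(ma - mb)
        assert diff_csmt <= 2.0 * math.hypot(sa, sb)
        (na, _), (nb, _) = self._subset_means(wm, "non-csmt")
        assert abs(na - nb) > diff_csmt


class TestPulsedVsCW:
    def test_no_mt_tissue_error_negligible(self):
        p = TwoPoolParameters(1.0, 1e-300, 0.0, 0.0, 1.25, 1.0, 12.3, 14e-6)
        res = compare_pulsed_vs_cw(p, fig_s1_protocol())
        assert res.max_rel_error <= 1e-9

    def test_white_matter_below_one_percent(self, wm):
        res = compare_pulsed_vs_cw(wm, fig_s1_protocol())
        assert res.max_rel_error < 0.01
        assert {"pulsed", "cw"} == set(res.traces)

    def test_error_grows_with_tr_at_fixed_b1rms(self, wm):
        """At fixed B1rms (fixed W-bar) the saturation deposition becomes
        more impulsive as TR grows, degrading the CW approximation."""
        from csmt import (
            SequenceParams,
            mean_saturation_rate,
            steady_state_bssfp_pulsed,
            steady_state_cw,
        )

        w = mean_saturation_rate(2.0455e-6, wm.g_lineshape)
        errors = []
        for tr_ms in (7.0, 20.0, 50.0, 100.0):
            tr = tr_ms * 1e-3
            seq = SequenceParams("bSSFP", math.radians(68), tr, 0.614e-3,
                                 math.pi)
            sp = abs(steady_state_bssfp_pulsed(wm, seq, w * tr))
            sc = abs(steady_state_cw(wm, seq, w))
            errors.append(abs(sp - sc) / sc)
        assert all(e1 < e2 for e1, e2 in zip(errors, errors[1:]))


class TestB1rmsSweep:
    def test_tracks_theory_and_monotone(self, wm):
        values = np.arange(0.2, 2.01, 0.2) * 1e-6
        table = b1rms_sweep_t1(wm, values)
        assert np.allclose(
            table["t1_fit_s"], table["t1_theory_s"], rtol=0.02
        )
        assert np.all(np.diff(table["t1_fit_s"]) < 0)

    def test_limits(self, wm):
        # zero-power limit holds for the pulsed model; the full-saturation
        # limit is a CW statement (the pulsed model departs once the
        # per-pulse saturation exponent W*TR greatly exceeds 1)
        table = b1rms_sweep_t1(wm, [1e-12, 50e-6], model="cw")
        assert table["t1_fit_s"].iloc[0] == pytest.approx(1 / 1.2517, rel=0.02)
        assert table["t1_fit_s"].iloc[-1] == pytest.approx(
            1 / (wm.r1_f + wm.k_f), rel=0.02
        )
        pulsed0 = b1rms_sweep_t1(wm, [1e-12])
        assert pulsed0["t1_fit_s"].iloc[0] == pytest.approx(
            1 / 1.2517, rel=0.02
        )

    def test_negative_b1rms_rejected(self, wm):
        with pytest.raises(ValueError):
            b1rms_sweep_t1(wm, [-1e-6])


class TestPhantom:
    def test_uniform_noiseless_phantom_is_constant(self, wm):
        shape = (3, 3, 2)
        ph = generate_phantom(
            shape, np.zeros(shape, dtype=int), {0: wm}, paper_protocol()
        )
        flat = ph.signals.reshape(-1, len(paper_protocol()))
        assert np.allclose(flat, flat[0])

    def test_two_region_jsr_recovers_theory(self, wm):
        other = TwoPoolParameters(1.0, 0.05, 2.0, 40.0, 0.9, 1.0, 9.0, 14e-6)
        shape = (2, 2, 1)
        labels = np.zeros(shape, dtype=int)
        labels[1, :, :] = 1
        prot = paper_protocol()
        ph = generate_phantom(shape, labels, {0: wm, 1: other}, prot)
        from csmt import fit_volume

        maps = fit_volume(ph.signals, ph.template, method="jsr")
        for lab, tis in ((0, wm), (1, other)):
            t1 = maps["t1"][labels == lab].mean()
            t2 = maps["t2"][labels == lab].mean()
            assert t1 == pytest.approx(1 / r1_csmt(tis, prot.w_bar(tis)), rel=0.02)
            assert t2 == pytest.approx(tis.t2_f, rel=0.02)

    def test_transmit_correction_removes_t2_bias(self, wm):
        shape = (2, 1, 1)
        labels = np.zeros(shape, dtype=int)
        b1 = np.full(shape, 0.8)
        prot = paper_protocol()
        ph = generate_phantom(shape, labels, {0: wm}, prot, b1_field=b1)
        from csmt import fit_volume

        uncorr = fit_volume(ph.signals, ph.template, method="jsr")
        corr = fit_volume(ph.signals, ph.template, method="jsr", b1_map=b1)
        err_un = abs(uncorr["t2"].mean() - wm.t2_f) / wm.t2_f
        err_corr = abs(corr["t2"].mean() - wm.t2_f) / wm.t2_f
        assert err_corr < 0.02
        assert err_un > err_corr

    def test_shape_mismatch_rejected(self, wm):
        with pytest.raises(ValueError):
            generate_phantom(
                (2, 2, 2), np.zeros((3, 3, 3), dtype=int), {0: wm},
                paper_protocol(),
            )
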