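"""Single-pool steady-state signal models and relaxometry estimators.

Three estimators of (M0, T1, T2) from variable-flip-angle SPGR/bSSFP data are
provided, mirroring common practice in quantitative MRI:

* ``Despot1`` — linearized Ernst fit of SPGR magnitudes for M0 and T1;
* ``Despot2`` — linearized bSSFP magnitude fit for M0 and T2 given T1;
* ``JSR``     — joint nonlinear least squares of SPGR magnitudes plus the
  real and imaginary bSSFP channels for M0 (magnitude & phase), T1, T2 and
  off-resonance.

Each estimator is a small model class whose :meth:`fit` returns a
:class:`RelaxometryResults` object carrying estimates, standard errors and
diagnostics; ``fit_despot1`` / ``fit_despot2`` / ``fit_jsr`` are functional
shorthands.  When a homogeneous single pool truly generated the data all three
agree (differing only in precision); systematic disagreement between them is a
signature of unmodelled magnetization transfer.

Sign conventions (precession ``exp(-i·Δω0·t)``, per-TR bSSFP phase
``Δω0·TR + Φ``, echo demodulated by the exciting pulse's phase) match the
2-pool simulator in :mod:`csmt.bloch`, to which these closed forms reduce when
the macromolecular pool is removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MeasurementSet",
    "FitOptions",
    "RelaxometryResults",
    "Despot1",
    "Despot2",
    "JSR",
    "fit_despot1",
    "fit_despot2",
    "fit_jsr",
    "signal_spgr",
    "signal_bssfp",
    "fit_volume",
]

_COLUMNS = ["seq_type", "flip_rad", "tr_s", "phase_inc_rad", "signal"]


# -- forward models --------------------------------------------------------

def signal_spgr(m0, t1, flip, tr):
    """Ernst steady-state SPGR magnitude: m0·sinα·(1−E1)/(1−E1·cosα).

    ``flip`` and ``tr`` may be scalars or broadcastable arrays.
    """
    if np.any(np.asarray(t1) <= 0) or np.any(np.asarray(tr) <= 0):
        raise ValueError("t1 and tr must be > 0")
    e1 = np.exp(-np.asarray(tr, dtype=float) / t1)
    out = m0 * np.sin(flip) * (1.0 - e1) / (1.0 - e1 * np.cos(flip))
    return out if np.ndim(out) else float(out)


def signal_bssfp(
    m0,
    t1,
    t2,
    delta_omega0,
    flip,
    tr,
    phase_increment=math.pi,
    te=None,
):
    """Single-pool balanced-SSFP steady-state complex signal at the echo.

    Computed as the exact fixed point of the rotation–precession–relaxation
    cycle (per-TR precession Δω0·TR + Φ), sampled ``te`` after the pulse
    (default TR/2) and demodulated by the exciting pulse's phase.  ``m0`` may
    be complex to carry a receive/transmit phase.  ``flip``, ``tr``,
    ``phase_increment`` and ``te`` broadcast, returning an array of signals.
    """
    if np.any(np.asarray(t1) <= 0) or np.any(np.asarray(t2) <= 0):
        raise ValueError("t1 and t2 must be > 0")
    scalar = all(
        np.ndim(v) == 0 for v in (flip, tr, phase_increment)
    ) and (te is None or np.ndim(te) == 0)
    flip, tr, phi = np.broadcast_arrays(
        np.atleast_1d(np.asarray(flip, dtype=float)), tr, phase_increment
    )
    te = tr / 2.0 if te is None else np.broadcast_to(te, flip.shape)
    n = flip.size
    e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
    theta = delta_omega0 * tr + phi
    ct, st = np.cos(theta), np.sin(theta)
    ca, sa = np.cos(flip), np.sin(flip)
    m0_mag = abs(m0)
    # period map from just before the pulse: M' = Rz(theta)·E·Rx(flip)·M + b
    z = np.zeros(n)
    one = np.ones(n)
    rz = np.stack(
        [np.stack([ct, st, z], -1), np.stack([-st, ct, z], -1),
         np.stack([z, z, one], -1)], -2
    )
    rel = np.zeros((n, 3, 3))
    rel[:, 0, 0] = e2
    rel[:, 1, 1] = e2
    rel[:, 2, 2] = e1
    rx = np.stack(
        [np.stack([one, z, z], -1), np.stack([z, ca, sa], -1),
         np.stack([z, -sa, ca], -1)], -2
    )
    A = rz @ rel @ rx
    b = np.zeros((n, 3))
    b[:, 2] = m0_mag * (1.0 - e1)
    m = np.linalg.solve(np.eye(3) - A, b[..., None])[..., 0]
    m = (rx @ m[..., None])[..., 0]
    s = m[:, 0] + 1j * m[:, 1]
    s = s * np.exp(-te / t2 - 1j * delta_omega0 * te)
    if m0_mag:
        s = s * (m0 / m0_mag)
    return complex(s[0]) if scalar else s


# -- data container --------------------------------------------------------

class MeasurementSet:
    """A set of steady-state measurements with their complex signal values.

    Wraps a DataFrame with columns ``seq_type`` ("SPGR"/"bSSFP"),
    ``flip_rad``, ``tr_s``, ``phase_inc_rad`` and complex ``signal``.
    ``transmit_scale`` is an optional relative B1+ factor multiplying all
    nominal flips at fit time.
    """

    def __init__(self, frame: pd.DataFrame, transmit_scale: float = 1.0):
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"measurement frame missing columns: {missing}")
        bad = set(frame["seq_type"]) - {"SPGR", "bSSFP"}
        if bad:
            raise ValueError(f"unknown seq_type values: {sorted(bad)}")
        if frame["signal"].isna().any():
            raise ValueError("NaN signal values in measurement set")
        self.frame = frame.reset_index(drop=True)
        self.transmit_scale = float(transmit_scale)

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple],
        transmit_scale: float = 1.0,
    ) -> "MeasurementSet":
        """Build from (seq_type, flip_rad, tr_s, phase_inc_rad, signal) tuples."""
        return cls(pd.DataFrame(records, columns=_COLUMNS), transmit_scale)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, mask) -> "MeasurementSet":
        return MeasurementSet(self.frame[mask], self.transmit_scale)

    @property
    def spgr(self) -> "MeasurementSet":
        return self.subset(self.frame["seq_type"] == "SPGR")

    @property
    def bssfp(self) -> "MeasurementSet":
        return self.subset(self.frame["seq_type"] == "bSSFP")

    def with_signals(self, signals: np.ndarray) -> "MeasurementSet":
        """Copy with the signal column replaced (same measurement geometry)."""
        frame = self.frame.copy()
        frame["signal"] = np.asarray(signals)
        return MeasurementSet(frame, self.transmit_scale)


@dataclass
class FitOptions:
    """Nonlinear-fit controls for :class:`JSR`.

    cost_tolerance:  stop when the cost (sum of squared residuals) change is
                     below this (default 1e-15).
    max_iterations:  cap on function evaluations (default 500).
    t2_init:         initial T2 (s) when no better guess exists.
    free_delta_omega0: fit Δω0 (default) or pin it to 0.
    multi_start:     one seeded perturbed restart if the first solution's cost
                     exceeds 1e-6·Σ|S|².
    seed:            RNG seed for the restart perturbation.
    """

    cost_tolerance: float = 1e-15
    max_iterations: int = 500
    t2_init: float = 0.08
    free_delta_omega0: bool = True
    multi_start: bool = True
    seed: int = 0
    t1_bounds: tuple[float, float] = (0.05, 10.0)
    t2_bounds: tuple[float, float] = (0.005, 5.0)

    def __post_init__(self):
        if self.cost_tolerance <= 0:
            raise ValueError("cost_tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RelaxometryResults:
    """Fitted single-pool parameters with uncertainties and diagnostics."""

    method: str
    m0: float
    t1: float
    t2: float = math.nan
    m0_phase: float = 0.0
    delta_omega0: float = math.nan
    residual_norm: float = math.nan
    converged: bool = True
    n_iter: int = 0
    bse: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def params(self) -> dict:
        return {
            "m0": self.m0,
            "m0_phase": self.m0_phase,
            "t1": self.t1,
            "t2": self.t2,
            "delta_omega0": self.delta_omega0,
        }

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            f"{self.method} relaxometry fit",
            "=" * 34,
            f"{'parameter':<14}{'estimate':>12}{'std err':>10}",
            "-" * 36,
        ]
        units = {"m0": "a.u.", "m0_phase": "rad", "t1": "s", "t2": "s",
                 "delta_omega0": "rad/s"}
        for name, value in self.params.items():
            if math.isnan(value) and name not in ("t1", "t2", "m0"):
                continue
            se = self.bse.get(name)
            se_s = f"{se:10.3g}" if se is not None and math.isfinite(se) else " " * 10
            lines.append(f"{name:<14}{value:12.6g}{se_s}  [{units[name]}]")
        lines.append("-" * 36)
        lines.append(
            f"cost {self.residual_norm:.3g}   converged {self.converged}   "
            f"n_iter {self.n_iter}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = dict(self.params)
        d.update(
            method=self.method,
            residual_norm=self.residual_norm,
            converged=self.converged,
            n_iter=self.n_iter,
            bse=dict(self.bse),
        )
        return d


# -- DESPOT linearizations -------------------------------------------------

def _linearize(mag: np.ndarray, flips: np.ndarray):
    """OLS of S/sinα on S/tanα; returns slope, intercept and their SEs."""
    y = mag / np.sin(flips)
    x = mag / np.tan(flips)
    X = np.column_stack([x, np.ones_like(x)])
    coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope, intercept = coef
    n = len(y)
    if n > 2:
        resid = y - X @ coef
        s2 = float(resid @ resid) / (n - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.array([math.nan, math.nan])
    resid = y - X @ coef
    return slope, intercept, se[0], se[1], float(resid @ resid)


class Despot1:
    """DESPOT1: M0 and T1 from SPGR magnitudes via the linearized Ernst fit."""

    def __init__(self, data: MeasurementSet):
        spgr = data.spgr
        if len(spgr) < 2:
            raise ValueError("DESPOT1 needs at least 2 SPGR measurements")
        if spgr.frame["flip_rad"].nunique() < 2:
            raise ValueError("degenerate design: all SPGR flip angles identical")
        if spgr.frame["tr_s"].nunique() != 1:
            raise ValueError("DESPOT1 requires a common TR")
        self.data = spgr

    def fit(self, options: FitOptions | None = None) -> RelaxometryResults:
        f = self.data.frame
        flips = f["flip_rad"].to_numpy() * self.data.transmit_scale
        mag = np.abs(f["signal"].to_numpy())
        tr = float(f["tr_s"].iloc[0])
        slope, intercept, se_s, se_i, rss = _linearize(mag, flips)
        ok = 0.0 < slope < 1.0
        if ok:
            t1 = -tr / math.log(slope)
            m0 = intercept / (1.0 - slope)
            t1_se = (
                tr / (slope * math.log(slope) ** 2) * se_s
                if math.isfinite(se_s)
                else math.nan
            )
        else:
            t1 = m0 = t1_se = math.nan
        return RelaxometryResults(
            method="DESPOT1",
            m0=m0,
            t1=t1,
            residual_norm=rss,
            converged=bool(ok),
            n_iter=1,
            bse={"t1": t1_se},
            diagnostics={"slope": slope, "intercept": intercept,
                         "slope_se": se_s, "intercept_se": se_i},
        )


class Despot2:
    """DESPOT2: M0 and T2 from Φ=π bSSFP magnitudes given a known T1."""

    def __init__(self, data: MeasurementSet, t1_known: float):
        if not t1_known > 0:
            raise ValueError("t1_known must be > 0")
        bssfp = data.bssfp
        bssfp = bssfp.subset(
            np.isclose(bssfp.frame["phase_inc_rad"], math.pi)
        )
        if len(bssfp) < 2:
            raise ValueError("DESPOT2 needs at least 2 bSSFP (Φ=π) measurements")
        if bssfp.frame["flip_rad"].nunique() < 2:
            raise ValueError("degenerate design: all bSSFP flip angles identical")
        if bssfp.frame["tr_s"].nunique() != 1:
            raise ValueError("DESPOT2 requires a common TR")
        self.data = bssfp
        self.t1_known = float(t1_known)

    def fit(self, options: FitOptions | None = None) -> RelaxometryResults:
        f = self.data.frame
        flips = f["flip_rad"].to_numpy() * self.data.transmit_scale
        mag = np.abs(f["signal"].to_numpy())
        tr = float(f["tr_s"].iloc[0])
        slope, intercept, se_s, se_i, rss = _linearize(mag, flips)
        e1 = math.exp(-tr / self.t1_known)
        e2 = (e1 - slope) / (1.0 - slope * e1)
        ok = 0.0 < e2 < 1.0
        if ok:
            t2 = -tr / math.log(e2)
            m0 = intercept * (1.0 - e1 * e2) / (1.0 - e1)
            de2 = abs((e1 * e1 - 1.0) / (1.0 - slope * e1) ** 2)
            t2_se = (
                tr / (e2 * math.log(e2) ** 2) * de2 * se_s
                if math.isfinite(se_s)
                else math.nan
            )
        else:
            t2 = m0 = t2_se = math.nan
        return RelaxometryResults(
            method="DESPOT2",
            m0=m0,
            t1=self.t1_known,
            t2=t2,
            residual_norm=rss,
            converged=bool(ok),
            n_iter=1,
            bse={"t2": t2_se},
            diagnostics={"slope": slope, "intercept": intercept,
                         "slope_se": se_s},
        )


# -- JSR joint fit ---------------------------------------------------------

class JSR:
    """Joint system relaxometry: one nonlinear fit of all SPGR + bSSFP data.

    Free parameters: M0 magnitude and phase, T1, T2 and (optionally)
    off-resonance Δω0.  Residuals are SPGR magnitudes plus the real and
    imaginary bSSFP channels; minimized with a trust-region-reflective
    least-squares solver.
    """

    def __init__(self, data: MeasurementSet):
        if len(data.spgr) < 1 or len(data.bssfp) < 1 or len(data) < 4:
            raise ValueError("JSR needs >= 4 measurements spanning SPGR and bSSFP")
        self.data = data
        fs = data.spgr.frame
        fb = data.bssfp.frame
        self._spgr_flip = fs["flip_rad"].to_numpy(dtype=float)
        self._spgr_tr = fs["tr_s"].to_numpy(dtype=float)
        self._spgr_mag = np.abs(fs["signal"].to_numpy(dtype=complex))
        self._b_flip = fb["flip_rad"].to_numpy(dtype=float)
        self._b_tr = fb["tr_s"].to_numpy(dtype=float)
        self._b_phi = fb["phase_inc_rad"].to_numpy(dtype=float)
        self._b_sig = fb["signal"].to_numpy(dtype=complex)

    # residual vector ------------------------------------------------------
    def _residuals(self, x: np.ndarray) -> np.ndarray:
        m0_mag, m0_phase, t1, t2, dw0 = x
        ts = self.data.transmit_scale
        r_spgr = (
            signal_spgr(m0_mag, t1, self._spgr_flip * ts, self._spgr_tr)
            - self._spgr_mag
        )
        model_b = signal_bssfp(
            m0_mag * np.exp(1j * m0_phase), t1, t2, dw0,
            self._b_flip * ts, self._b_tr, self._b_phi,
        )
        diff = np.atleast_1d(model_b) - self._b_sig
        return np.concatenate([np.atleast_1d(r_spgr), diff.real, diff.imag])

    def fit(self, options: FitOptions | None = None) -> RelaxometryResults:
        opts = options or FitOptions()
        f = self.data.frame
        power = float(np.sum(np.abs(f["signal"].to_numpy()) ** 2))

        # initialize T1/M0 from DESPOT1 on the SPGR subset when possible
        t1_init, m0_init = 1.0, float(np.max(np.abs(f["signal"]))) * 2.0
        try:
            d1 = Despot1(self.data).fit()
            if d1.converged and opts.t1_bounds[0] < d1.t1 < opts.t1_bounds[1]:
                t1_init, m0_init = d1.t1, d1.m0
        except ValueError:
            pass
        x0 = np.array([max(m0_init, 1e-12), 0.0, t1_init, opts.t2_init, 0.0])

        tr_min = float(f["tr_s"].min())
        dw_max = math.pi / tr_min if opts.free_delta_omega0 else 1e-12
        lo = np.array([0.0, -math.pi, opts.t1_bounds[0], opts.t2_bounds[0], -dw_max])
        hi = np.array([np.inf, math.pi, opts.t1_bounds[1], opts.t2_bounds[1], dw_max])
        x0 = np.clip(x0, lo + 1e-15, np.minimum(hi, 1e15) - 1e-15)

        def solve(x_start):
            return least_squares(
                self._residuals,
                x_start,
                bounds=(lo, hi),
                method="trf",
                ftol=max(opts.cost_tolerance, 2.3e-16),
                xtol=1e-15,
                gtol=1e-15,
                max_nfev=opts.max_iterations,
            )

        res = solve(x0)
        cost = 2.0 * res.cost  # scipy cost is one half the residual sum of squares
        if opts.multi_start and cost > 1e-6 * power:
            rng = np.random.default_rng(opts.seed)
            x1 = x0 * (1.0 + 0.2 * rng.standard_normal(x0.size))
            x1 = np.clip(x1, lo + 1e-15, np.minimum(hi, 1e15) - 1e-15)
            res2 = solve(x1)
            if res2.cost < res.cost:
                res = res2
                cost = 2.0 * res.cost

        m0_mag, m0_phase, t1, t2, dw0 = res.x
        bse = {}
        dof = res.fun.size - res.x.size
        if dof > 0:
            try:
                jtj = res.jac.T @ res.jac
                cov = np.linalg.pinv(jtj) * (cost / dof)
                se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
                bse = dict(zip(["m0", "m0_phase", "t1", "t2", "delta_omega0"], se))
            except np.linalg.LinAlgError:
                pass
        return RelaxometryResults(
            method="JSR",
            m0=m0_mag,
            m0_phase=m0_phase,
            t1=t1,
            t2=t2,
            delta_omega0=dw0,
            residual_norm=cost,
            converged=bool(res.status > 0),
            n_iter=int(res.nfev),
            bse=bse,
            diagnostics={"status": res.status, "message": res.message},
        )


# -- functional shorthands -------------------------------------------------

def fit_despot1(
    spgr: MeasurementSet, options: FitOptions | None = None
) -> RelaxometryResults:
    """DESPOT1 fit of the SPGR subset of ``spgr``."""
    return Despot1(spgr).fit(options)


def fit_despot2(
    bssfp: MeasurementSet, t1_known: float, options: FitOptions | None = None
) -> RelaxometryResults:
    """DESPOT2 fit of the Φ=π bSSFP subset of ``bssfp`` given ``t1_known``."""
    return Despot2(bssfp, t1_known).fit(options)


def fit_jsr(
    all_data: MeasurementSet, options: FitOptions | None = None
) -> RelaxometryResults:
    """Joint fit of all SPGR and bSSFP measurements."""
    return JSR(all_data).fit(options)


# -- voxelwise fitting -----------------------------------------------------

def fit_volume(
    signals: np.ndarray,
    template: MeasurementSet,
    method: str = "jsr",
    b1_map: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    options: FitOptions | None = None,
) -> dict[str, np.ndarray]:
    """Per-voxel fits over a 4-D array of signals (..., n_measurements).

    ``template`` supplies the measurement geometry; ``b1_map`` an optional
    per-voxel transmit scale.  Returns maps of t1, t2, m0 (NaN outside the
    mask or where a fit fails).
    """
    signals = np.asarray(signals)
    if signals.shape[-1] != len(template):
        raise ValueError("last axis of signals must match the measurement count")
    spatial = signals.shape[:-1]
    if b1_map is not None and np.shape(b1_map) != spatial:
        raise ValueError("b1_map shape must match the spatial shape")
    if mask is not None and np.shape(mask) != spatial:
        raise ValueError("mask shape must match the spatial shape")

    out = {k: np.full(spatial, np.nan) for k in ("t1", "t2", "m0")}
    method = method.lower()
    for idx in np.ndindex(spatial):
        if mask is not None and not mask[idx]:
            continue
        ts = float(b1_map[idx]) if b1_map is not None else template.transmit_scale
        data = template.with_signals(signals[idx])
        data.transmit_scale = ts
        try:
            if method == "jsr":
                r = JSR(data).fit(options)
            elif method == "despot":
                r1 = Despot1(data).fit(options)
                r = Despot2(data, r1.t1).fit(options) if r1.converged else r1
                r.m0 = r1.m0
                r.t1 = r1.t1
            else:
                raise ValueError("method must be 'jsr' or 'despot'")
        except ValueError:
            continue
        out["t1"][idx] = r.t1
        out["t2"][idx] = r.t2
        out["m0"][idx] = r.m0
    return out
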