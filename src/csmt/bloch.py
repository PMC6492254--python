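"""Time-domain propagation and steady states of the 2-pool MT system.

The spin state is the 4-vector (mx_f, my_f, mz_f, mz_m): free-pool transverse
and longitudinal magnetization plus the macromolecular longitudinal component
(the macromolecular transverse decay is far too fast to represent; RF purely
saturates that pool).  Evolution between pulses is the exact solution of the
coupled linear relaxation/exchange/precession system via a 5x5 augmented matrix
exponential.  RF pulses are instantaneous rotations of the free pool combined
with a lumped exponential saturation of mz_m; the repetition period is a full
TR of free evolution, so the pulse duration enters only through field
amplitudes and the saturation exponent.

Periodic steady states are fixed points of the affine map of one TR, obtained
by a single linear solve (with an iteration fallback for ill-conditioned maps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .tissue import GAMMA_PROTON, TwoPoolParameters

__all__ = [
    "SequenceParams",
    "equilibrium_state",
    "free_propagator",
    "rotation_operator",
    "pulse_operator_pulsed",
    "pulse_saturation_exponent",
    "steady_state_spgr_pulsed",
    "steady_state_bssfp_pulsed",
    "steady_state_cw",
    "steady_state_signal",
    "iterate_period",
]

_SPOIL = np.diag([0.0, 0.0, 1.0, 1.0])
_COND_LIMIT = 1e12


@dataclass(frozen=True)
class SequenceParams:
    """One steady-state measurement: sequence type, timing and RF geometry.

    seq_type:        "SPGR" (ideally spoiled) or "bSSFP" (balanced).
    flip:            nominal flip angle (rad); the achieved flip is
                     flip * transmit_scale.
    tr:              repetition time (s).
    tau_rf:          RF pulse duration (s), < tr; affects amplitudes only.
    phase_increment: per-TR RF phase increment Φ (rad); bSSFP only.
    delta_omega0:    off-resonance (rad/s).
    te:              echo time (s); defaults to 0 for SPGR, tr/2 for bSSFP.
    transmit_scale:  relative B1+ factor (scales flip; in pulsed mode its
                     square also scales the saturation exponent).
    """

    seq_type: str
    flip: float
    tr: float
    tau_rf: float = 0.614e-3
    phase_increment: float = math.pi
    delta_omega0: float = 0.0
    te: float | None = None
    transmit_scale: float = 1.0

    def __post_init__(self):
        if self.seq_type not in ("SPGR", "bSSFP"):
            raise ValueError("seq_type must be 'SPGR' or 'bSSFP'")
        if not 0 < self.tau_rf < self.tr:
            raise ValueError("need 0 < tau_rf < tr")
        te = self.echo_time
        if not 0 <= te <= self.tr:
            raise ValueError("need 0 <= te <= tr")

    @property
    def echo_time(self) -> float:
        if self.te is not None:
            return self.te
        return 0.0 if self.seq_type == "SPGR" else self.tr / 2.0


def equilibrium_state(p: TwoPoolParameters) -> np.ndarray:
    """Thermal equilibrium (0, 0, m0_f, m0_m)."""
    return np.array([0.0, 0.0, p.m0_f, p.m0_m])


def _generator(
    p: TwoPoolParameters, omega: float, w_cw: float
) -> tuple[np.ndarray, np.ndarray]:
    """Drift matrix A and constant term c of dM/dt = A·M + c with B1 = 0.

    ``omega`` is the transverse precession rate in the frame used (rad/s);
    ``w_cw`` an optional continuous saturation rate acting on mz_m.
    """
    A = np.array(
        [
            [-p.r2_f, omega, 0.0, 0.0],
            [-omega, -p.r2_f, 0.0, 0.0],
            [0.0, 0.0, -(p.r1_f + p.k_f), p.k_m],
            [0.0, 0.0, p.k_f, -(p.r1_m + p.k_m + w_cw)],
        ]
    )
    c = np.array([0.0, 0.0, p.r1_f * p.m0_f, p.r1_m * p.m0_m])
    return A, c


def free_propagator(
    p: TwoPoolParameters,
    duration: float,
    delta_omega0: float = 0.0,
    w_cw: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact affine map (F, f) of free evolution: M(t+d) = F·M(t) + f.

    Matrix exponential of the augmented 5x5 system; duration 0 yields the
    identity map.  ``w_cw`` adds a continuous saturation rate on mz_m (used by
    the CW-equivalent model).
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0.0:
        return np.eye(4), np.zeros(4)
    A, c = _generator(p, delta_omega0, w_cw)
    aug = np.zeros((5, 5))
    aug[:4, :4] = A * duration
    aug[:4, 4] = c * duration
    phi = expm(aug)
    return phi[:4, :4], phi[:4, 4]


def rotation_operator(flip: float, phase: float = 0.0) -> np.ndarray:
    """Instantaneous free-pool rotation by ``flip`` about a transverse axis.

    ``phase`` is the axis angle from +x; mz_m is untouched.
    """
    ca, sa = math.cos(flip), math.sin(flip)
    cp, sp = math.cos(phase), math.sin(phase)
    # Rz(phase) @ Rx(flip) @ Rz(-phase) on (mx, my, mz)
    R3 = np.array(
        [
            [cp * cp + sp * sp * ca, cp * sp * (1 - ca), -sp * sa],
            [cp * sp * (1 - ca), sp * sp + cp * cp * ca, cp * sa],
            [sp * sa, -cp * sa, ca],
        ]
    )
    R = np.eye(4)
    R[:3, :3] = R3
    return R


def pulse_saturation_exponent(
    energy: float, g: float, gamma: float = GAMMA_PROTON
) -> float:
    """Lumped per-pulse saturation exponent W_inst·τRF = π·γ²·(∫B1²dt)·G.

    ``energy`` is the pulse energy ∫B1²dt (T²·s).  Equal, by construction, to
    W̄·TR for the B1rms that spreads the same energy over the full TR.
    """
    if energy < 0 or g < 0:
        raise ValueError("energy and g must be >= 0")
    return math.pi * gamma**2 * energy * g


def pulse_operator_pulsed(
    p: TwoPoolParameters,
    flip: float,
    tau_rf: float,
    w_instant: float,
    phase: float = 0.0,
) -> np.ndarray:
    """Instantaneous pulse map: free-pool rotation + mz_m saturation.

    The macromolecular pool is multiplied by exp(−w_instant·tau_rf) where
    ``w_instant`` is the CW rate at the pulse's own RMS amplitude.
    """
    if w_instant < 0:
        raise ValueError("w_instant must be >= 0")
    op = rotation_operator(flip, phase)
    op[3, 3] = math.exp(-w_instant * tau_rf)
    return op


# -- periodic steady states ------------------------------------------------

def _fixed_point(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fixed point x = A·x + b of an affine period map."""
    M = np.eye(4) - A
    if np.linalg.cond(M) > _COND_LIMIT:
        # near-singular period map: fall back to brute iteration
        x = np.zeros(4)
        for _ in range(200000):
            x_new = A @ x + b
            if np.max(np.abs(x_new - x)) < 1e-14:
                return x_new
            x = x_new
        raise np.linalg.LinAlgError("singular period map: steady state diverges")
    return np.linalg.solve(M, b)


def _period_map(
    p: TwoPoolParameters, seq: SequenceParams, sat_exponent: float, w_cw: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affine map of one TR from just before the pulse, plus the pulse op.

    bSSFP phase cycling is absorbed into an effective precession rate
    Δω0 + Φ/TR so every pulse rotates about +x (precession per TR is then
    Δω0·TR + Φ).  SPGR ideally spoils the transverse state at the end of TR.
    Returns (P, F_TR·P-composition matrix A, offset b) collapsed to
    (pulse_op, A, b) with M⁻_{n+1} = A·M⁻_n + b.
    """
    ts = seq.transmit_scale
    pulse = rotation_operator(seq.flip * ts, 0.0)
    if sat_exponent:
        pulse[3, 3] = math.exp(-sat_exponent * ts**2)
    if seq.seq_type == "SPGR":
        omega = seq.delta_omega0  # spoiled: phase cycling is irrelevant
    else:
        omega = seq.delta_omega0 + seq.phase_increment / seq.tr
    F, f = free_propagator(p, seq.tr, omega, w_cw)
    A = F @ pulse
    b = f
    if seq.seq_type == "SPGR":
        A = _SPOIL @ A
        b = _SPOIL @ b
    return pulse, A, b


def _echo_signal(
    p: TwoPoolParameters,
    seq: SequenceParams,
    pulse: np.ndarray,
    m_before: np.ndarray,
    w_cw: float,
) -> complex:
    """Complex demodulated free-pool signal at the echo time."""
    te = seq.echo_time
    if seq.seq_type == "SPGR":
        # ideal spoiling: signal from the longitudinal state just before the
        # pulse, tipped by the achieved flip, decayed/precessed over TE
        s = math.sin(seq.flip * seq.transmit_scale) * m_before[2]
        return s * np.exp((-1j * seq.delta_omega0 - p.r2_f) * te)
    m = pulse @ m_before
    # within-TR evolution uses the physical off-resonance only: the receiver
    # is referenced to the phase of the exciting pulse
    F, f = free_propagator(p, te, seq.delta_omega0, w_cw)
    m = F @ m + f
    return complex(m[0], m[1])


def steady_state_spgr_pulsed(
    p: TwoPoolParameters, seq: SequenceParams, sat_exponent: float
) -> complex:
    """Ideally spoiled SPGR steady-state signal under pulsed saturation.

    ``sat_exponent`` is the per-pulse macromolecular saturation exponent at
    nominal transmit (see :func:`pulse_saturation_exponent`).
    """
    if seq.seq_type != "SPGR":
        raise ValueError("sequence is not SPGR")
    pulse, A, b = _period_map(p, seq, sat_exponent, 0.0)
    m = _fixed_point(A, b)
    return _echo_signal(p, seq, pulse, m, 0.0)


def steady_state_bssfp_pulsed(
    p: TwoPoolParameters, seq: SequenceParams, sat_exponent: float
) -> complex:
    """Balanced SSFP steady-state signal under pulsed saturation."""
    if seq.seq_type != "bSSFP":
        raise ValueError("sequence is not bSSFP")
    pulse, A, b = _period_map(p, seq, sat_exponent, 0.0)
    m = _fixed_point(A, b)
    return _echo_signal(p, seq, pulse, m, 0.0)


def steady_state_cw(
    p: TwoPoolParameters, seq: SequenceParams, w_bar: float
) -> complex:
    """Steady-state signal in the CW-equivalent model.

    Saturation acts continuously on mz_m at rate ``w_bar`` throughout TR and
    the pulse applies no impulsive saturation.  For SPGR this reproduces, to
    the accuracy of the quasi-static (dMzm/dt ≈ 0) approximation, the Ernst
    signal of the effective single pool (m0_csmt, 1/r1_csmt).
    """
    if w_bar < 0:
        raise ValueError("w_bar must be >= 0")
    pulse, A, b = _period_map(p, seq, 0.0, w_bar)
    m = _fixed_point(A, b)
    return _echo_signal(p, seq, pulse, m, w_bar)


def steady_state_signal(
    p: TwoPoolParameters,
    seq: SequenceParams,
    *,
    mode: str,
    sat_exponent: float = 0.0,
    w_bar: float = 0.0,
) -> complex:
    """Dispatch to the pulsed or CW steady-state model."""
    if mode == "cw":
        return steady_state_cw(p, seq, w_bar)
    if mode != "pulsed":
        raise ValueError("mode must be 'pulsed' or 'cw'")
    if seq.seq_type == "SPGR":
        return steady_state_spgr_pulsed(p, seq, sat_exponent)
    return steady_state_bssfp_pulsed(p, seq, sat_exponent)


def iterate_period(
    p: TwoPoolParameters,
    seq: SequenceParams,
    sat_exponent: float,
    n_periods: int,
    w_cw: float = 0.0,
    m0: np.ndarray | None = None,
) -> np.ndarray:
    """Propagate the period map ``n_periods`` times from equilibrium.

    Brute-force oracle for the fixed-point solve; returns the state just
    before the next pulse.
    """
    _, A, b = _period_map(p, seq, sat_exponent, w_cw)
    m = equilibrium_state(p) if m0 is None else np.asarray(m0, dtype=float)
    for _ in range(n_periods):
        m = A @ m + b
    return m
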