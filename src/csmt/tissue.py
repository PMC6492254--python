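"""Two-pool magnetization-transfer tissue model and its effective single-pool reduction.

A voxel is modelled as a mobile "free" proton pool (observable, with relaxation
rates ``r1_f``/``r2_f``) exchanging longitudinal magnetization with a semi-solid
macromolecular pool (unobservable, characterized by ``r1_m`` and an absorption
lineshape value ``g_lineshape``).  Under short-TR steady-state imaging with a
fixed RMS RF field, the coupled system behaves as a *single* pool whose
equilibrium magnetization and longitudinal rate depend on the mean macromolecular
saturation rate W̄ = π(γ·B1rms)²·G.  This module holds the tissue
parameterization, the CW mean-saturation-rate formula, and the closed forms for
the effective parameters and the inversion-recovery observed rate.

All quantities are SI: tesla, seconds, s⁻¹, radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

__all__ = [
    "GAMMA_PROTON",
    "TwoPoolParameters",
    "get_preset",
    "PRESET_NAMES",
    "mean_saturation_rate",
    "r1_csmt",
    "m0_csmt",
    "r1_observed_ir",
]

#: Proton gyromagnetic ratio, rad s⁻¹ T⁻¹.
GAMMA_PROTON = 2.6752218744e8

_FIELDS = ("m0_f", "m0_m", "k_f", "k_m", "r1_f", "r1_m", "r2_f", "g_lineshape")


@dataclass(frozen=True)
class TwoPoolParameters:
    """Constants of the 2-pool MT model.

    Parameters
    ----------
    m0_f : float
        Equilibrium free-pool magnetization (arbitrary units, > 0).
    m0_m : float
        Equilibrium macromolecular magnetization (same units, >= 0).
    k_f : float
        Free -> macromolecular exchange rate (s⁻¹, >= 0).
    k_m : float
        Macromolecular -> free exchange rate (s⁻¹, >= 0).
    r1_f, r1_m : float
        Longitudinal relaxation rates of the two pools (s⁻¹, > 0).
    r2_f : float
        Free-pool transverse relaxation rate (s⁻¹, > 0).
    g_lineshape : float
        Macromolecular absorption lineshape value G (seconds, >= 0), treated
        as frequency independent.
    """

    m0_f: float
    m0_m: float
    k_f: float
    k_m: float
    r1_f: float
    r1_m: float
    r2_f: float
    g_lineshape: float

    def __post_init__(self) -> None:
        for name in _FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.m0_f <= 0:
            raise ValueError("m0_f must be > 0")
        for name in ("m0_m", "k_f", "k_m", "g_lineshape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("r1_f", "r1_m", "r2_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    # -- convenience ------------------------------------------------------
    @property
    def t1_f(self) -> float:
        """Free-pool T1 (s)."""
        return 1.0 / self.r1_f

    @property
    def t2_f(self) -> float:
        """Free-pool T2 (s)."""
        return 1.0 / self.r2_f

    def without_mt(self) -> "TwoPoolParameters":
        """Copy with the macromolecular pool removed (single-pool tissue)."""
        return replace(self, m0_m=1e-300, k_f=0.0, k_m=0.0)

    # -- plain-text config I/O -------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the parameters as ``key = value`` plain text (SI units)."""
        lines = [f"{k} = {v!r}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TwoPoolParameters":
        """Read a ``key = value`` plain-text tissue file (SI units)."""
        values: dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed tissue line: {raw!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in _FIELDS:
                raise ValueError(f"unknown tissue field {key!r}")
            values[key] = float(val)
        missing = [k for k in _FIELDS if k not in values]
        if missing:
            raise ValueError(f"tissue file missing fields: {missing}")
        return cls(**values)


# White-matter values of Gloor et al.'s 2-pool model, the reference tissue for
# all numerical studies in this package.
_GLOOR_WM = TwoPoolParameters(
    m0_f=1.0,
    m0_m=0.157,
    k_f=4.45,
    k_m=28.34,
    r1_f=1.1,
    r1_m=1.0,
    r2_f=12.3,
    g_lineshape=14e-6,
)

_PRESETS = {"gloor_wm": _GLOOR_WM}

PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> TwoPoolParameters:
    """Return a named tissue preset (currently ``gloor_wm``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown tissue preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def mean_saturation_rate(
    b1rms: float, g: float, gamma: float = GAMMA_PROTON
) -> float:
    """Mean CW-equivalent macromolecular saturation rate W̄ = π(γ·B1rms)²·G.

    Parameters
    ----------
    b1rms : float
        RMS RF field amplitude over the repetition period (tesla, >= 0).
    g : float
        Absorption lineshape value (seconds, >= 0).
    gamma : float
        Gyromagnetic ratio (rad s⁻¹ T⁻¹).

    Returns
    -------
    float
        Saturation rate in s⁻¹.
    """
    if b1rms < 0:
        raise ValueError("b1rms must be >= 0")
    if g < 0:
        raise ValueError("g must be >= 0")
    return math.pi * (gamma * b1rms) ** 2 * g


def r1_csmt(p: TwoPoolParameters, w_bar: float) -> float:
    """Effective longitudinal rate R1csmt(W̄) of the reduced single pool.

    R1csmt = R1f + kf·(1 − km/(R1m + km + W̄)).  Monotone non-decreasing in
    W̄, ranging from R1f + kf·R1m/(R1m+km) at zero power to R1f + kf at full
    saturation.
    """
    if w_bar < 0:
        raise ValueError("w_bar must be >= 0")
    denom = p.r1_m + p.k_m + w_bar
    return p.r1_f + p.k_f * (1.0 - p.k_m / denom)


def m0_csmt(p: TwoPoolParameters, w_bar: float) -> float:
    """Effective equilibrium magnetization M0csmt(W̄) of the reduced single pool.

    Steady-state (dMzm/dt = 0) form:
    M0csmt = [R1f·M0f + km·R1m·M0m/(R1m + km + W̄)] / R1csmt.
    Monotone non-increasing in W̄; tends to R1f·M0f/(R1f+kf) at full saturation.
    """
    if w_bar < 0:
        raise ValueError("w_bar must be >= 0")
    denom = p.r1_m + p.k_m + w_bar
    num = p.r1_f * p.m0_f + p.k_m * p.r1_m * p.m0_m / denom
    return num / r1_csmt(p, w_bar)


def r1_observed_ir(p: TwoPoolParameters) -> float:
    """Slow recovery rate measured by long-delay inversion recovery.

    The coupled longitudinal system relaxes bi-exponentially; long inversion
    delays sample the slower eigenvalue:

    R1obs = ½(R1f+kf+R1m+km) − ½·sqrt((R1f+kf+R1m+km)² − 4(R1f·R1m + R1f·km + R1m·kf))

    Even at vanishing RF power this differs from ``r1_csmt(p, 0)``: steady-state
    and inversion-recovery experiments sample different interactions of the same
    2-pool system.
    """
    a = p.r1_f + p.k_f
    b = p.r1_m + p.k_m
    disc = (a + b) ** 2 - 4.0 * (p.r1_f * p.r1_m + p.r1_f * p.k_m + p.r1_m * p.k_f)
    if disc < 0:
        raise ArithmeticError(
            "negative discriminant in bi-exponential rate (invalid parameters?)"
        )
    return 0.5 * (a + b) - 0.5 * math.sqrt(disc)
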