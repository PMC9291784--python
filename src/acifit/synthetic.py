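"""Synthetic A/Ci curves with matched PhiII traces.

Curves are generated from known parameters through the same forward model
the fitter inverts, so every downstream module is testable without
instrument data. The PhiII channel is built by *electron-demand inversion*:
at each point the electron transport the realized assimilation would
require,

    J_required = (A + RL) * (4*Cc + 8*Gamma*(1 + 2*alpha_g + alpha_s)) / (Cc - Gamma*),

capped at the curve's J (supply can't exceed capacity), is divided by
Qin * absorptance * beta_PSII to give PhiII. That reproduces the diagnostic
signature of real curves — PhiII rising over rubisco-limited points, flat
over RuBP-regeneration-limited points, declining over TPU-limited points —
while staying internally consistent with the gas-exchange channel.

Noise is Gaussian and homoscedastic on A (matching the unweighted SSR the
fitter minimises) and on PhiII; Ci is treated as an error-free regressor.
Named presets cover the measurement situations that matter for fitting:
a classic three-regime curve, a TPU-transition curve, a curve with no
RuBP-regeneration segment (rubisco hands over directly to TPU), a
subsaturating-light curve in which TPU never limits, and a TPU-free curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import temperature
from .fitting import ACiCurve, GasExchangePoint
from .fluorescence import DEFAULT_ABSORPTANCE, DEFAULT_BETA_PSII
from .model_core import LimitationState, PhotoParams, solve_point

__all__ = ["Scenario", "SimulationTruth", "generate_curve", "preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class Scenario:
    """Everything needed to simulate one curve."""

    truth: PhotoParams
    ci_min: float = 5.0      # Pa
    ci_max: float = 150.0    # Pa
    n: int = 15
    spacing: str = "geometric"  # or "linear"
    ci_grid: tuple[float, ...] | None = None  # explicit grid overrides min/max/n
    tleaf: float = 25.0
    qin: float = 1500.0
    o2: float = 21.0
    patm: float = 101.325
    noise_a: float = 0.3      # umol m-2 s-1
    noise_phi: float = 0.005  # unitless
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.noise_a < 0 or self.noise_phi < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.grid().size < 5:
            raise ValueError("need >= 5 Ci points")

    def grid(self) -> np.ndarray:
        if self.ci_grid is not None:
            return np.asarray(self.ci_grid, dtype=float)
        if self.spacing == "geometric":
            return np.geomspace(self.ci_min, self.ci_max, self.n)
        return np.linspace(self.ci_min, self.ci_max, self.n)


@dataclass
class SimulationTruth:
    """Ground truth carried alongside a generated curve."""

    params: PhotoParams
    states: list[LimitationState]
    a_true: list[float]
    cc_true: list[float]
    phi_true: list[float]
    sub_compensation: list[bool]

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {"vcmax": p.vcmax, "j": p.j, "tpu": p.tpu, "gm": p.gm,
                       "rl": p.rl, "alpha_g": p.alpha_g, "alpha_s": p.alpha_s},
            "states": [s.value for s in self.states],
            "a_true": self.a_true,
            "cc_true": self.cc_true,
            "phi_true": self.phi_true,
            "sub_compensation": self.sub_compensation,
        }


def generate_curve(s: Scenario) -> tuple[ACiCurve, SimulationTruth]:
    """Simulate one A/Ci curve (with PhiII) from a scenario.

    Deterministic under a fixed seed. Points whose true chloroplast CO2
    falls at or below the photocompensation point are marked
    sub-compensation in the truth record but still emitted.
    """
    rng = np.random.default_rng(s.seed)
    ci = s.grid()
    p = s.truth
    k = temperature.kinetics_at(s.tleaf, {"o2": s.o2})

    states: list[LimitationState] = []
    a_true: list[float] = []
    cc_true: list[float] = []
    phi_true: list[float] = []
    subcomp: list[bool] = []
    pts: list[GasExchangePoint] = []

    denom_phi = s.qin * DEFAULT_ABSORPTANCE * DEFAULT_BETA_PSII
    for c in ci:
        pred = solve_point(float(c), p, k)
        a, cc = pred.a, pred.cc
        states.append(pred.state)
        a_true.append(a)
        cc_true.append(cc)
        sub = cc <= k.gamma_star
        subcomp.append(bool(sub))
        if sub:
            j_req = 0.0
        else:
            j_req = (a + p.rl) * (4.0 * cc + 8.0 * k.gamma_star
                                  * (1.0 + 2.0 * p.alpha_g + p.alpha_s)) / (cc - k.gamma_star)
            j_req = min(max(j_req, 0.0), p.j)
        phi = j_req / denom_phi
        phi_true.append(phi)

        a_obs = a + (rng.normal(0.0, s.noise_a) if s.noise_a > 0 else 0.0)
        phi_obs = phi + (rng.normal(0.0, s.noise_phi) if s.noise_phi > 0 else 0.0)
        phi_obs = float(min(max(phi_obs, 0.0), 1.0))
        pts.append(GasExchangePoint(a_obs=float(a_obs), ci=float(c), tleaf=s.tleaf,
                                    qin=s.qin, phi_ps2=phi_obs, o2=s.o2, patm=s.patm))

    curve = ACiCurve(points=pts, id=f"sim_{s.name}_seed{s.seed}",
                     metadata={"preset": s.name, "seed": s.seed})
    truth = SimulationTruth(params=p, states=states, a_true=a_true,
                            cc_true=cc_true, phi_true=phi_true,
                            sub_compensation=subcomp)
    return curve, truth


_PRESETS: dict[str, Scenario] = {
    # rubisco -> RuBP regeneration -> TPU, comfortable segments of each
    "classic_three_regime": Scenario(
        truth=PhotoParams(vcmax=100.0, j=140.0, tpu=10.0, gm=10.0, rl=1.0),
        name="classic_three_regime"),
    # the reference recovery scenario: clear TPU plateau at the high-Ci end
    "tpu_transition": Scenario(
        truth=PhotoParams(vcmax=120.0, j=160.0, tpu=11.0, gm=8.0, rl=1.2),
        name="tpu_transition"),
    # high rubisco + electron-transport capacity, low TPU: rubisco hands over
    # directly to TPU with no RuBP-regeneration-limited window
    "no_j_segment": Scenario(
        truth=PhotoParams(vcmax=200.0, j=260.0, tpu=9.0, gm=8.0, rl=1.5),
        name="no_j_segment"),
    # high-but-not-saturating light: J low enough that 3*TPU exceeds J/4 and
    # TPU never becomes the operative limitation
    "subsaturating_light": Scenario(
        truth=PhotoParams(vcmax=120.0, j=110.0, tpu=12.0, gm=8.0, rl=1.2),
        qin=800.0, name="subsaturating_light"),
    # TPU absent from the truth entirely
    "no_tpu": Scenario(
        truth=PhotoParams(vcmax=120.0, j=160.0, tpu=None, gm=8.0, rl=1.2),
        name="no_tpu"),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str, seed: int | None = None, **overrides) -> Scenario:
    """A fully specified named scenario; unknown names raise with the menu."""
    try:
        s = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    if seed is not None:
        overrides["seed"] = seed
    return replace(s, **overrides) if overrides else s
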