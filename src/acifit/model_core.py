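"""Forward biochemical model of C3 leaf photosynthesis.

Net CO2 assimilation A is the minimum of three candidate rates, each tied to
a different limiting process:

* rubisco-limited carboxylation (Michaelis–Menten in chloroplast CO2),
* RuBP-regeneration-limited carboxylation (electron-transport supply J),
* triose phosphate utilization (TPU), the rate at which phosphorylated
  intermediates are converted to end products, releasing phosphate.

The RuBP-regeneration and TPU rates carry the glycine/serine export terms
``alpha_g`` and ``alpha_s`` — fractions of photorespiratory glycolate carbon
leaving the cycle — which make the TPU-limited rate CO2-sensitive (including
*reverse* sensitivity: A declining as CO2 rises).

All CO2 quantities are partial pressures in Pa; O2 in kPa; rates in
umol m-2 s-1. Chloroplast CO2 (Cc) relates to intercellular CO2 (Ci) through
a finite mesophyll conductance gm via Cc = Ci - A/gm; :func:`solve_point`
resolves that implicit coupling exactly (closed-form quadratic per candidate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


__all__ = [
    "LimitationState",
    "NOT_LIMITING",
    "KineticConstants",
    "PhotoParams",
    "ModelPrediction",
    "a_rubisco",
    "a_rubp_regen",
    "a_tpu",
    "a_min",
    "solve_point",
    "predict_curve",
]


class LimitationState(Enum):
    """Which process caps assimilation at a point."""

    RUBISCO = "rubisco"
    RUBP_REGEN = "rubp_regen"
    TPU_LIMITED = "tpu"


#: Tie-break priority: on exact ties the lower-Ci process wins.
STATE_PRIORITY = {
    LimitationState.RUBISCO: 0,
    LimitationState.RUBP_REGEN: 1,
    LimitationState.TPU_LIMITED: 2,
}

_STATE_ORDER = (
    LimitationState.RUBISCO,
    LimitationState.RUBP_REGEN,
    LimitationState.TPU_LIMITED,
)


class _NotLimiting:
    """Sentinel: the TPU expression has no admissible value at this Cc."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_LIMITING"


NOT_LIMITING = _NotLimiting()


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics and photocompensation point at leaf temperature.

    Parameters
    ----------
    gamma_star : CO2 photocompensation point, Pa.
    kc : Michaelis constant for CO2, Pa.
    ko : Michaelis constant for O2, kPa.
    o : chloroplast O2 partial pressure, kPa.
    tref : temperature the values refer to, degC.
    """

    gamma_star: float
    kc: float
    ko: float
    o: float
    tref: float = 25.0

    def __post_init__(self) -> None:
        for name in ("gamma_star", "kc", "ko", "o"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"KineticConstants.{name} must be finite and > 0, got {v}")

    @property
    def km_effective(self) -> float:
        """Effective Michaelis constant Kc*(1 + O/Ko), Pa; always > Kc."""
        return self.kc * (1.0 + self.o / self.ko)


@dataclass(frozen=True)
class PhotoParams:
    """Fittable photosynthesis parameters.

    ``tpu=None`` disables the TPU limitation entirely (the classical
    two-limitation model). ``gm=math.inf`` means no mesophyll resistance
    (Cc == Ci).
    """

    vcmax: float
    j: float
    tpu: float | None = None
    gm: float = math.inf
    rl: float = 0.0
    alpha_g: float = 0.0
    alpha_s: float = 0.0

    def __post_init__(self) -> None:
        if self.vcmax < 0 or self.j < 0 or self.rl < 0:
            raise ValueError("vcmax, j and rl must be >= 0")
        if self.tpu is not None and self.tpu < 0:
            raise ValueError("tpu must be >= 0 or None")
        if not self.gm > 0:
            raise ValueError("gm must be > 0 (math.inf allowed)")
        if self.alpha_g < 0 or self.alpha_s < 0 or self.alpha_g + self.alpha_s > 1 + 1e-9:
            raise ValueError("alphas must satisfy 0 <= alpha_g, alpha_s and alpha_g + alpha_s <= 1")


@dataclass
class ModelPrediction:
    """Model output at one point: net A, chloroplast CO2, operative limitation
    and the per-limitation candidate rates (``a_p`` may be None when TPU is
    disabled, or NOT_LIMITING where the TPU expression is inadmissible)."""

    a: float
    cc: float
    state: LimitationState | None
    a_c: float | None
    a_j: float | None
    a_p: object = None
    flag: str | None = None


def _check_cc(cc: float) -> None:
    if not (isinstance(cc, (int, float)) and math.isfinite(cc)) or cc <= 0:
        raise ValueError(f"Cc must be finite and > 0 Pa, got {cc!r}")


def a_rubisco(cc: float, p: PhotoParams, k: KineticConstants) -> float:
    """Rubisco-limited net assimilation at chloroplast CO2 ``cc`` (Pa).

    A_c = Vcmax*(Cc - Gamma*)/(Cc + Kc*(1 + O/Ko)) - RL
    """
    _check_cc(cc)
    return p.vcmax * (cc - k.gamma_star) / (cc + k.km_effective) - p.rl


def a_rubp_regen(cc: float, p: PhotoParams, k: KineticConstants) -> float:
    """RuBP-regeneration-limited net assimilation.

    A_j = J*(Cc - Gamma*)/(4*Cc + 8*Gamma*(1 + 2*alpha_g + alpha_s)) - RL

    With alpha_g = alpha_s = 0 this is the classical electron-transport
    limited rate J*(Cc - Gamma*)/(4Cc + 8Gamma*) - RL.
    """
    _check_cc(cc)
    den = 4.0 * cc + 8.0 * k.gamma_star * (1.0 + 2.0 * p.alpha_g + p.alpha_s)
    return p.j * (cc - k.gamma_star) / den - p.rl


def a_tpu(cc: float, p: PhotoParams, k: KineticConstants):
    """TPU-limited net assimilation, or NOT_LIMITING below the pole.

    A_p = 3*TPU*(Cc - Gamma*)/(Cc - Gamma*(1 + 3*alpha_g + 4*alpha_s)) - RL

    defined only where the denominator is positive. With both alphas zero the
    expression collapses to the flat line 3*TPU - RL; with glycine/serine
    export it declines as Cc rises (reverse CO2 sensitivity).
    """
    if p.tpu is None:
        raise ValueError("TPU disabled: PhotoParams.tpu is None")
    _check_cc(cc)
    den = cc - k.gamma_star * (1.0 + 3.0 * p.alpha_g + 4.0 * p.alpha_s)
    if den <= 0:
        return NOT_LIMITING
    return 3.0 * p.tpu * (cc - k.gamma_star) / den - p.rl


def a_min(cc: float, p: PhotoParams, k: KineticConstants) -> ModelPrediction:
    """Minimum-rule prediction at a known chloroplast CO2 (no gm coupling).

    NOT_LIMITING candidates are excluded; exact ties resolve to the
    lower-priority state (RUBISCO < RUBP_REGEN < TPU_LIMITED).
    """
    ac = a_rubisco(cc, p, k)
    aj = a_rubp_regen(cc, p, k)
    ap = a_tpu(cc, p, k) if p.tpu is not None else None

    candidates: list[tuple[float, int, LimitationState]] = [
        (ac, 0, LimitationState.RUBISCO),
        (aj, 1, LimitationState.RUBP_REGEN),
    ]
    if isinstance(ap, float):
        candidates.append((ap, 2, LimitationState.TPU_LIMITED))
    if not candidates:  # pragma: no cover - ac/aj always defined for cc > 0
        raise ValueError("no candidate rate defined")
    a, _, state = min(candidates, key=lambda t: (t[0], t[1]))
    return ModelPrediction(a=a, cc=cc, state=state, a_c=ac, a_j=aj, a_p=ap)


def _candidate_coeffs(state: LimitationState, p: PhotoParams, k: KineticConstants):
    """Coefficients of A + RL = (ns*Cc + nc)/(ds*Cc + dc) for one candidate."""
    g = k.gamma_star
    if state is LimitationState.RUBISCO:
        return p.vcmax, -p.vcmax * g, 1.0, k.km_effective
    if state is LimitationState.RUBP_REGEN:
        return p.j, -p.j * g, 4.0, 8.0 * g * (1.0 + 2.0 * p.alpha_g + p.alpha_s)
    if p.tpu is None:
        return None
    return 3.0 * p.tpu, -3.0 * p.tpu * g, 1.0, -g * (1.0 + 3.0 * p.alpha_g + 4.0 * p.alpha_s)


def _solve_candidate(state: LimitationState, ci: float, p: PhotoParams,
                     k: KineticConstants) -> tuple[float, float] | None:
    """Self-consistent (A, Cc) for one candidate under Cc = Ci - A/gm.

    Returns None where the candidate has no admissible root (TPU below its
    pole, or no root with Cc > 0).
    """
    coeffs = _candidate_coeffs(state, p, k)
    if coeffs is None:
        return None
    ns, nc, ds, dc = coeffs
    g = p.gm
    if math.isinf(g):
        den = ds * ci + dc
        if den <= 0:
            return None
        return (ns * ci + nc) / den - p.rl, ci

    # substitute Cc = Ci - A/gm, x = A + RL: quadratic qa*x^2 + qb*x + qc = 0
    c0 = ci + p.rl / g
    qa = ds / g
    qb = -(ds * c0 + dc + ns / g)
    qc = ns * c0 + nc
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    # numerically stable root pair (qa can be tiny at large gm)
    q = -0.5 * (qb + math.copysign(sq, qb)) if qb != 0 else 0.5 * sq
    roots: list[float] = []
    if qa != 0 and q != 0:
        roots = sorted({q / qa, qc / q})
    elif q != 0:
        roots = [qc / q]
    elif qa != 0:
        roots = [0.0]
    for x in roots:  # ascending: the physical branch is the smaller root
        a = x - p.rl
        cc = ci - a / g
        if cc > 0 and (ds * cc + dc) > 0:
            return a, cc
    return None


def solve_point(ci: float, p: PhotoParams, k: KineticConstants) -> ModelPrediction:
    """Predict (A, Cc, limitation) at intercellular CO2 ``ci`` (Pa).

    Each candidate limitation is solved self-consistently with the mesophyll
    diffusion constraint Cc = Ci - A/gm; the operative limitation is the one
    whose self-consistent A is smallest (ties break toward RUBISCO).
    """
    if not (isinstance(ci, (int, float)) and math.isfinite(ci)) or ci <= 0:
        raise ValueError(f"Ci must be finite and > 0 Pa, got {ci!r}")

    sols: dict[LimitationState, tuple[float, float] | None] = {
        s: _solve_candidate(s, ci, p, k) for s in _STATE_ORDER
    }
    rc, rj = sols[LimitationState.RUBISCO], sols[LimitationState.RUBP_REGEN]
    rp = sols[LimitationState.TPU_LIMITED]

    a_c = rc[0] if rc else None
    a_j = rj[0] if rj else None
    if p.tpu is None:
        a_p: object = None
    else:
        a_p = rp[0] if rp else NOT_LIMITING

    defined = [(sols[s][0], STATE_PRIORITY[s], s) for s in _STATE_ORDER if sols[s] is not None]
    if rc is None or rj is None:
        # rubisco/RuBP roots exist for any Ci > 0 under valid params; reaching
        # here means the point is physically inadmissible — flag, don't hide.
        return ModelPrediction(a=math.nan, cc=math.nan, state=None, a_c=a_c,
                               a_j=a_j, a_p=a_p, flag="no_admissible_root")
    a, _, state = min(defined, key=lambda t: (t[0], t[1]))
    cc = sols[state][1]
    return ModelPrediction(a=a, cc=cc, state=state, a_c=a_c, a_j=a_j, a_p=a_p)


def predict_curve(
    ci_values: Sequence[float],
    p: PhotoParams,
    k: KineticConstants | Sequence[KineticConstants],
) -> list[ModelPrediction]:
    """Elementwise :func:`solve_point` over a Ci vector.

    ``k`` may be a single constant set or one per point (e.g. when leaf
    temperature varies along the curve).
    """
    ci_values = list(ci_values)
    if isinstance(k, KineticConstants):
        ks: Sequence[KineticConstants] = [k] * len(ci_values)
    else:
        ks = list(k)
        if len(ks) != len(ci_values):
            raise ValueError("need one KineticConstants per Ci value")
    return [solve_point(ci, p, kk) for ci, kk in zip(ci_values, ks)]
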