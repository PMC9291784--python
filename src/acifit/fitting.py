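"""Estimate photosynthesis parameters from A/Ci curves.

The estimation problem has latent per-point limitation states: which of the
three candidate processes (rubisco carboxylation, RuBP regeneration, TPU)
caps assimilation at each measured Ci is unknown a priori. The fitter
alternates

1. bounded nonlinear least squares on sum((A_obs - A_model)^2), where each
   point's A_model uses its currently assigned limitation, solved
   self-consistently with the mesophyll diffusion constraint Cc = Ci - A/gm;
2. reassignment of every point to the limitation whose self-consistent rate
   is smallest under the updated parameters,

until the assignment is stable. Because the piecewise objective has local
minima, several seeded multistarts jitter the initial guess and the
lowest-SSR result wins. Any parameter can be fixed (e.g. gm and RL measured
independently), and the whole TPU branch (TPU, alpha_g, alpha_s) can be
excluded to fit the classical two-limitation model; :func:`compare_fits`
reports the SSR reduction and a nested-model F statistic between the two
variants.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from . import temperature
from .model_core import (
    NOT_LIMITING,
    KineticConstants,
    LimitationState,
    PhotoParams,
    solve_point,
)

__all__ = [
    "GasExchangePoint",
    "ACiCurve",
    "FitOptions",
    "FitResult",
    "FitComparison",
    "DEFAULT_BOUNDS",
    "initial_guess",
    "assign_limitations",
    "fit_curve",
    "compare_fits",
    "bootstrap_uncertainty",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("vcmax", "j", "tpu", "gm", "rl", "alpha_g", "alpha_s")

DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "vcmax": (0.0, 1000.0),
    "j": (0.0, 1000.0),
    "tpu": (0.0, 200.0),
    "gm": (0.05, 100.0),
    "rl": (0.0, 10.0),
    "alpha_g": (0.0, 1.0),
    "alpha_s": (0.0, 1.0),
}

_STATE_TO_INDEX = {
    LimitationState.RUBISCO: 0,
    LimitationState.RUBP_REGEN: 1,
    LimitationState.TPU_LIMITED: 2,
}
_INDEX_TO_STATE = {v: k for k, v in _STATE_TO_INDEX.items()}

_ALPHA_PENALTY = 1e3


@dataclass(frozen=True)
class GasExchangePoint:
    """One steady-state gas-exchange measurement."""

    a_obs: float          # net assimilation, umol m-2 s-1 (negative legal)
    ci: float             # intercellular CO2, Pa
    tleaf: float = 25.0   # leaf temperature, degC
    qin: float = 1500.0   # incident PPFD, umol m-2 s-1
    phi_ps2: float | None = None  # PSII quantum yield, unitless in [0, 1]
    o2: float = 21.0      # O2 partial pressure, kPa
    patm: float = 101.325  # atmospheric pressure, kPa

    def __post_init__(self) -> None:
        if not self.ci > 0:
            raise ValueError(f"Ci must be > 0 Pa, got {self.ci}")
        if not self.patm > 0:
            raise ValueError("Patm must be > 0 kPa")
        if self.phi_ps2 is not None and not 0.0 <= self.phi_ps2 <= 1.0:
            raise ValueError("PhiPS2 must lie in [0, 1]")


@dataclass
class ACiCurve:
    """An ordered A/Ci curve: the unit of fitting."""

    points: list[GasExchangePoint]
    id: str = "curve"
    metadata: dict = field(default_factory=dict)

    def sorted_by_ci(self) -> "ACiCurve":
        order = sorted(range(len(self.points)), key=lambda i: self.points[i].ci)
        if order == list(range(len(self.points))):
            return self
        meta = dict(self.metadata)
        meta.setdefault("source_order", order)
        return ACiCurve(points=[self.points[i] for i in order], id=self.id, metadata=meta)

    def ci_array(self) -> np.ndarray:
        return np.array([pt.ci for pt in self.points], dtype=float)

    def a_array(self) -> np.ndarray:
        return np.array([pt.a_obs for pt in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class FitOptions:
    """Controls for :func:`fit_curve`."""

    include_tpu: bool = True
    fixed: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    multistart_n: int = 10
    rng_seed: int = 0
    max_assign_iter: int = 50
    ssr_rel_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.multistart_n < 1:
            raise ValueError("multistart_n must be >= 1")
        if not self.ssr_rel_tol > 0:
            raise ValueError("ssr_rel_tol must be > 0")
        bad = set(self.fixed) - set(PARAM_NAMES)
        if bad:
            raise ValueError(f"unknown fixed parameter(s): {sorted(bad)}")

    def free_names(self) -> tuple[str, ...]:
        names = list(PARAM_NAMES)
        if not self.include_tpu:
            names = [n for n in names if n not in ("tpu", "alpha_g", "alpha_s")]
        return tuple(n for n in names if n not in self.fixed)


@dataclass
class FitResult:
    """Point estimates plus per-point limitation states and diagnostics."""

    params: PhotoParams
    states: list[LimitationState]
    ssr: float
    n_assign_iter: int
    converged: bool
    residuals: np.ndarray
    n_points: int
    free_names: tuple[str, ...]
    fixed: dict[str, float]
    flags: list[str] = field(default_factory=list)
    bootstrap: dict[str, tuple[float, float]] | None = None

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {
                "vcmax": p.vcmax, "j": p.j, "tpu": p.tpu, "gm": p.gm,
                "rl": p.rl, "alpha_g": p.alpha_g, "alpha_s": p.alpha_s,
            },
            "states": [s.value for s in self.states],
            "ssr": self.ssr,
            "n_assign_iter": self.n_assign_iter,
            "converged": self.converged,
            "residuals": [float(r) for r in self.residuals],
            "n_points": self.n_points,
            "free_names": list(self.free_names),
            "fixed": dict(self.fixed),
            "flags": list(self.flags),
            "bootstrap": (
                {k: [lo, hi] for k, (lo, hi) in self.bootstrap.items()}
                if self.bootstrap is not None else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        prm = d["params"]
        gm = prm["gm"]
        return cls(
            params=PhotoParams(
                vcmax=prm["vcmax"], j=prm["j"], tpu=prm["tpu"],
                gm=math.inf if gm in (None, "inf") else float(gm),
                rl=prm["rl"], alpha_g=prm["alpha_g"], alpha_s=prm["alpha_s"],
            ),
            states=[LimitationState(s) for s in d["states"]],
            ssr=d["ssr"],
            n_assign_iter=d["n_assign_iter"],
            converged=d["converged"],
            residuals=np.array(d["residuals"], dtype=float),
            n_points=d["n_points"],
            free_names=tuple(d["free_names"]),
            fixed=dict(d["fixed"]),
            flags=list(d["flags"]),
            bootstrap=(
                {k: (v[0], v[1]) for k, v in d["bootstrap"].items()}
                if d.get("bootstrap") is not None else None
            ),
        )

    def summary_json(self) -> str:
        """Canonical JSON form (used for determinism checks)."""
        return json.dumps(self.to_dict(), sort_keys=True)


@dataclass
class FitComparison:
    """Nested-model comparison of without-TPU vs with-TPU fits."""

    ssr_without: float
    ssr_with: float
    delta_ssr: float
    pct_reduction: float
    delta_free_params: int
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


# ---------------------------------------------------------------------------
# vectorized self-consistent candidate rates (fast path used inside fitting)

def _candidate_matrix(ci: np.ndarray, p: PhotoParams, gs: np.ndarray,
                      km: np.ndarray) -> np.ndarray:
    """(3, n) self-consistent candidate A values; NaN where inadmissible.

    Row order: rubisco, RuBP regeneration, TPU. Mirrors
    :func:`acifit.model_core._solve_candidate` but vectorized over points.
    """
    n = ci.size
    m = 3 if p.tpu is not None else 2
    rates = np.empty((m, 1))
    rates[0, 0], rates[1, 0] = p.vcmax, p.j
    ds = np.empty((m, 1))
    ds[0, 0], ds[1, 0] = 1.0, 4.0
    dc = np.empty((m, n))
    dc[0] = km
    dc[1] = 8.0 * gs * (1.0 + 2.0 * p.alpha_g + p.alpha_s)
    if m == 3:
        rates[2, 0] = 3.0 * p.tpu
        ds[2, 0] = 1.0
        dc[2] = -gs * (1.0 + 3.0 * p.alpha_g + 4.0 * p.alpha_s)
    ns = np.broadcast_to(rates, (m, n))
    nc = -rates * gs  # broadcasts to (m, n)

    g = p.gm
    if math.isinf(g):
        den = ds * ci + dc
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (ns * ci + nc) / den - p.rl
        a[den <= 0] = np.nan
        out = np.full((3, n), np.nan)
        out[:m] = a
        return out

    c0 = ci + p.rl / g
    qa = ds / g
    qb = -(ds * c0 + dc + ns / g)
    qc = ns * c0 + nc
    disc = qb * qb - 4.0 * qa * qc
    valid = disc >= 0
    sq = np.sqrt(np.where(valid, disc, 0.0))
    q = np.where(qb == 0, 0.5 * sq, -0.5 * (qb + np.sign(qb) * sq))
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(q != 0, qc / q, 0.0)     # stable small root
        r2 = np.where(qa != 0, q / qa, np.inf)  # large root
    res = np.full((m, n), np.nan)
    for x in (np.minimum(r1, r2), np.maximum(r1, r2)):
        a = x - p.rl
        cc = ci - a / g
        ok = valid & np.isnan(res) & (cc > 0) & (ds * cc + dc > 0) & np.isfinite(a)
        res[ok] = a[ok]
    out = np.full((3, n), np.nan)
    out[:m] = res
    return out


def _assign_from_matrix(cand: np.ndarray) -> np.ndarray:
    """argmin over candidate rows with NaN excluded; ties -> lowest row index."""
    masked = np.where(np.isnan(cand), np.inf, cand)
    return np.argmin(masked, axis=0)


def _model_for_states(cand: np.ndarray, states_idx: np.ndarray) -> np.ndarray:
    """Assigned-candidate A per point; inadmissible assignments fall back to
    the minimum over the remaining candidates (keeps the objective finite
    while the optimizer wanders through inadmissible corners)."""
    n = cand.shape[1]
    a = cand[states_idx, np.arange(n)]
    bad = np.isnan(a)
    if bad.any():
        a[bad] = np.where(np.isnan(cand), np.inf, cand)[:, bad].min(axis=0)
        a[~np.isfinite(a)] = -1e3  # every candidate inadmissible: huge misfit
    return a


def _kinetics_arrays(curve: ACiCurve, config: Mapping[str, float] | None):
    """Per-point (gamma_star, km_effective) plus the KineticConstants list.

    Each point's own O2 enters Km_effective; Gamma* and the Michaelis
    constants come from the (temperature-scaled) config.
    """
    ks = []
    for pt in curve.points:
        base = temperature.kinetics_at(pt.tleaf, config)
        ks.append(KineticConstants(gamma_star=base.gamma_star, kc=base.kc,
                                   ko=base.ko, o=pt.o2, tref=pt.tleaf))
    gs = np.array([k.gamma_star for k in ks])
    km = np.array([k.km_effective for k in ks])
    return gs, km, ks


# ---------------------------------------------------------------------------
# public operations

def initial_guess(curve: ACiCurve, opts: FitOptions,
                  config: Mapping[str, float] | None = None) -> PhotoParams:
    """Heuristic starting parameters, clipped to the fitting bounds.

    Vcmax from a one-substrate Michaelis-Menten fit to the lowest-Ci third
    (Cc approximated by Ci), J from 1.1*4*(A_max + RL_guess), TPU from
    (A_max + RL_guess)/3; gm starts at 5 umol m-2 s-1 Pa-1, RL at 1, alphas
    at 0.
    """
    if len(curve) < 5:
        raise ValueError(f"need >= 5 points to fit, got {len(curve)}")
    curve = curve.sorted_by_ci()
    gs, km, _ = _kinetics_arrays(curve, config)
    ci = curve.ci_array()
    a = curve.a_array()
    rl0 = 1.0

    n_low = max(3, len(curve) // 3)
    f = (ci[:n_low] - gs[:n_low]) / (ci[:n_low] + km[:n_low])
    keep = f > 0
    denom = float(np.sum(f[keep] ** 2))
    if denom > 1e-12:
        vc = float(np.sum((a[:n_low][keep] + rl0) * f[keep]) / denom)
    else:
        vc = 100.0  # degenerate low-Ci data: fall back to a mid-range default
    if not math.isfinite(vc) or vc <= 0:
        vc = 100.0

    amax = float(np.max(a))
    j0 = 1.1 * 4.0 * (amax + rl0)
    tpu0 = (amax + rl0) / 3.0

    b = opts.bounds
    def clip(name: str, v: float) -> float:
        lo, hi = b.get(name, DEFAULT_BOUNDS[name])
        return float(min(max(v, lo if lo > 0 else max(lo, 1e-6)), hi))

    guess = PhotoParams(
        vcmax=clip("vcmax", vc),
        j=clip("j", max(j0, 1e-6)),
        tpu=clip("tpu", max(tpu0, 1e-6)) if opts.include_tpu else None,
        gm=clip("gm", 5.0),
        rl=min(max(1.0, b.get("rl", DEFAULT_BOUNDS["rl"])[0]), b.get("rl", DEFAULT_BOUNDS["rl"])[1]),
        alpha_g=0.0,
        alpha_s=0.0,
    )
    # fixed parameters override the heuristic outright
    return _apply_fixed(guess, opts)


def _apply_fixed(p: PhotoParams, opts: FitOptions) -> PhotoParams:
    updates = {}
    for name, val in opts.fixed.items():
        if name == "tpu" and not opts.include_tpu:
            continue
        updates[name] = val
    if not opts.include_tpu:
        updates["tpu"] = None
        updates["alpha_g"] = 0.0
        updates["alpha_s"] = 0.0
    return replace(p, **updates) if updates else p


def assign_limitations(curve: ACiCurve, params: PhotoParams,
                       kinetics: KineticConstants | Sequence[KineticConstants]) -> list[LimitationState]:
    """Per-point operative limitation under ``params`` (argmin of the
    self-consistent candidate rates, RUBISCO-first tie-break)."""
    if isinstance(kinetics, KineticConstants):
        kinetics = [kinetics] * len(curve)
    gs = np.array([k.gamma_star for k in kinetics])
    km = np.array([k.km_effective for k in kinetics])
    cand = _candidate_matrix(curve.ci_array(), params, gs, km)
    return [_INDEX_TO_STATE[i] for i in _assign_from_matrix(cand)]


def _pack(p: PhotoParams, free: tuple[str, ...]) -> np.ndarray:
    d = {"vcmax": p.vcmax, "j": p.j, "tpu": p.tpu, "gm": p.gm, "rl": p.rl,
         "alpha_g": p.alpha_g, "alpha_s": p.alpha_s}
    return np.array([d[n] for n in free], dtype=float)


def _unpack(theta: np.ndarray, template: PhotoParams, free: tuple[str, ...],
            include_tpu: bool) -> PhotoParams:
    d = {n: float(v) for n, v in zip(free, theta)}
    if "alpha_g" in d or "alpha_s" in d:
        ag = d.get("alpha_g", template.alpha_g)
        as_ = d.get("alpha_s", template.alpha_s)
        tot = ag + as_
        if tot > 1.0:  # keep PhotoParams constructible; penalty steers back
            d["alpha_g"], d["alpha_s"] = ag / tot, as_ / tot
    p = replace(template, **d)
    if not include_tpu and p.tpu is not None:
        p = replace(p, tpu=None)
    return p


def _fit_given_start(curve: ACiCurve, p0: PhotoParams, opts: FitOptions,
                     gs: np.ndarray, km: np.ndarray):
    ci = curve.ci_array()
    a_obs = curve.a_array()
    free = opts.free_names()
    lo = np.array([opts.bounds.get(n, DEFAULT_BOUNDS[n])[0] for n in free])
    hi = np.array([opts.bounds.get(n, DEFAULT_BOUNDS[n])[1] for n in free])

    def residuals_for(p: PhotoParams, sidx: np.ndarray) -> np.ndarray:
        cand = _candidate_matrix(ci, p, gs, km)
        return a_obs - _model_for_states(cand, sidx)

    def objective(theta: np.ndarray, sidx: np.ndarray) -> np.ndarray:
        p = _unpack(theta, p0, free, opts.include_tpu)
        r = residuals_for(p, sidx)
        # raw (pre-normalisation) alpha sum drives the simplex penalty
        d = dict(zip(free, theta))
        ag = d.get("alpha_g", p0.alpha_g)
        as_ = d.get("alpha_s", p0.alpha_s)
        pen = _ALPHA_PENALTY * max(0.0, float(ag + as_) - 1.0)
        return np.append(r, pen)

    p = p0
    states = _assign_from_matrix(_candidate_matrix(ci, p, gs, km))
    prev: list[tuple[np.ndarray, float, PhotoParams, np.ndarray]] = []
    converged = False
    n_iter = 0
    ssr = float(np.sum(residuals_for(p, states) ** 2))
    r = residuals_for(p, states)
    for n_iter in range(1, opts.max_assign_iter + 1):
        theta0 = np.clip(_pack(p, free), lo, hi)
        if free:
            sol = least_squares(objective, theta0, bounds=(lo, hi), args=(states,),
                                method="trf", x_scale="jac")
            p = _unpack(sol.x, p0, free, opts.include_tpu)
        r = residuals_for(p, states)
        ssr = float(r @ r)
        new_states = _assign_from_matrix(_candidate_matrix(ci, p, gs, km))
        if np.array_equal(new_states, states):
            converged = True
            break
        if len(prev) >= 2 and np.array_equal(new_states, prev[-2][0]):
            # period-2 assignment cycle: accept the lower-SSR iterate
            if prev[-1][1] < ssr:
                states, ssr, p, r = prev[-1]
            converged = True
            break
        prev.append((states, ssr, p, r))
        states = new_states
    return p, states, ssr, r, n_iter, converged


def fit_curve(curve: ACiCurve, opts: FitOptions | None = None,
              config: Mapping[str, float] | None = None,
              initial: PhotoParams | None = None) -> FitResult:
    """Fit an A/Ci curve by iterative limitation assignment and bounded
    nonlinear least squares.

    ``initial`` overrides the heuristic starting point (used by the
    bootstrap); multistarts jitter whichever start is in effect.
    """
    opts = opts or FitOptions()
    if len(curve) < 5:
        raise ValueError(f"need >= 5 points to fit, got {len(curve)}")
    curve = curve.sorted_by_ci()
    gs, km, _ = _kinetics_arrays(curve, config)

    base = initial if initial is not None else initial_guess(curve, opts, config)
    base = _apply_fixed(base, opts)
    free = opts.free_names()
    rng = np.random.default_rng(opts.rng_seed)

    # restarts cover the gm axis deterministically: the SSR surface is nearly
    # flat along gm, and basins of attraction in gm are narrow, so random
    # x2 jitter around one start misses the global minimum too often
    if "gm" in free and opts.multistart_n > 1:
        lo_gm = max(opts.bounds.get("gm", DEFAULT_BOUNDS["gm"])[0], 0.5)
        hi_gm = min(opts.bounds.get("gm", DEFAULT_BOUNDS["gm"])[1], 60.0)
        gm_ladder = np.geomspace(lo_gm, hi_gm, opts.multistart_n - 1)
    else:
        gm_ladder = None

    best = None
    for m in range(opts.multistart_n):
        p0 = base
        if m > 0:
            # alternate between jittered and plain-heuristic starts so a bad
            # joint jitter cannot poison the whole gm ladder
            p0 = _jitter(base, free, opts, rng) if m % 2 else base
            if gm_ladder is not None:
                p0 = replace(p0, gm=float(gm_ladder[m - 1]))
        try:
            p, sidx, ssr, r, n_iter, conv = _fit_given_start(curve, p0, opts, gs, km)
        except Exception:  # a pathological start must not sink the fit
            logger.exception("multistart %d failed for curve %s", m, curve.id)
            continue
        if best is None or ssr < best[2]:
            best = (p, sidx, ssr, r, n_iter, conv)
    if best is None:
        raise RuntimeError(f"all {opts.multistart_n} starts failed for curve {curve.id}")
    p, sidx, ssr, r, n_iter, conv = best

    states = [_INDEX_TO_STATE[i] for i in sidx]
    flags: list[str] = []
    if not conv:
        logger.warning("curve %s: assignment did not stabilise in %d iterations",
                       curve.id, opts.max_assign_iter)
    counts = {s: states.count(s) for s in LimitationState}
    exclusive = {
        LimitationState.RUBISCO: ("vcmax",),
        LimitationState.RUBP_REGEN: ("j",),
        LimitationState.TPU_LIMITED: ("tpu", "alpha_g", "alpha_s"),
    }
    for s, names in exclusive.items():
        if s is LimitationState.TPU_LIMITED and not opts.include_tpu:
            continue
        if counts[s] < 2:
            for nm in names:
                if nm in free:
                    flags.append(f"{nm}_underdetermined")
    if len(set(states)) == 1:
        flags.append("single_limitation")

    return FitResult(
        params=p, states=states, ssr=ssr, n_assign_iter=n_iter, converged=conv,
        residuals=r, n_points=len(curve), free_names=free,
        fixed=dict(opts.fixed), flags=flags,
    )


def _jitter(base: PhotoParams, free: tuple[str, ...], opts: FitOptions,
            rng: np.random.Generator) -> PhotoParams:
    """Seeded log-uniform jitter on free rate parameters (x / up to 2; up to
    4 for gm, whose basin of attraction is narrow); additive uniform jitter
    for the alphas (which start at zero)."""
    updates: dict[str, float] = {}
    vals = {"vcmax": base.vcmax, "j": base.j, "tpu": base.tpu, "gm": base.gm,
            "rl": base.rl, "alpha_g": base.alpha_g, "alpha_s": base.alpha_s}
    for name in free:
        lo, hi = opts.bounds.get(name, DEFAULT_BOUNDS[name])
        if name in ("alpha_g", "alpha_s"):
            v = vals[name] + rng.uniform(0.0, 0.15)
        else:
            span = math.log(4) if name == "gm" else math.log(2)
            v = (vals[name] if vals[name] else 1.0) * math.exp(rng.uniform(-span, span))
        updates[name] = float(min(max(v, lo), hi))
    if "alpha_g" in updates or "alpha_s" in updates:
        ag = updates.get("alpha_g", base.alpha_g)
        as_ = updates.get("alpha_s", base.alpha_s)
        if ag + as_ > 1.0:
            updates["alpha_g"], updates["alpha_s"] = ag / (ag + as_), as_ / (ag + as_)
    return replace(base, **updates)


def compare_fits(without: FitResult, with_tpu: FitResult) -> FitComparison:
    """SSR reduction and nested-model F statistic for adding the TPU branch.

    F = (dSSR/dp) / (SSR_with/(n - p_with)); the statistic and its degrees of
    freedom are reported, not thresholded — residuals on a segmented model
    are only approximately the classical nested-regression setting.
    """
    ssr0, ssr1 = without.ssr, with_tpu.ssr
    delta = ssr0 - ssr1
    pct = 100.0 * (1.0 - ssr1 / ssr0) if ssr0 > 0 else 0.0
    dp = len(with_tpu.free_names) - len(without.free_names)
    df_den = with_tpu.n_points - len(with_tpu.free_names)
    if dp > 0 and df_den > 0 and ssr1 > 0:
        f_stat = (delta / dp) / (ssr1 / df_den)
        p_value = float(f_dist.sf(f_stat, dp, df_den))
    else:
        f_stat, p_value = math.nan, math.nan
    return FitComparison(
        ssr_without=ssr0, ssr_with=ssr1, delta_ssr=delta, pct_reduction=pct,
        delta_free_params=dp, f_stat=f_stat, df_num=dp, df_den=df_den,
        p_value=p_value,
    )


def bootstrap_uncertainty(curve: ACiCurve, opts: FitOptions, b: int, seed: int,
                          config: Mapping[str, float] | None = None
                          ) -> dict[str, tuple[float, float]]:
    """Residual-bootstrap 95% percentile intervals for the free parameters.

    Residuals from the point fit are resampled with replacement onto the
    fitted curve and each replicate is refitted from the point estimate
    (single start — replicates stay near the original optimum).
    """
    if b == 0:
        return {}
    base = fit_curve(curve, opts, config)
    fitted = curve.sorted_by_ci().a_array() - base.residuals
    pts = curve.sorted_by_ci().points
    rng = np.random.default_rng(seed)
    refit_opts = replace(opts, multistart_n=1)
    draws: dict[str, list[float]] = {n: [] for n in opts.free_names()}
    for _ in range(b):
        res = base.residuals[rng.integers(0, len(pts), len(pts))]
        new_pts = [replace(pt, a_obs=float(fv + rv))
                   for pt, fv, rv in zip(pts, fitted, res)]
        rep = fit_curve(ACiCurve(new_pts, id=curve.id), refit_opts, config,
                        initial=base.params)
        vals = {"vcmax": rep.params.vcmax, "j": rep.params.j, "tpu": rep.params.tpu,
                "gm": rep.params.gm, "rl": rep.params.rl,
                "alpha_g": rep.params.alpha_g, "alpha_s": rep.params.alpha_s}
        for n in draws:
            draws[n].append(vals[n])
    return {n: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for n, v in draws.items()}
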