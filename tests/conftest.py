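"""Shared fixtures and the independent root-finding oracle.

The oracle solves the mesophyll-diffusion coupling Cc = Ci - A/gm for each
candidate limitation by bracketed bisection on f(A) = candidate(Ci - A/gm) - A,
deliberately avoiding the closed-form quadratic used by the implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from acifit.model_core import (
    NOT_LIMITING,
    KineticConstants,
    LimitationState,
    PhotoParams,
    a_rubisco,
    a_rubp_regen,
    a_tpu,
)


BERNACCHI_25 = KineticConstants(gamma_star=4.275, kc=40.49, ko=27.84, o=21.0)


@pytest.fixture
def kinetics_25() -> KineticConstants:
    return BERNACCHI_25


def _candidate_at(state: LimitationState, cc: float, p: PhotoParams,
                  k: KineticConstants) -> float | None:
    if cc <= 0:
        return None
    if state is LimitationState.RUBISCO:
        return a_rubisco(cc, p, k)
    if state is LimitationState.RUBP_REGEN:
        return a_rubp_regen(cc, p, k)
    if p.tpu is None:
        return None
    v = a_tpu(cc, p, k)
    return None if v is NOT_LIMITING else v


def bisect_candidate(state: LimitationState, ci: float, p: PhotoParams,
                     k: KineticConstants, tol: float = 1e-12) -> float | None:
    """Self-consistent A for one candidate by scan + bisection; None if no
    admissible root in the physical bracket."""
    if math.isinf(p.gm):
        return _candidate_at(state, ci, p, k)

    def f(a: float) -> float | None:
        v = _candidate_at(state, ci - a / p.gm, p, k)
        return None if v is None else v - a

    a_hi = min(p.vcmax, p.j / 4.0, (3.0 * p.tpu * 10.0) if p.tpu is not None else math.inf)
    # lower bracket must sit below every candidate's Cc->0 limit, which can
    # fall well under -RL at sub-compensation Ci with strong alpha export
    a_lo = -p.rl - 1.0 - max(5.0, p.j / 8.0, p.vcmax * k.gamma_star / k.km_effective)
    grid = np.linspace(a_lo, a_hi + 1.0, 400)
    vals = [f(a) for a in grid]
    for i in range(len(grid) - 1):
        va, vb = vals[i], vals[i + 1]
        if va is None or vb is None or va * vb > 0:
            continue
        a, b = grid[i], grid[i + 1]
        fa = va
        for _ in range(200):
            m = 0.5 * (a + b)
            fm = f(m)
            if fm is None:
                break
            if fa * fm <= 0:
                b = m
            else:
                a, fa = m, fm
            if b - a < tol:
                break
        else:
            return 0.5 * (a + b)
        if fm is not None:
            return 0.5 * (a + b)
    return None


def bisect_solve(ci: float, p: PhotoParams, k: KineticConstants) -> tuple[float, LimitationState]:
    """Oracle counterpart of solve_point: per-candidate bisection, then the
    minimum with RUBISCO-first tie-break."""
    best = None
    for prio, state in enumerate((LimitationState.RUBISCO, LimitationState.RUBP_REGEN,
                                  LimitationState.TPU_LIMITED)):
        a = bisect_candidate(state, ci, p, k)
        if a is None:
            continue
        if best is None or (a, prio) < (best[0], best[2]):
            best = (a, state, prio)
    assert best is not None, "oracle found no admissible candidate"
    return best[0], best[1]


def random_params(rng: np.random.Generator, with_tpu: bool = True) -> PhotoParams:
    """A random admissible parameter draw within the fitting bounds."""
    ag = rng.uniform(0.0, 0.5)
    as_ = rng.uniform(0.0, min(0.5, 1.0 - ag))
    return PhotoParams(
        vcmax=rng.uniform(20.0, 300.0),
        j=rng.uniform(20.0, 400.0),
        tpu=rng.uniform(3.0, 30.0) if with_tpu else None,
        gm=rng.uniform(0.5, 50.0),
        rl=rng.uniform(0.0, 5.0),
        alpha_g=ag,
        alpha_s=as_,
    )
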