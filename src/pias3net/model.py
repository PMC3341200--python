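"""State space, mass-action right-hand side and integration services.

The network couples two kinase arms through a shared inhibitor:

* the MAPK arm -- phospho-ERK (an input held piecewise constant)
  phosphorylates MITF at S73 and activates RSK1, which phosphorylates
  MITF at S409;
* the JAK-STAT arm -- phospho-JAK (the second input) phosphorylates
  STAT3 at Y705.

PIAS3 binds the four MITF phospho-forms (each with its own affinity) and
phosphorylated STAT3.  Free MITF species, PIAS3, STAT3 forms and the five
PIAS3 complexes give 14 molecular species; a 15th state variable ``R``
tracks the fraction of S73-phosphorylated MITF that is ubiquitinated and
thereby exposed to proteasomal degradation.

All amounts are in arbitrary units (au), time in minutes.  Complexes
degrade at 20% of the mean of their constituents' free degradation rates;
the S73-phosphorylated species (free and in complex) contribute their
degradation only in proportion to ``R``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .params import CoreParameters

__all__ = [
    "STATE_NAMES",
    "SIdx",
    "InputSchedule",
    "Trajectory",
    "SolverError",
    "SolverSettings",
    "ubiquitination_terms",
    "ubiquitination_rate",
    "rhs",
    "simulate",
    "find_steady_state",
    "default_initial_state",
    "total_mitf",
    "phospho_mitf",
    "unphospho_mitf",
    "mitf_pias3_complex",
    "total_pias3",
    "total_stat3",
]

#: The 15 dynamical quantities: 14 species amounts (au) plus the
#: dimensionless ubiquitinated fraction R.
STATE_NAMES: tuple[str, ...] = (
    "MITF",
    "MITFp73",
    "MITFp409",
    "MITFpp",
    "PIAS3",
    "PIAS3_MITF",
    "PIAS3_MITFp73",
    "PIAS3_MITFp409",
    "PIAS3_MITFpp",
    "RSK1",
    "RSK1p",
    "STAT3",
    "STAT3p",
    "PIAS3_STAT3p",
    "R",
)

N_STATES = len(STATE_NAMES)


class SIdx:
    """Integer indices into the state vector, by species name."""

    MITF = 0
    MITFp73 = 1
    MITFp409 = 2
    MITFpp = 3
    PIAS3 = 4
    PIAS3_MITF = 5
    PIAS3_MITFp73 = 6
    PIAS3_MITFp409 = 7
    PIAS3_MITFpp = 8
    RSK1 = 9
    RSK1p = 10
    STAT3 = 11
    STAT3p = 12
    PIAS3_STAT3p = 13
    R = 14


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails to complete a requested span."""


@dataclass(frozen=True)
class SolverSettings:
    """Integration tolerances and reporting resolution."""

    rtol: float = 1e-6
    atol: float = 1e-8
    report_step: float = 1.0  # minutes between reported points
    max_steps: int = 500_000  # internal solver steps per output interval

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.report_step <= 0:
            raise ValueError("tolerances and report_step must be > 0")


@dataclass(frozen=True)
class InputSchedule:
    """Piecewise-constant phospho-ERK and phospho-JAK input levels.

    ``breakpoints`` is an ordered sequence of ``(time, erkp, jakp)``
    triples; the level from the latest breakpoint at or before ``t``
    applies.  The first breakpoint must be at the start of the horizon.
    """

    breakpoints: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.breakpoints:
            raise ValueError("schedule needs at least one breakpoint")
        times = [b[0] for b in self.breakpoints]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(b[1] < 0 or b[2] < 0 for b in self.breakpoints):
            raise ValueError("input levels must be >= 0")

    @classmethod
    def constant(cls, erkp: float, jakp: float, t0: float = 0.0) -> "InputSchedule":
        return cls(((t0, erkp, jakp),))

    @classmethod
    def resting(cls, params: CoreParameters) -> "InputSchedule":
        return cls.constant(params.ERKp_baseline, params.JAKp_baseline)

    def with_step(self, t: float, erkp: float, jakp: float) -> "InputSchedule":
        """Return a schedule with an additional step at time ``t``."""
        kept = tuple(b for b in self.breakpoints if b[0] < t)
        return InputSchedule(kept + ((t, erkp, jakp),))

    def levels(self, t: float) -> tuple[float, float]:
        times = [b[0] for b in self.breakpoints]
        i = bisect.bisect_right(times, t) - 1
        if i < 0:
            raise ValueError(f"time {t} precedes the schedule domain (starts {times[0]})")
        return self.breakpoints[i][1], self.breakpoints[i][2]


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs_core(t, y, p, erkp, jakp):  # pragma: no cover - exercised via wrappers
    (M, M73, M409, Mpp, P, PM, PM73, PM409, PMpp,
     RK, RKp, S, Sp, PSp, R) = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8],
        y[9], y[10], y[11], y[12], y[13], y[14],
    )
    (k73E, k73m, k73a, k409p, k409m,
     kMass, kMdiss, k73ass, k73diss, k409ass, k409diss, kppass, kppdiss,
     kSp, kSm, kSpass, kSpdiss,
     pM, gM, g73, g409, pP, gP, pS, gS,
     kRp, kRm, _erk0, _jak0, ku) = (
        p[0], p[1], p[2], p[3], p[4],
        p[5], p[6], p[7], p[8], p[9], p[10], p[11], p[12],
        p[13], p[14], p[15], p[16],
        p[17], p[18], p[19], p[20], p[21], p[22], p[23], p[24],
        p[25], p[26], p[27], p[28], p[29],
    )

    k73f = k73E * erkp + k73a  # total S73 phosphorylation rate constant

    # net phosphorylation fluxes (forward direction named by the substrate)
    f73_M = k73f * M - k73m * M73
    f73_M409 = k73f * M409 - k73m * Mpp
    f73_PM = k73f * PM - k73m * PM73
    f73_PM409 = k73f * PM409 - k73m * PMpp

    f409_M = k409p * RKp * M - k409m * M409
    f409_M73 = k409p * RKp * M73 - k409m * Mpp
    f409_PM = k409p * RKp * PM - k409m * PM409
    f409_PM73 = k409p * RKp * PM73 - k409m * PMpp

    # net binding fluxes (association direction positive)
    bM = kMass * M * P - kMdiss * PM
    bM73 = k73ass * M73 * P - k73diss * PM73
    bM409 = k409ass * M409 * P - k409diss * PM409
    bMpp = kppass * Mpp * P - kppdiss * PMpp
    bS = kSpass * Sp * P - kSpdiss * PSp

    fR = kRp * erkp * RK - kRm * RKp
    fS = kSp * jakp * S - kSm * Sp

    # ubiquitinated fraction R (a = 1 min carries the units)
    term_i = (1.0 - R) * erkp * ku
    term_ii = -g73 * R * (1.0 - R) / (1.0 - R * g73)
    B = M73 + Mpp
    if B < 0.0:
        B = 0.0
    influx = pM - M409 * g409
    if influx < 0.0:
        influx = 0.0
    denom = B + influx
    if denom <= 0.0:
        A = 1.0
    else:
        A = B / denom
    term_iii = -R * (1.0 - A)
    dR = term_i + term_ii + term_iii

    out = np.empty(15)
    out[0] = pM - f73_M - f409_M - bM - gM * M
    out[1] = f73_M - f409_M73 - bM73 - g73 * R * M73
    out[2] = -f73_M409 + f409_M - bM409 - g409 * M409
    out[3] = f73_M409 + f409_M73 - bMpp - (g73 * R + g409) * Mpp
    out[4] = pP - bM - bM73 - bM409 - bMpp - bS - gP * P
    out[5] = -f73_PM - f409_PM + bM - 0.1 * (gM + gP) * PM
    out[6] = f73_PM - f409_PM73 + bM73 - 0.1 * (g73 * R + gP) * PM73
    out[7] = -f73_PM409 + f409_PM + bM409 - 0.1 * (g409 + gP) * PM409
    out[8] = (f73_PM409 + f409_PM73 + bMpp
              - 0.1 * (g73 * R + gP) * PMpp - 0.1 * (g409 + gP) * PMpp)
    out[9] = -fR
    out[10] = fR
    out[11] = pS - fS - gS * S
    out[12] = fS - bS - gS * Sp
    out[13] = bS - 0.1 * (gS + gP) * PSp
    out[14] = dR
    return out


def ubiquitination_terms(
    state: np.ndarray, params: CoreParameters, erkp: float
) -> dict[str, float]:
    """The three contributions to ``dR/dt`` plus the auxiliaries A and B.

    ``term_i`` is the ubiquitination of untagged protein (rate
    ``(1-R) * ERKp * k_u``), ``term_ii`` the depletion of the tagged pool
    by its own degradation, and ``term_iii`` the dilution of the tagged
    fraction by production of fresh, untagged protein.  The unit-carrying
    constant ``a`` equals one minute.

    ``term_ii`` uses the singularity-free form
    ``-gamma * a * R * (1-R) / (1 - R * gamma * a)``, algebraically equal
    to ``-(R - R')/a`` for R > 0 but regular at R = 0.  The dilution ratio
    ``A = B / (B + max(p_MITF - MITFp409 * gamma_MITFp409, 0) * a)`` with
    ``B = [MITFp73] + [MITFpp]`` is clamped so that a net *negative*
    production influx never inflates A beyond 1 (which would let R leave
    [0, 1]); with no positive influx A = 1 and the dilution term vanishes.
    """
    y = np.asarray(state, dtype=float)
    R = y[SIdx.R]
    g73 = params.gamma_MITFp73
    g409 = params.gamma_MITFp409
    a = 1.0  # minutes
    B = max(y[SIdx.MITFp73] + y[SIdx.MITFpp], 0.0)
    influx = max(params.p_MITF - y[SIdx.MITFp409] * g409, 0.0)
    denom = B + influx * a
    A = 1.0 if denom <= 0.0 else B / denom
    term_i = (1.0 - R) * erkp * params.k_u
    term_ii = -g73 * a * R * (1.0 - R) / (1.0 - R * g73 * a)
    term_iii = -(R - R * A) / a
    return {"term_i": term_i, "term_ii": term_ii, "term_iii": term_iii,
            "A": A, "B": B, "a": a}


def ubiquitination_rate(state: np.ndarray, params: CoreParameters, erkp: float) -> float:
    """``dR/dt`` -- the sum of the three ubiquitination bookkeeping terms."""
    t = ubiquitination_terms(state, params, erkp)
    return t["term_i"] + t["term_ii"] + t["term_iii"]


def rhs(
    t: float,
    state: np.ndarray,
    params: CoreParameters,
    schedule: InputSchedule,
) -> np.ndarray:
    """Time-derivative of the 15 state variables under the given inputs."""
    erkp, jakp = schedule.levels(t)
    return _rhs_core(t, np.asarray(state, dtype=np.float64), params.as_array(), erkp, jakp)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A simulated time course: time grid, states, and full provenance.

    ``y`` holds the raw solver output (one row per time point).  Tiny
    negative excursions within solver tolerance can occur; ``values``
    exposes the reporting view with amounts floored at zero.  The ODE
    itself is never evaluated on clipped states.
    """

    t: np.ndarray
    y: np.ndarray
    params: CoreParameters
    schedule: InputSchedule
    settings: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    @property
    def values(self) -> np.ndarray:
        return np.clip(self.y, 0.0, None)

    def state_at(self, time: float) -> np.ndarray:
        """Linearly interpolated (clipped) state at ``time``."""
        if time < self.t[0] - 1e-9 or time > self.t[-1] + 1e-9:
            raise ValueError(f"time {time} outside trajectory range "
                             f"[{self.t[0]}, {self.t[-1]}]")
        v = self.values
        return np.array([np.interp(time, self.t, v[:, j]) for j in range(v.shape[1])])

    def column(self, name: str) -> np.ndarray:
        return self.values[:, STATE_NAMES.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.values[-1]

    def to_frame(self):
        """Tidy table: time, states, inputs and the two activity readouts."""
        import pandas as pd

        from .activity import DEFAULT_WEIGHTS, mitf_activity, stat3_activity

        v = self.values
        data = {"time_min": self.t}
        for j, name in enumerate(STATE_NAMES):
            data[name] = v[:, j]
        levels = np.array([self.schedule.levels(tt) for tt in self.t])
        data["ERKp"] = levels[:, 0]
        data["JAKp"] = levels[:, 1]
        data["MITF_activity"] = np.array(
            [mitf_activity(row, DEFAULT_WEIGHTS) for row in v])
        data["STAT3_activity"] = np.array([stat3_activity(row) for row in v])
        return pd.DataFrame(data)


def default_initial_state(params: CoreParameters) -> np.ndarray:
    """All-zero species with the conserved RSK1 pool unphosphorylated."""
    y0 = np.zeros(N_STATES)
    y0[SIdx.RSK1] = params.RSK1_total
    return y0


def _integrate_constant(
    y0: np.ndarray,
    span: np.ndarray,
    p_arr: np.ndarray,
    erkp: float,
    jakp: float,
    settings: SolverSettings,
) -> np.ndarray:
    """LSODA integration over ``span`` (times relative to y0) at constant inputs."""
    out, info = odeint(
        _rhs_core,
        y0,
        span,
        args=(p_arr, erkp, jakp),
        tfirst=True,
        rtol=settings.rtol,
        atol=settings.atol,
        mxstep=settings.max_steps,
        full_output=True,
        printmessg=False,
    )
    if info["message"] != "Integration successful.":
        raise SolverError(
            f"LSODA failed over t=[{span[0]}, {span[-1]}] at inputs "
            f"ERKp={erkp}, JAKp={jakp}: {info['message']}"
        )
    return out


def simulate(
    params: CoreParameters,
    schedule: InputSchedule,
    initial: np.ndarray,
    duration: float,
    settings: SolverSettings | None = None,
    t_eval: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the model over ``[0, duration]`` minutes.

    The schedule is honoured exactly by restarting the integrator at each
    input breakpoint.  Reported points are ``t_eval`` if given, otherwise
    a uniform grid at the settings' reporting step (always including 0 and
    ``duration``).  Solver failures raise :class:`SolverError` with the
    failing span and input levels; they are never silently truncated.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    settings = settings or SolverSettings()
    initial = np.asarray(initial, dtype=np.float64)
    if initial.shape != (N_STATES,):
        raise ValueError(f"initial state must have shape ({N_STATES},)")

    if t_eval is None:
        grid = np.arange(0.0, duration, settings.report_step)
        grid = np.append(grid, duration)
    else:
        grid = np.asarray(t_eval, dtype=float)
        if grid[0] != 0.0:
            grid = np.insert(grid, 0, 0.0)
        if grid[-1] != duration:
            grid = np.append(grid, duration)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("t_eval must be strictly increasing within [0, duration]")

    # segment boundaries: schedule breakpoints inside (0, duration)
    cuts = [b[0] for b in schedule.breakpoints if 0.0 < b[0] < duration]
    bounds = [0.0] + cuts + [duration]

    p_arr = params.as_array()
    t_out = [np.array([0.0])]
    y_out = [initial[None, :]]
    y_cur = initial
    for lo, hi in zip(bounds, bounds[1:]):
        erkp, jakp = schedule.levels(lo)
        inner = grid[(grid > lo) & (grid < hi)]
        span = np.concatenate(([lo], inner, [hi]))
        sol = _integrate_constant(y_cur, span, p_arr, erkp, jakp, settings)
        y_cur = sol[-1]
        keep = np.concatenate((inner, [hi]))
        t_out.append(keep)
        y_out.append(sol[1:])
    t_all = np.concatenate(t_out)
    y_all = np.vstack(y_out)
    # retain only requested grid points (segment bounds may add extras)
    mask = np.isin(t_all, grid) | np.isclose(t_all[:, None], grid[None, :]).any(axis=1)
    return Trajectory(t_all[mask], y_all[mask], params, schedule, settings)


def find_steady_state(
    params: CoreParameters,
    erkp: float | None = None,
    jakp: float | None = None,
    initial: np.ndarray | None = None,
    tol: float = 1e-6,
    horizon: float = 50_000.0,
    max_horizon: float = 400_000.0,
    settings: SolverSettings | None = None,
) -> np.ndarray:
    """Steady state under constant inputs, found by long integration.

    Integrates for ``horizon`` minutes (extending up to ``max_horizon``)
    and verifies that the largest component of the right-hand side,
    relative to the state scale ``|x_i| + 1``, is below ``tol``.  Raises
    :class:`SolverError` on non-convergence.
    """
    settings = settings or SolverSettings()
    if erkp is None:
        erkp = params.ERKp_baseline
    if jakp is None:
        jakp = params.JAKp_baseline
    y = np.asarray(initial, dtype=np.float64) if initial is not None \
        else default_initial_state(params)
    p_arr = params.as_array()
    elapsed = 0.0
    span_len = horizon
    while True:
        sol = _integrate_constant(
            y, np.array([0.0, span_len]), p_arr, erkp, jakp, settings)
        y = sol[-1]
        elapsed += span_len
        f = _rhs_core(0.0, y, p_arr, erkp, jakp)
        rel = np.max(np.abs(f) / (np.abs(y) + 1.0))
        if rel < tol:
            return np.clip(y, 0.0, None)
        if elapsed >= max_horizon:
            raise SolverError(
                f"no steady state within {elapsed:.0f} min at "
                f"ERKp={erkp}, JAKp={jakp} (residual {rel:.2e} > {tol:.0e})"
            )
        span_len = min(span_len * 2, max_horizon - elapsed)


# ---------------------------------------------------------------------------
# Derived totals (accept a single state vector or a trajectory matrix)
# ---------------------------------------------------------------------------

def _sum(y: np.ndarray, idx: Sequence[int]) -> np.ndarray | float:
    y = np.asarray(y)
    return y[..., list(idx)].sum(axis=-1)


def total_mitf(y: np.ndarray):
    """Total MITF: all four phospho-forms, free and PIAS3-bound."""
    return _sum(y, (SIdx.MITF, SIdx.MITFp73, SIdx.MITFp409, SIdx.MITFpp,
                    SIdx.PIAS3_MITF, SIdx.PIAS3_MITFp73,
                    SIdx.PIAS3_MITFp409, SIdx.PIAS3_MITFpp))


def phospho_mitf(y: np.ndarray):
    """MITF carrying at least one phosphate, free and PIAS3-bound."""
    return _sum(y, (SIdx.MITFp73, SIdx.MITFp409, SIdx.MITFpp,
                    SIdx.PIAS3_MITFp73, SIdx.PIAS3_MITFp409, SIdx.PIAS3_MITFpp))


def unphospho_mitf(y: np.ndarray):
    return _sum(y, (SIdx.MITF, SIdx.PIAS3_MITF))


def mitf_pias3_complex(y: np.ndarray):
    """Total MITF-PIAS3 complex across the four MITF phospho-forms."""
    return _sum(y, (SIdx.PIAS3_MITF, SIdx.PIAS3_MITFp73,
                    SIdx.PIAS3_MITFp409, SIdx.PIAS3_MITFpp))


def total_pias3(y: np.ndarray):
    """Total PIAS3: free plus all five complexes."""
    return _sum(y, (SIdx.PIAS3, SIdx.PIAS3_MITF, SIdx.PIAS3_MITFp73,
                    SIdx.PIAS3_MITFp409, SIdx.PIAS3_MITFpp, SIdx.PIAS3_STAT3p))


def total_stat3(y: np.ndarray):
    """Total STAT3: free, phosphorylated, and PIAS3-bound."""
    return _sum(y, (SIdx.STAT3, SIdx.STAT3p, SIdx.PIAS3_STAT3p))
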