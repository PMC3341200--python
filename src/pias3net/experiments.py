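"""The catalog of 28 virtual experiments and the machinery to run them.

Each catalog entry formalizes one published wet-lab experiment on the
MITF-PIAS3-STAT3 system as

* one or more *conditions* (e.g. with / without PIAS3 transfection, wild
  type vs mutant), each an ordered list of phases.  A phase holds a
  duration and a perturbation: absolute core-parameter overrides
  (transfections raise production rates, mutations zero or rescale rate
  constants), input kinase levels (stimulation steps phospho-ERK and/or
  phospho-JAK), and an optional RSK1-total override (RSK1 transfection);
* *readouts* -- named scalar quantities extracted from the simulated
  trajectories at stated times;
* a *success criterion* -- a conjunction of interval, ratio and ordering
  clauses with the published bounds.

Unless a condition overrides initial values, every protocol starts from
the resting steady state at baseline inputs (phospho-ERK = phospho-JAK =
10 au) with default production rates; permanent genotype perturbations
(``pre_params``) are also applied while computing that resting state.
Transfection phases then run from the resting state with elevated
production for the stated incubation time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .activity import DEFAULT_WEIGHTS, mitf_activity, stat3_activity
from .model import (
    SIdx,
    STATE_NAMES,
    InputSchedule,
    SolverError,
    SolverSettings,
    Trajectory,
    find_steady_state,
    mitf_pias3_complex,
    phospho_mitf,
    simulate,
    total_mitf,
    unphospho_mitf,
)
from .params import CoreParameters

__all__ = [
    "Perturbation",
    "Phase",
    "Condition",
    "Readout",
    "Clause",
    "ExperimentSpec",
    "ExperimentResult",
    "experiment_catalog",
    "run_experiment",
    "run_all",
    "QUANTITIES",
]

logger = logging.getLogger(__name__)

_Items = tuple[tuple[str, float], ...]


def _items(mapping: Mapping[str, float] | None) -> _Items:
    return tuple(sorted((k, float(v)) for k, v in (mapping or {}).items()))


@dataclass(frozen=True)
class Perturbation:
    """Absolute overrides applied during one phase.

    ``params`` are core-parameter overrides (absolute values, not
    factors); ``erkp`` / ``jakp`` replace the baseline input levels;
    ``rsk1_total`` tops the conserved RSK1 pool up to the given total at
    phase start (transfection of the kinase).
    """

    params: _Items = ()
    erkp: float | None = None
    jakp: float | None = None
    rsk1_total: float | None = None

    def __post_init__(self) -> None:
        valid = set(CoreParameters.__dataclass_fields__)
        for name, value in self.params:
            if name not in valid:
                raise ValueError(f"perturbation references unknown parameter {name!r}")
            if value < 0:
                raise ValueError(f"perturbation value for {name} must be >= 0")

    def apply(self, params: CoreParameters) -> CoreParameters:
        return params.replace(**dict(self.params)) if self.params else params


def perturb(
    params: Mapping[str, float] | None = None,
    erkp: float | None = None,
    jakp: float | None = None,
    rsk1_total: float | None = None,
) -> Perturbation:
    return Perturbation(_items(params), erkp, jakp, rsk1_total)


@dataclass(frozen=True)
class Phase:
    duration: float
    perturbation: Perturbation = field(default_factory=Perturbation)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase duration must be > 0")


@dataclass(frozen=True)
class Condition:
    """One simulated arm of an experiment.

    ``initial`` overrides individual state variables of the resting
    steady state (state name -> value); ``pre_params`` are parameter
    overrides that are *also* active while computing the resting state
    (permanent genotype, e.g. a binding-dead mutant).  ``steady_state``
    conditions ignore phase durations and instead report the steady
    state under the (single) phase's perturbation.
    """

    name: str
    phases: tuple[Phase, ...]
    initial: _Items = ()
    pre_params: _Items = ()
    steady_state: bool = False

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("condition needs at least one phase")
        if self.steady_state and len(self.phases) != 1:
            raise ValueError("steady-state condition must have exactly one phase")
        for name, _ in self.initial:
            if name not in STATE_NAMES:
                raise ValueError(f"initial override references unknown state {name!r}")

    @property
    def duration(self) -> float:
        return sum(p.duration for p in self.phases)

    def cache_key(self) -> tuple:
        """Signature of everything that determines this condition's dynamics."""
        return (self.phases, self.initial, self.pre_params, self.steady_state)


# ---------------------------------------------------------------------------
# Readouts
# ---------------------------------------------------------------------------

def _frac_phospho(y: np.ndarray) -> float:
    tot = total_mitf(y)
    return float(phospho_mitf(y) / tot) if tot > 0 else math.nan


def _frac_unphospho(y: np.ndarray) -> float:
    tot = total_mitf(y)
    return float(unphospho_mitf(y) / tot) if tot > 0 else math.nan


#: State-level quantities a readout may reference.
QUANTITIES: dict[str, Callable[[np.ndarray], float]] = {
    **{name: (lambda y, j=j: float(np.asarray(y)[..., j]))
       for j, name in enumerate(STATE_NAMES)},
    "MITF_activity": lambda y: mitf_activity(y, DEFAULT_WEIGHTS),
    "STAT3_activity": stat3_activity,
    "MITF_total": lambda y: float(total_mitf(y)),
    "MITF_PIAS3_complex": lambda y: float(mitf_pias3_complex(y)),
    "MITF_phospho_frac": _frac_phospho,
    "MITF_unphospho_frac": _frac_unphospho,
}

#: Trajectory-level quantities (need the whole time course).
TRAJECTORY_QUANTITIES = ("t90_RSK1p",)


def _t90(t: np.ndarray, x: np.ndarray) -> float:
    """Earliest time at which ``x`` reaches 90% of its maximum over ``t``."""
    target = 0.9 * float(np.max(x))
    above = np.nonzero(x >= target)[0]
    if len(above) == 0:
        return math.nan
    i = above[0]
    if i == 0:
        return float(t[0])
    # linear interpolation between the bracketing points
    t0, t1, x0, x1 = t[i - 1], t[i], x[i - 1], x[i]
    return float(t0 + (target - x0) / (x1 - x0) * (t1 - t0))


@dataclass(frozen=True)
class Readout:
    """A named scalar extracted from one condition's trajectory.

    ``time`` is in minutes from the start of the condition's protocol;
    ``None`` means the end of the final phase.
    """

    name: str
    condition: str
    quantity: str
    time: float | None = None

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES and self.quantity not in TRAJECTORY_QUANTITIES:
            raise ValueError(f"unknown readout quantity {self.quantity!r}")

    def extract(self, traj: Trajectory) -> float:
        if self.quantity == "t90_RSK1p":
            return _t90(traj.t, traj.column("RSK1p"))
        t = traj.t[-1] if self.time is None else self.time
        return QUANTITIES[self.quantity](traj.state_at(t))


# ---------------------------------------------------------------------------
# Success criteria
# ---------------------------------------------------------------------------

_OPS = {"gt": np.greater, "ge": np.greater_equal,
        "lt": np.less, "le": np.less_equal}


@dataclass(frozen=True)
class Clause:
    """One boolean clause over named readouts.

    kinds:
      ``window``       lo <= x <= hi
      ``ratio_window`` lo <= num/den <= hi
      ``compare``      a OP factor * b       (OP in gt/ge/lt/le)
    Bounds left as ``None`` are unconstrained.
    """

    kind: str
    x: str | None = None
    num: str | None = None
    den: str | None = None
    a: str | None = None
    b: str | None = None
    lo: float | None = None
    hi: float | None = None
    op: str | None = None
    factor: float = 1.0
    label: str = ""

    def evaluate(self, readouts: Mapping[str, float]) -> tuple[bool, str]:
        if self.kind == "window":
            x = readouts[self.x]
            ok = ((self.lo is None or x >= self.lo)
                  and (self.hi is None or x <= self.hi))
            return bool(ok) and math.isfinite(x), f"{self.x}={x:.6g} in [{self.lo}, {self.hi}]"
        if self.kind == "ratio_window":
            num, den = readouts[self.num], readouts[self.den]
            if den <= 0 or not math.isfinite(den) or not math.isfinite(num):
                return False, f"{self.num}/{self.den} undefined (den={den:.6g})"
            r = num / den
            ok = ((self.lo is None or r >= self.lo)
                  and (self.hi is None or r <= self.hi))
            return bool(ok), f"{self.num}/{self.den}={r:.6g} in [{self.lo}, {self.hi}]"
        if self.kind == "compare":
            a, b = readouts[self.a], readouts[self.b]
            if not (math.isfinite(a) and math.isfinite(b)):
                return False, f"{self.a} vs {self.b}: non-finite readout"
            ok = bool(_OPS[self.op](a, self.factor * b))
            return ok, f"{self.a}={a:.6g} {self.op} {self.factor:g}*{self.b}={self.factor * b:.6g}"
        raise ValueError(f"unknown clause kind {self.kind!r}")


@dataclass(frozen=True)
class ExperimentSpec:
    id: int
    description: str
    conditions: tuple[Condition, ...]
    readouts: tuple[Readout, ...]
    criterion: tuple[Clause, ...]

    def __post_init__(self) -> None:
        names = {c.name for c in self.conditions}
        if len(names) != len(self.conditions):
            raise ValueError(f"experiment {self.id}: duplicate condition names")
        for r in self.readouts:
            if r.condition not in names:
                raise ValueError(
                    f"experiment {self.id}: readout {r.name} references "
                    f"unknown condition {r.condition!r}")
        rnames = {r.name for r in self.readouts}
        for cl in self.criterion:
            for ref in (cl.x, cl.num, cl.den, cl.a, cl.b):
                if ref is not None and ref not in rnames:
                    raise ValueError(
                        f"experiment {self.id}: clause references unknown "
                        f"readout {ref!r}")


@dataclass
class ExperimentResult:
    id: int
    passed: bool
    readouts: dict[str, float]
    clauses: list[dict]
    error: str | None = None

    @property
    def errored(self) -> bool:
        return self.error is not None


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

class _Runner:
    """Simulates conditions with steady-state and condition-level caching.

    One runner is scoped to a single core-parameter set; caches may be
    shared across the experiments of a batch because replicated protocol
    arms (the shared stimulated arm of the paired complex-association
    experiments, the common unactivated background of the STAT3-activity
    series) are content-identical.
    """

    def __init__(self, params: CoreParameters, settings: SolverSettings | None = None):
        self.params = params
        self.settings = settings or SolverSettings()
        self._ss_cache: dict[_Items, np.ndarray] = {}
        self._cond_cache: dict[tuple, Trajectory] = {}

    def resting_state(self, pre_params: _Items = ()) -> np.ndarray:
        if pre_params not in self._ss_cache:
            p = self.params.replace(**dict(pre_params))
            self._ss_cache[pre_params] = find_steady_state(
                p, settings=self.settings)
        return self._ss_cache[pre_params]

    def run_condition(self, cond: Condition, times: list[float],
                      dense: bool = False) -> Trajectory:
        """Simulate ``cond``, reporting at least at the given global times."""
        key = (cond.cache_key(), dense, tuple(sorted(set(times))))
        if key in self._cond_cache:
            return self._cond_cache[key]

        y0 = self.resting_state(cond.pre_params).copy()
        for name, value in cond.initial:
            y0[STATE_NAMES.index(name)] = value

        base = self.params.replace(**dict(cond.pre_params))

        if cond.steady_state:
            pert = cond.phases[0].perturbation
            p = pert.apply(base)
            erkp = pert.erkp if pert.erkp is not None else p.ERKp_baseline
            jakp = pert.jakp if pert.jakp is not None else p.JAKp_baseline
            y = find_steady_state(p, erkp, jakp, initial=y0, settings=self.settings)
            traj = Trajectory(np.array([0.0, 1.0]), np.vstack([y, y]),
                              p, InputSchedule.constant(erkp, jakp), self.settings)
            self._cond_cache[key] = traj
            return traj

        t_parts: list[np.ndarray] = [np.array([0.0])]
        y_parts: list[np.ndarray] = [y0[None, :]]
        offset = 0.0
        y = y0
        for phase_no, phase in enumerate(cond.phases):
            pert = phase.perturbation
            p = pert.apply(base)
            erkp = pert.erkp if pert.erkp is not None else p.ERKp_baseline
            jakp = pert.jakp if pert.jakp is not None else p.JAKp_baseline
            if pert.rsk1_total is not None:
                # transfected kinase arrives unphosphorylated
                current = y[SIdx.RSK1] + y[SIdx.RSK1p]
                y = y.copy()
                y[SIdx.RSK1] += max(pert.rsk1_total - current, 0.0)
                p = p.replace(RSK1_total=pert.rsk1_total)
            lo, hi = offset, offset + phase.duration
            local = sorted({t - lo for t in times if lo < t <= hi}
                           | {phase.duration})
            if dense:
                step = min(self.settings.report_step, phase.duration)
                grid = set(np.arange(0.0, phase.duration, step))
                local = sorted((grid | set(local)) - {0.0})
            logger.debug("condition=%s phase=%d duration=%.0f ERKp=%g JAKp=%g "
                         "overrides=%s", cond.name, phase_no, phase.duration,
                         erkp, jakp, dict(pert.params))
            traj = simulate(p, InputSchedule.constant(erkp, jakp), y,
                            phase.duration, self.settings,
                            t_eval=np.array([0.0] + local))
            y = traj.y[-1]
            t_parts.append(traj.t[1:] + lo)
            y_parts.append(traj.y[1:])
            offset = hi
        full = Trajectory(np.concatenate(t_parts), np.vstack(y_parts),
                          self.params, InputSchedule.resting(self.params),
                          self.settings)
        self._cond_cache[key] = full
        return full


def run_experiment(
    spec: ExperimentSpec,
    params: CoreParameters,
    settings: SolverSettings | None = None,
    runner: _Runner | None = None,
) -> ExperimentResult:
    """Simulate all conditions of one experiment and evaluate its criterion.

    Solver failures mark the experiment *errored* (``passed=False`` with
    ``error`` set), which is distinct from an honest criterion failure.
    """
    runner = runner or _Runner(params, settings)
    needed: dict[str, list[float]] = {}
    dense_conds = set()
    for r in spec.readouts:
        cond = next(c for c in spec.conditions if c.name == r.condition)
        t = cond.duration if r.time is None else r.time
        needed.setdefault(r.condition, []).append(t)
        if r.quantity in TRAJECTORY_QUANTITIES:
            dense_conds.add(r.condition)
    try:
        trajs = {
            c.name: runner.run_condition(c, needed.get(c.name, []),
                                         dense=c.name in dense_conds)
            for c in spec.conditions
        }
        readouts = {r.name: r.extract(trajs[r.condition]) for r in spec.readouts}
    except SolverError as exc:
        return ExperimentResult(spec.id, False, {}, [], error=str(exc))
    clauses = []
    passed = True
    for cl in spec.criterion:
        ok, detail = cl.evaluate(readouts)
        clauses.append({"label": cl.label or cl.kind, "passed": ok, "detail": detail})
        passed = passed and ok
    return ExperimentResult(spec.id, passed, readouts, clauses)


def run_all(
    params: CoreParameters,
    settings: SolverSettings | None = None,
    catalog: tuple[ExperimentSpec, ...] | None = None,
    progress: bool = False,
) -> dict[int, ExperimentResult]:
    """Run every catalog experiment under one core-parameter set.

    Deterministic given parameters and solver settings.  Per-experiment
    solver errors are recorded, never propagated, so one pathological
    parameter draw cannot abort a batch.
    """
    catalog = catalog or experiment_catalog()
    runner = _Runner(params, settings)
    it = catalog
    if progress:
        from tqdm import tqdm

        it = tqdm(catalog, desc="experiments")
    results = {}
    for spec in it:
        results[spec.id] = run_experiment(spec, params, settings, runner=runner)
    return results


def outcome_vector(results: Mapping[int, ExperimentResult]) -> np.ndarray:
    """Boolean pass vector ordered by experiment id (NaN-free; errors = False)."""
    return np.array([results[i].passed for i in sorted(results)], dtype=bool)


# ---------------------------------------------------------------------------
# The catalog
# ---------------------------------------------------------------------------

#: initial-state override: no endogenous MITF (fibroblast background)
_ZERO_MITF: _Items = tuple(
    (s, 0.0) for s in ("MITF", "MITFp73", "MITFp409", "MITFpp",
                       "PIAS3_MITF", "PIAS3_MITFp73", "PIAS3_MITFp409",
                       "PIAS3_MITFpp"))

#: initial-state override: MITF and PIAS3 pools reduced to 1 au
_LOW_MITF_PIAS3: _Items = tuple(
    (s, 1.0) for s in ("MITF", "MITFp73", "MITFp409", "MITFpp", "PIAS3",
                       "PIAS3_MITF", "PIAS3_MITFp73", "PIAS3_MITFp409",
                       "PIAS3_MITFpp"))

_S409A = {"k_Mp409_plus": 0.0}  # alanine at S409: site cannot be phosphorylated

_INCUBATION = 2880.0  # minutes (2 days of transfected-gene expression)


def _ratio_exp(
    eid: int,
    description: str,
    base: Mapping[str, float],
    pias3_level: float,
    lo: float,
    hi: float,
    erkp: float | None = None,
    rsk1_total: float | None = None,
    initial: _Items = (),
) -> ExperimentSpec:
    """MITF-activity ratio template: +PIAS3 vs -PIAS3 after incubation."""
    with_p = dict(base)
    with_p["p_PIAS3"] = pias3_level
    conds = (
        Condition("pias3", (Phase(_INCUBATION, perturb(with_p, erkp=erkp,
                                                       rsk1_total=rsk1_total)),),
                  initial=initial),
        Condition("control", (Phase(_INCUBATION, perturb(base, erkp=erkp,
                                                         rsk1_total=rsk1_total)),),
                  initial=initial),
    )
    return ExperimentSpec(
        eid, description, conds,
        readouts=(Readout("act_pias3", "pias3", "MITF_activity"),
                  Readout("act_control", "control", "MITF_activity")),
        criterion=(Clause("ratio_window", num="act_pias3", den="act_control",
                          lo=lo, hi=hi,
                          label=f"activity with PIAS3 within [{lo:.0%}, {hi:.0%}] "
                                f"of no-PIAS3"),),
    )


def _stat3_fold_exp(
    eid: int,
    description: str,
    overrides: Mapping[str, float],
    lo: float,
    hi: float,
) -> ExperimentSpec:
    """STAT3-activity template: incubation + activation vs unactivated background."""
    conds = (
        Condition("test", (Phase(_INCUBATION, perturb(overrides)),
                           Phase(360.0, perturb(overrides, erkp=1000, jakp=1000)))),
        Condition("background", (Phase(3240.0, perturb({"p_STAT3": 5.0})),)),
    )
    return ExperimentSpec(
        eid, description, conds,
        readouts=(Readout("stat3p", "test", "STAT3p"),
                  Readout("background", "background", "STAT3p")),
        criterion=(Clause("ratio_window", num="stat3p", den="background",
                          lo=lo, hi=hi,
                          label=f"phospho-STAT3 {lo:g}-{hi:g} fold over background"),),
    )


def experiment_catalog() -> tuple[ExperimentSpec, ...]:
    """Build the full 28-experiment catalog from the published protocols."""
    specs: list[ExperimentSpec] = []

    # 1 -- RSK1 phosphorylation kinetics upon strong MAPK activation
    specs.append(ExperimentSpec(
        1, "Temporal development of ERK and RSK1 kinase activity",
        conditions=(Condition("act", (Phase(60.0, perturb(erkp=1000)),)),),
        readouts=(Readout("t90", "act", "t90_RSK1p"),),
        criterion=(Clause("window", x="t90", lo=3.0, hi=10.0,
                          label="RSK1p reaches 90% of max in 3-10 min"),),
    ))

    # 2 -- MITF phosphorylation distribution in growing (unstimulated) culture
    specs.append(ExperimentSpec(
        2, "Distribution between MITF phosphorylation states before stimulation",
        conditions=(Condition("growing", (Phase(1.0, perturb(erkp=80)),),
                              steady_state=True),),
        readouts=(Readout("phospho", "growing", "MITF_phospho_frac"),
                  Readout("unphospho", "growing", "MITF_unphospho_frac")),
        criterion=(Clause("window", x="phospho", lo=0.25, hi=0.75,
                          label="phosphorylated MITF 25-75% of total"),
                   Clause("window", x="unphospho", lo=0.25, hi=0.75,
                          label="unphosphorylated MITF 25-75% of total")),
    ))

    # 3 -- MITF phosphorylation 30 min after strong stimulation
    specs.append(ExperimentSpec(
        3, "MITF phosphorylation states after stimulation",
        conditions=(Condition("act", (Phase(30.0, perturb(erkp=1000, jakp=1000)),)),),
        readouts=(Readout("phospho30", "act", "MITF_phospho_frac", time=30.0),),
        criterion=(Clause("window", x="phospho30", lo=0.8,
                          label=">80% of MITF phosphorylated at 30 min"),),
    ))

    # 4 -- MITF degradation profile after stimulation
    specs.append(ExperimentSpec(
        4, "Temporal development of MITF degradation",
        conditions=(Condition("act", (Phase(300.0, perturb(erkp=950, jakp=950)),)),),
        readouts=(Readout("tot0", "act", "MITF_total", time=0.0),
                  Readout("tot60", "act", "MITF_total", time=60.0),
                  Readout("tot300", "act", "MITF_total", time=300.0)),
        criterion=(Clause("ratio_window", num="tot60", den="tot0", lo=0.5,
                          label="<50% of MITF degraded at 1 h"),
                   Clause("ratio_window", num="tot300", den="tot0", hi=1.0 / 3.0,
                          label=">=2/3 of MITF degraded at 5 h")),
    ))

    # 5 -- MITF activity under increasing PIAS3 transfection doses
    lvls = (0.5, 1.0, 2.0, 4.0)
    specs.append(ExperimentSpec(
        5, "MITF activity in response to PIAS3 transfection dose",
        conditions=tuple(
            Condition(f"pias3_{lv:g}",
                      (Phase(_INCUBATION, perturb({"p_MITF": 18.0, "p_PIAS3": lv})),))
            for lv in lvls),
        readouts=tuple(Readout(f"act_{lv:g}", f"pias3_{lv:g}", "MITF_activity")
                       for lv in lvls),
        criterion=tuple(
            Clause("compare", a=f"act_{a:g}", b=f"act_{b:g}", op="gt",
                   label=f"activity decreasing: {a:g} > {b:g} PIAS3")
            for a, b in zip(lvls, lvls[1:])
        ) + (Clause("compare", a="act_4", b="act_0.5", factor=0.5, op="lt",
                    label="highest PIAS3 dose below half of lowest"),),
    ))

    # 6 -- MITF-PIAS3 complex kinetics upon activation (endogenous production)
    specs.append(ExperimentSpec(
        6, "MITF-PIAS3 complex in response to activation",
        conditions=(Condition("act", (Phase(30.0, perturb(erkp=500, jakp=50)),)),),
        readouts=(Readout("c0", "act", "MITF_PIAS3_complex", time=0.0),
                  Readout("c10", "act", "MITF_PIAS3_complex", time=10.0),
                  Readout("c30", "act", "MITF_PIAS3_complex", time=30.0)),
        criterion=(Clause("compare", a="c10", b="c0", op="gt",
                          label="complex up at 10 min"),
                   Clause("compare", a="c30", b="c10", op="lt",
                          label="complex down again at 30 min")),
    ))

    # 7 -- as 6 but with transfected MITF and PIAS3, stronger activation
    t7 = {"p_MITF": 10.0, "p_PIAS3": 10.0}
    specs.append(ExperimentSpec(
        7, "MITF-PIAS3 complex after activation with transfected MITF and PIAS3",
        conditions=(Condition("act", (Phase(_INCUBATION, perturb(t7)),
                                      Phase(30.0, perturb(t7, erkp=1200, jakp=250)))),),
        readouts=(Readout("c0", "act", "MITF_PIAS3_complex", time=_INCUBATION),
                  Readout("c10", "act", "MITF_PIAS3_complex", time=_INCUBATION + 10),
                  Readout("c30", "act", "MITF_PIAS3_complex", time=_INCUBATION + 30)),
        criterion=(Clause("compare", a="c10", b="c0", op="gt",
                          label="complex up at 10 min"),
                   Clause("compare", a="c30", b="c10", op="lt",
                          label="complex down again at 30 min")),
    ))

    # 8 -- MITF activity with vs without constitutively active RSK1
    specs.append(ExperimentSpec(
        8, "MITF activity in response to constitutively active RSK1",
        conditions=(Condition("rsk1", (Phase(_INCUBATION,
                                             perturb({"p_MITF": 7.0},
                                                     rsk1_total=5000)),)),
                    Condition("control", (Phase(_INCUBATION,
                                                perturb({"p_MITF": 7.0})),))),
        readouts=(Readout("act_rsk1", "rsk1", "MITF_activity"),
                  Readout("act_control", "control", "MITF_activity")),
        criterion=(Clause("ratio_window", num="act_rsk1", den="act_control",
                          lo=0.5, hi=2.0,
                          label="activities within two-fold of each other"),),
    ))

    # 9-12 -- PIAS3 inhibition of (mutant) MITF activity, +/- RSK1.
    # The replicated arms share one experiment-specific record: MITF
    # production 7, PIAS3 production 4, activation level 20 (the MAPK arm
    # only -- these protocols probe MITF), RSK1 total 5000 where present.
    base_912 = {"p_MITF": 7.0}
    pias3_912 = 4.0
    act_912 = 20.0
    rsk_912 = 5000.0
    specs.append(_ratio_exp(9, "MITF activity inhibition by PIAS3",
                            base_912, pias3_912, 0.02, 0.42, erkp=act_912))
    specs.append(_ratio_exp(10, "MITF activity inhibition by PIAS3 with active RSK1",
                            base_912, pias3_912, 0.44, 0.84, erkp=act_912,
                            rsk1_total=rsk_912))
    specs.append(_ratio_exp(11, "MITF-S409A activity inhibition by PIAS3",
                            {**base_912, **_S409A}, pias3_912, 0.15, 0.55,
                            erkp=act_912))
    specs.append(_ratio_exp(12, "MITF-S409A activity inhibition by PIAS3 "
                                "with active RSK1",
                            {**base_912, **_S409A}, pias3_912, 0.10, 0.50,
                            erkp=act_912, rsk1_total=rsk_912))

    # 13-16 -- phospho-mimetic S/D mutants, fibroblasts without endogenous MITF
    base_1316 = {"p_MITF": 1.5}
    pias3_1316 = 4.5
    s73d = {"k_Mp73_minus": 0.0, "k_Mp73a_plus": 5.0}
    s409d = {"k_Rp_plus": 0.04, "k_Rp_minus": 0.004,
             "k_Mp409_plus": 0.01, "k_Mp409_minus": 0.0}
    specs.append(_ratio_exp(13, "MITF activity inhibition by transfected PIAS3",
                            base_1316, pias3_1316, 0.30, 0.70, initial=_ZERO_MITF))
    specs.append(_ratio_exp(14, "MITF-S73D activity inhibition by PIAS3",
                            {**base_1316, **s73d}, pias3_1316, 0.10, 0.50,
                            initial=_ZERO_MITF))
    specs.append(_ratio_exp(15, "MITF-S409D activity inhibition by PIAS3",
                            {**base_1316, **s409d}, pias3_1316, 0.75, 1.15,
                            initial=_ZERO_MITF))
    specs.append(_ratio_exp(16, "MITF-S73/409D activity inhibition by PIAS3",
                            {**base_1316, **s73d, **s409d}, pias3_1316, 0.45, 0.85,
                            initial=_ZERO_MITF))

    # 17-18 -- PIAS3-STAT3 complex response to stimulation, WT vs S409A MITF
    t17 = {"p_MITF": 10.0, "p_PIAS3": 10.0, "p_STAT3": 10.0}
    t18 = {**t17, **_S409A}
    stim17 = Condition("stim", (Phase(_INCUBATION, perturb(t17)),
                                Phase(15.0, perturb(t17, erkp=1000, jakp=1000))))
    unstim17 = Condition("unstim", (Phase(_INCUBATION + 15.0, perturb(t17)),))
    specs.append(ExperimentSpec(
        17, "PIAS3-STAT3 complex response to stimulation",
        conditions=(stim17, unstim17),
        readouts=(Readout("complex_stim", "stim", "PIAS3_STAT3p"),
                  Readout("complex_unstim", "unstim", "PIAS3_STAT3p")),
        # "at least 25% higher" implies a strict increase, so the factor
        # clause is paired with strict dominance (matters only when both
        # readouts degenerate to zero, e.g. binding-dead parameter draws)
        criterion=(Clause("compare", a="complex_stim", b="complex_unstim",
                          factor=1.25, op="ge",
                          label="complex >=25% higher with stimulation"),
                   Clause("compare", a="complex_stim", b="complex_unstim",
                          op="gt", label="complex strictly higher with stimulation"),),
    ))
    specs.append(ExperimentSpec(
        18, "PIAS3-STAT3 complex with S409A MITF",
        conditions=(
            Condition("wt_stim", stim17.phases),
            Condition("mut_stim", (Phase(_INCUBATION, perturb(t18)),
                                   Phase(15.0, perturb(t18, erkp=1000, jakp=1000)))),
            Condition("mut_unstim", (Phase(_INCUBATION + 15.0, perturb(t18)),)),
        ),
        readouts=(Readout("wt", "wt_stim", "PIAS3_STAT3p"),
                  Readout("mut_stim", "mut_stim", "PIAS3_STAT3p"),
                  Readout("mut_unstim", "mut_unstim", "PIAS3_STAT3p")),
        criterion=(Clause("compare", a="wt", b="mut_stim", factor=1.25, op="ge",
                          label="WT stimulated >=25% above S409A stimulated"),
                   Clause("compare", a="wt", b="mut_stim", op="gt",
                          label="WT stimulated strictly above S409A stimulated"),
                   Clause("compare", a="wt", b="mut_unstim", factor=1.25, op="ge",
                          label="WT stimulated >=25% above S409A unstimulated"),
                   Clause("compare", a="wt", b="mut_unstim", op="gt",
                          label="WT stimulated strictly above S409A unstimulated")),
    ))

    # 19-24 -- STAT3 activity fold-change over an unactivated STAT3-only
    # background; shared experiment-specific record.
    stat_1924 = 5.0
    pias_1924 = 7.0
    mitf_small, mitf_large = 10.0, 50.0
    specs.append(_stat3_fold_exp(
        19, "STAT3 activity in response to activation",
        {"p_STAT3": stat_1924}, 10.0, 20.0))
    specs.append(_stat3_fold_exp(
        20, "STAT3 activity with transfected PIAS3",
        {"p_STAT3": stat_1924, "p_PIAS3": pias_1924}, 2.67, 5.33))
    specs.append(_stat3_fold_exp(
        21, "STAT3 activity with PIAS3 and little MITF",
        {"p_STAT3": stat_1924, "p_PIAS3": pias_1924, "p_MITF": mitf_small},
        2.67, 5.33))
    specs.append(_stat3_fold_exp(
        22, "STAT3 activity with PIAS3 and much MITF",
        {"p_STAT3": stat_1924, "p_PIAS3": pias_1924, "p_MITF": mitf_large},
        6.67, 13.33))
    specs.append(_stat3_fold_exp(
        23, "STAT3 activity with PIAS3 and little S409A MITF",
        {"p_STAT3": stat_1924, "p_PIAS3": pias_1924, "p_MITF": mitf_small,
         **_S409A}, 5.67, 11.33))
    specs.append(_stat3_fold_exp(
        24, "STAT3 activity with PIAS3 and much S409A MITF",
        {"p_STAT3": stat_1924, "p_PIAS3": pias_1924, "p_MITF": mitf_large,
         **_S409A}, 10.0, 20.0))

    # 25 -- MITF activity under STAT3 mutants (inactive Y705F vs active STAT3-C)
    y705f = {"k_Sp_plus": 0.0}
    stat3c_25 = {"k_Sp_plus": 0.02, "k_Sp_minus": 0.0}

    def c25(name: str, mitf: bool, pias3: bool, stat3_mut: Mapping[str, float]):
        over = {"p_MITF": 2.0 if mitf else 0.0,
                "p_PIAS3": 2.0 if pias3 else 0.0,
                "p_STAT3": 20.0, **stat3_mut}
        return Condition(name, (Phase(_INCUBATION, perturb(over)),),
                         initial=_LOW_MITF_PIAS3)

    specs.append(ExperimentSpec(
        25, "MITF activity with Y705F-STAT3 and constitutively active STAT3-C",
        conditions=(c25("i", False, False, y705f),
                    c25("ii", False, False, stat3c_25),
                    c25("iii", True, False, y705f),
                    c25("iv", True, False, stat3c_25),
                    c25("v", True, True, y705f),
                    c25("vi", True, True, stat3c_25)),
        readouts=tuple(Readout(f"f_{n}", n, "MITF_activity")
                       for n in ("i", "ii", "iii", "iv", "v", "vi")),
        criterion=(Clause("ratio_window", num="f_i", den="f_ii", lo=0.5, hi=1.5,
                          label="(i) within 50-150% of (ii)"),
                   Clause("ratio_window", num="f_iii", den="f_iv", lo=0.8, hi=1.2,
                          label="(iii) within 80-120% of (iv)"),
                   Clause("ratio_window", num="f_v", den="f_vi", lo=0.125, hi=1.0,
                          label="(v) within 12.5-100% of (vi)"),
                   Clause("compare", a="f_i", b="f_iii", op="lt",
                          label="(i) below (iii)"),
                   Clause("compare", a="f_iii", b="f_v", factor=2.0, op="gt",
                          label="(iii) above 200% of (v)")),
    ))

    # 26 -- activation response of WT vs binding-dead MITF (mast cells).
    # The mutation is genotypic: it also shapes the resting steady state.
    mut26 = {"k_Mass": 0.0, "k_Mp73ass": 0.0, "k_Mp409ass": 0.0, "k_Mppass": 0.0}
    specs.append(ExperimentSpec(
        26, "MITF and STAT3 activation response, WT vs PIAS3-binding-dead MITF",
        conditions=(Condition("wt", (Phase(240.0, perturb(erkp=1000, jakp=1000)),)),
                    Condition("mut", (Phase(240.0, perturb(mut26, erkp=1000,
                                                           jakp=1000)),),
                              pre_params=_items(mut26))),
        readouts=(Readout("wt_m0", "wt", "MITF_activity", time=0.0),
                  Readout("wt_m30", "wt", "MITF_activity", time=30.0),
                  Readout("wt_s0", "wt", "STAT3_activity", time=0.0),
                  Readout("wt_s240", "wt", "STAT3_activity", time=240.0),
                  Readout("mut_m0", "mut", "MITF_activity", time=0.0),
                  Readout("mut_m30", "mut", "MITF_activity", time=30.0),
                  Readout("mut_m240", "mut", "MITF_activity", time=240.0),
                  Readout("mut_s0", "mut", "STAT3_activity", time=0.0),
                  Readout("mut_s30", "mut", "STAT3_activity", time=30.0),
                  Readout("mut_s240", "mut", "STAT3_activity", time=240.0)),
        criterion=(Clause("compare", a="wt_m30", b="wt_m0", factor=2.0, op="gt",
                          label="WT MITF activity doubled at 30 min"),
                   Clause("compare", a="wt_s240", b="wt_s0", factor=2.0, op="gt",
                          label="WT STAT3 activity doubled at 4 h"),
                   Clause("compare", a="mut_m30", b="mut_m0", factor=2.0, op="lt",
                          label="mutant MITF activity not doubled at 30 min"),
                   Clause("compare", a="mut_m240", b="mut_m0", factor=2.0, op="lt",
                          label="mutant MITF activity not doubled at 4 h"),
                   Clause("compare", a="mut_s30", b="mut_s0", factor=2.0, op="lt",
                          label="mutant STAT3 activity not doubled at 30 min"),
                   Clause("compare", a="mut_s240", b="mut_s0", factor=2.0, op="lt",
                          label="mutant STAT3 activity not doubled at 4 h")),
    ))

    # 27 -- STAT3 activity response to MITF / phospho-mimetic-S409 MITF.
    # Host fibroblasts express no endogenous MITF, so the untransfected
    # arm has zero MITF production (the same convention the experiment-25
    # protocol applies to untransfected genes in this cell line).
    t27 = {"p_STAT3": 5.0}
    s409d_27 = {"k_Mp409_plus": 5.0, "k_Mp409_minus": 0.0}
    specs.append(ExperimentSpec(
        27, "STAT3 activity in response to transfected MITF or S409D-mimic MITF",
        conditions=(
            Condition("base", (Phase(_INCUBATION, perturb({**t27, "p_MITF": 0.0})),)),
            Condition("wt", (Phase(_INCUBATION, perturb({**t27, "p_MITF": 5.0})),)),
            Condition("mut", (Phase(_INCUBATION,
                                    perturb({**t27, "p_MITF": 5.0, **s409d_27})),)),
        ),
        readouts=(Readout("sp_base", "base", "STAT3p"),
                  Readout("sp_wt", "wt", "STAT3p"),
                  Readout("sp_mut", "mut", "STAT3p")),
        criterion=(Clause("compare", a="sp_wt", b="sp_base", op="gt",
                          label="STAT3 activity increased by WT MITF"),
                   Clause("compare", a="sp_mut", b="sp_base", op="gt",
                          label="STAT3 activity increased by mutant MITF"),
                   Clause("compare", a="sp_wt", b="sp_mut", op="gt",
                          label="WT increase exceeds mutant increase")),
    ))

    # 28 -- MITF activity response to constitutively active STAT3 (the
    # phosphorylation-rate x25 reading of STAT3-C, distinct from the
    # absolute 0.02 used in the experiment-25 protocol)
    stat3c_28 = {"k_Sp_plus": 0.0002 * 25, "k_Sp_minus": 0.0}
    specs.append(ExperimentSpec(
        28, "MITF activity in response to transfected STAT3-C",
        conditions=(
            Condition("stat3c", (Phase(_INCUBATION,
                                       perturb({"p_MITF": 5.0, "p_STAT3": 5.0,
                                                **stat3c_28})),)),
            Condition("control", (Phase(_INCUBATION, perturb({"p_MITF": 5.0})),)),
        ),
        readouts=(Readout("act_stat3c", "stat3c", "MITF_activity"),
                  Readout("act_control", "control", "MITF_activity")),
        criterion=(Clause("compare", a="act_stat3c", b="act_control",
                          factor=1.1, op="ge",
                          label="MITF activity increased by >=10%"),),
    ))

    specs.sort(key=lambda s: s.id)
    assert [s.id for s in specs] == list(range(1, 29))
    return tuple(specs)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def spec_to_dict(spec: ExperimentSpec) -> dict:
    return {
        "id": spec.id,
        "description": spec.description,
        "conditions": [
            {
                "name": c.name,
                "steady_state": c.steady_state,
                "initial": [list(x) for x in c.initial],
                "pre_params": [list(x) for x in c.pre_params],
                "phases": [
                    {
                        "duration": ph.duration,
                        "params": [list(x) for x in ph.perturbation.params],
                        "erkp": ph.perturbation.erkp,
                        "jakp": ph.perturbation.jakp,
                        "rsk1_total": ph.perturbation.rsk1_total,
                    }
                    for ph in c.phases
                ],
            }
            for c in spec.conditions
        ],
        "readouts": [
            {"name": r.name, "condition": r.condition,
             "quantity": r.quantity, "time": r.time}
            for r in spec.readouts
        ],
        "criterion": [
            {k: v for k, v in vars(cl).items() if v is not None and v != ""}
            for cl in spec.criterion
        ],
    }


def spec_from_dict(data: dict) -> ExperimentSpec:
    conditions = tuple(
        Condition(
            c["name"],
            tuple(
                Phase(ph["duration"],
                      Perturbation(tuple((k, float(v)) for k, v in ph["params"]),
                                   ph.get("erkp"), ph.get("jakp"),
                                   ph.get("rsk1_total")))
                for ph in c["phases"]
            ),
            initial=tuple((k, float(v)) for k, v in c.get("initial", [])),
            pre_params=tuple((k, float(v)) for k, v in c.get("pre_params", [])),
            steady_state=c.get("steady_state", False),
        )
        for c in data["conditions"]
    )
    readouts = tuple(
        Readout(r["name"], r["condition"], r["quantity"], r.get("time"))
        for r in data["readouts"]
    )
    criterion = tuple(Clause(**cl) for cl in data["criterion"])
    return ExperimentSpec(data["id"], data["description"], conditions,
                          readouts, criterion)


def catalog_to_yaml(path, catalog: tuple[ExperimentSpec, ...] | None = None) -> None:
    """Write the catalog as a human-editable YAML file."""
    import yaml

    catalog = catalog or experiment_catalog()
    with open(path, "w") as fh:
        yaml.safe_dump([spec_to_dict(s) for s in catalog], fh, sort_keys=False)


def catalog_from_yaml(path) -> tuple[ExperimentSpec, ...]:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return tuple(spec_from_dict(d) for d in data)
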