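"""Initialization, time-stepping loop, trajectory recording and scenarios.

The engine wraps the per-step rules of :mod:`ovulesim.dynamics` into a full
run: seeded initialization of the 50-cell file, an explicit-Euler loop with
growth and division interleaved (transport -> growth -> division each step),
snapshot recording every ``record_stride`` steps, and timed multiplicative
parameter perturbations.  Two named perturbation presets mirror the
experimental treatments the model is meant to explain qualitatively:

``npa``
    polar-transport inhibition (the NPA spray): the PIN1 efflux efficiency
    ``E_p`` is rescaled by a small factor at ``t_on``, after which no new
    auxin maxima should arise.
``br``
    enhanced brassinosteroid signalling (*bzr1-1D* / eBL): a larger, faster
    elongating placenta, encoded as an increased growth rate ``r``.

Perturbations are multiplicative and permanent once applied.

The default inner loop for the quasi-steady PIN mode is a numba-compiled
scalar kernel (falling back to pure numpy when numba is unavailable or for
the full-PIN / auxin-coupled variants); a regression test pins the two code
paths to each other.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .dynamics import (
    GROWTH_EXPONENTIAL,
    MODE_QUASI_STEADY,
    ModelParams,
    NumericalInstabilityError,
    PinAllocation,
    TissueState,
    auxin_derivative,
    grow_cells,
    divide_cells,
    pin_relaxation_rate,
    quasi_steady_pins,
)

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly through run_simulation
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

PERTURBABLE = ("E_p", "r", "A", "D_a")

SCENARIOS = ("control", "npa", "br")

#: default time at which the NPA preset switches the parameter on.  The
#: first group of auxin maxima is fully established well before the first
#: division wave (ln(l_div)/r = 138.6 time units with the published
#: parameters), so the preset applies the treatment at t = 130, once every
#: first-group maximum has grown strong but before the wave.  With transport
#: knocked down the maxima are no longer self-sustaining and decay slowly
#: toward the uniform equilibrium, so treating earlier aborts the weakest,
#: still-emerging maxima.
DEFAULT_NPA_T_ON = 130.0


class ConfigError(ValueError):
    """A configuration file contained unknown or invalid keys."""


@dataclass(frozen=True)
class Perturbation:
    """One timed, permanent, multiplicative parameter rescaling."""

    t_on: float
    param: str
    factor: float

    def __post_init__(self) -> None:
        if self.t_on < 0:
            raise ValueError(f"t_on must be >= 0, got {self.t_on}")
        if self.factor <= 0:
            raise ValueError(f"factor must be > 0, got {self.factor}")
        if self.param not in PERTURBABLE:
            raise ValueError(
                f"parameter {self.param!r} is not perturbable; "
                f"choose one of {PERTURBABLE}")


@dataclass
class PerturbationSchedule:
    """Ordered list of timed parameter rescalings applied during a run."""

    entries: List[Perturbation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(
            (e if isinstance(e, Perturbation) else Perturbation(*e)
             for e in self.entries),
            key=lambda e: e.t_on)

    @classmethod
    def none(cls) -> "PerturbationSchedule":
        return cls([])

    @classmethod
    def npa(cls, t_on: float = DEFAULT_NPA_T_ON,
            factor: float = 0.05) -> "PerturbationSchedule":
        """Polar transport inhibition: E_p knocked down at ``t_on``."""
        return cls([Perturbation(t_on, "E_p", factor)])

    @classmethod
    def br(cls, factor: float = 1.5, t_on: float = 0.0) -> "PerturbationSchedule":
        """Enhanced BR signalling: faster placenta elongation from ``t_on``."""
        return cls([Perturbation(t_on, "r", factor)])


@dataclass(frozen=True)
class Event:
    """Something that happened during a run (division wave, perturbation)."""

    t: float
    n_divisions: int
    note: str


@dataclass
class Trajectory:
    """Recorded snapshots of one simulation run plus its event log."""

    params: ModelParams
    snapshots: List[TissueState]
    events: List[Event] = field(default_factory=list)
    clamp_count: int = 0  # negative-concentration clamps (0 for defaults)

    def __post_init__(self) -> None:
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    @property
    def final_state(self) -> TissueState:
        return self.snapshots[-1]

    def division_times(self, min_gap: float = 1.0) -> List[float]:
        """Times of division waves (division events clustered by ``min_gap``).

        With the default synchronous growth all cells divide in the same
        step, so each wave is a single event; the clustering only matters for
        auxin-coupled or perturbed growth where divisions can straggle.
        """
        times = sorted(e.t for e in self.events if e.n_divisions > 0)
        waves: List[float] = []
        for t in times:
            if not waves or t - waves[-1] > min_gap:
                waves.append(t)
        return waves

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (snapshot, cell)."""
        rows = []
        for s in self.snapshots:
            mids = s.midpoints()
            rows.append(pd.DataFrame({
                "time": s.t,
                "cell_index": np.arange(1, s.n_cells + 1),
                "lineage_id": s.lineage,
                "position": mids,
                "length": s.l,
                "auxin": s.a,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def states_from_frame(df: pd.DataFrame) -> List[TissueState]:
        """Rebuild the snapshot list from a long trajectory table."""
        states = []
        for t, grp in df.groupby("time", sort=True):
            grp = grp.sort_values("cell_index")
            states.append(TissueState(
                float(t), grp["auxin"].to_numpy(float),
                grp["length"].to_numpy(float),
                grp["lineage_id"].to_numpy(object)))
        return states


def initialize(params: ModelParams,
               rng: Optional[np.random.Generator] = None) -> TissueState:
    """Seeded initial tissue: N0 cells of length 1 with a shallow noisy field.

    Cell *i* (1-based) starts with
    ``a_i = base_level + grad_amp * (1 - i/N0)**2 + noise_amp * theta_i``,
    ``theta_i ~ U(0, 1)``, i.e. a slightly auxin-richer base (cell 1) than
    apex (cell N0) plus a small frozen perturbation that seeds the
    patterning instability.
    """
    if params.N0 < 3:
        raise ValueError(f"N0 must be >= 3, got {params.N0}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    i = np.arange(1, params.N0 + 1, dtype=float)
    theta = rng.uniform(0.0, 1.0, size=params.N0)
    a = (params.base_level
         + params.grad_amp * (1.0 - i / params.N0) ** 2
         + params.noise_amp * theta)
    l = np.ones(params.N0)
    return TissueState(0.0, a, l)


# ---------------------------------------------------------------------------
# inner loops
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True)
    def _chunk_qss(a, l, A, G_a, D_a, E_p, p_const, r, dt, l_div,
                   max_steps, exponential_growth):  # pragma: no cover
        """Step the quasi-steady model until a division is due, a record
        point is reached (``max_steps``), or an instability appears.

        Returns (steps_done, status, cell) with status 0 = ran to max_steps,
        1 = a cell now exceeds l_div, 2 = non-finite value in ``cell``.
        Negative concentrations are clamped to 0; the clamp count rides in
        ``cell`` when status >= 0.
        """
        N = a.shape[0]
        rate = np.empty(N)
        np_tot = 2.0 * p_const
        clamps = 0
        for s in range(max_steps):
            for i in range(N):
                il = i - 1 if i > 0 else N - 1
                ir = i + 1 if i < N - 1 else 0
                a_l = a[il]
                a_r = a[ir]
                d_i = a_l + a_r
                if d_i <= 0.0:
                    return s, 2, i
                # this cell's membranes
                p_left = np_tot * a_l / d_i
                p_right = np_tot * a_r / d_i
                # neighbours' membranes facing this cell
                dl = a[il - 1 if il > 0 else N - 1] + a[i]
                dr = a[i] + a[ir + 1 if ir < N - 1 else 0]
                p_from_left = np_tot * a[i] / dl
                p_from_right = np_tot * a[i] / dr
                transport = (a[i] * (p_left + p_right)
                             - p_from_left * a_l - p_from_right * a_r)
                diffusion = a_l + a_r - 2.0 * a[i]
                rate[i] = (A - G_a * a[i] - E_p * transport
                           + D_a * diffusion)
            grown = False
            for i in range(N):
                a[i] = a[i] + dt * rate[i]
                if not np.isfinite(a[i]):
                    return s + 1, 2, i
                if a[i] < 0.0:
                    a[i] = 0.0
                    clamps += 1
                if exponential_growth:
                    l[i] = l[i] + dt * r * l[i]
                else:
                    l[i] = l[i] + dt * r
                if l[i] > l_div:
                    grown = True
            if grown:
                return s + 1, 1, clamps
        return max_steps, 0, clamps


def _numpy_step(a: np.ndarray, l: np.ndarray, pins: Optional[PinAllocation],
                params: ModelParams, work: dict) -> Tuple[np.ndarray, np.ndarray,
                                                          Optional[PinAllocation], int]:
    """One generic step on raw arrays (any mode); returns clamp count."""
    state = TissueState(0.0, a, l)
    eff = params.with_updates(**work)
    if eff.mode == MODE_QUASI_STEADY:
        cur = quasi_steady_pins(a, eff)
        new_pins = None
    else:
        cur = pins if pins is not None else quasi_steady_pins(a, eff)
        dpl, dpr = pin_relaxation_rate(a, cur, eff)
        new_pins = PinAllocation(np.maximum(cur.p_left + eff.dt * dpl, 0.0),
                                 np.maximum(cur.p_right + eff.dt * dpr, 0.0))
    rate = auxin_derivative(state, cur, eff)
    a_new = a + eff.dt * rate
    neg = a_new < 0.0
    clamps = int(neg.sum())
    if clamps:
        a_new = np.where(neg, 0.0, a_new)
    factor = np.ones_like(a_new)
    if eff.auxin_coupled_growth:
        m = a_new.mean()
        if m > 0:
            factor = a_new / m
    if eff.growth_law == GROWTH_EXPONENTIAL:
        l_new = l + eff.dt * eff.r * l * factor
    else:
        l_new = l + eff.dt * eff.r * factor
    return a_new, l_new, new_pins, clamps


def _divide_arrays(a, l, lineage, pins, params, work
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray,
                              Optional[PinAllocation], int]:
    state = TissueState(0.0, a, l, lineage, pins)
    eff = params.with_updates(**work)
    new = divide_cells(state, eff)
    return new.a, new.l, new.lineage, new.pins, new.n_cells - state.n_cells


def run_simulation(params: ModelParams,
                   schedule: Optional[PerturbationSchedule] = None,
                   record_stride: int = 500) -> Trajectory:
    """Integrate the model to ``T_end`` and record snapshots.

    Each step applies transport (and PIN relaxation in full-PIN mode), then
    growth, then the division check; schedule entries fire the first time
    ``t`` crosses their ``t_on`` and stay applied.  A snapshot is stored
    every ``record_stride`` steps plus the initial and final states.
    """
    if record_stride < 1:
        raise ValueError("record_stride must be >= 1")
    if params.T_end <= 0:
        raise ValueError("T_end must be > 0")
    schedule = schedule or PerturbationSchedule.none()

    state = initialize(params)
    a, l, lineage = state.a.copy(), state.l.copy(), state.lineage.copy()
    pins: Optional[PinAllocation] = None
    work: dict = {}  # multiplicatively perturbed parameter values
    pending = list(schedule.entries)
    events: List[Event] = []
    snapshots: List[TissueState] = [state.copy()]
    clamp_total = 0

    n_steps = int(math.ceil(params.T_end / params.dt - 1e-9))
    dt = params.dt
    use_fast = (_HAVE_NUMBA and params.mode == MODE_QUASI_STEADY
                and not params.auxin_coupled_growth)

    step = 0
    while step < n_steps:
        t = step * dt
        while pending and pending[0].t_on <= t + 1e-12:
            pert = pending.pop(0)
            base = work.get(pert.param, getattr(params, pert.param))
            work[pert.param] = base * pert.factor
            events.append(Event(t, 0,
                                f"perturbation {pert.param} x{pert.factor}"))
            logger.info("t=%g: applied %s x%g", t, pert.param, pert.factor)
        next_record = record_stride * (step // record_stride + 1)
        chunk = min(next_record, n_steps) - step
        if use_fast:
            eff = {k: work.get(k, getattr(params, k))
                   for k in ("A", "G_a", "D_a", "E_p", "p", "r")}
            if pending:
                chunk = min(chunk, max(1, int(
                    (pending[0].t_on - t) / dt + 0.5)))
            done, status, info = _chunk_qss(
                a, l, eff["A"], eff["G_a"], eff["D_a"], eff["E_p"],
                eff["p"], eff["r"], dt, params.l_div, chunk,
                params.growth_law == GROWTH_EXPONENTIAL)
            step += done
            if status == 2:
                raise NumericalInstabilityError(
                    f"non-finite or degenerate state in cell {info + 1} "
                    f"at step {step}", cell_index=info + 1, step=step)
            clamp_total += info if status in (0, 1) else 0
            if status == 1:
                a, l, lineage, pins, n_new = _divide_arrays(
                    a, l, lineage, pins, params, work)
                events.append(Event(step * dt, n_new,
                                    f"division wave: +{n_new} cells"))
        else:
            sub = chunk
            if pending:
                sub = min(sub, max(1, int((pending[0].t_on - t) / dt + 0.5)))
            for _ in range(sub):
                a, l, pins, clamps = _numpy_step(a, l, pins, params, work)
                clamp_total += clamps
                step += 1
                if not np.all(np.isfinite(a)):
                    i = int(np.argmin(np.isfinite(a)))
                    raise NumericalInstabilityError(
                        f"non-finite auxin in cell {i + 1} at step {step}",
                        cell_index=i + 1, step=step)
                if np.any(l > params.l_div):
                    a, l, lineage, pins, n_new = _divide_arrays(
                        a, l, lineage, pins, params, work)
                    events.append(Event(step * dt, n_new,
                                        f"division wave: +{n_new} cells"))
        if step >= next_record or step >= n_steps:
            snapshots.append(TissueState(step * dt, a.copy(), l.copy(),
                                         lineage.copy(),
                                         pins.copy() if pins else None))
    if clamp_total:
        logger.warning("run clamped %d negative concentration(s) to zero",
                       clamp_total)
    return Trajectory(params, snapshots, events, clamp_total)


@dataclass(frozen=True)
class StabilityReport:
    """Advisory explicit-Euler step-size check (never blocks execution)."""

    value: float
    threshold: float
    warn: bool
    message: str


def stability_check(params: ModelParams) -> StabilityReport:
    """Heuristic stiffness number ``dt * (G_a + 2 D_a + 2 E_p n p)``.

    Values at or above 0.5 suggest the explicit Euler step may be too large;
    the published step (5e-4) gives 2.55e-3.
    """
    value = params.dt * (params.G_a + 2.0 * params.D_a
                         + 2.0 * params.E_p * params.n * params.p)
    warn = value >= 0.5
    msg = (f"stiffness number {value:.3g} "
           + (">= 0.5: explicit Euler step may be unstable; reduce dt"
              if warn else "< 0.5: step size looks safe"))
    if warn:
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return StabilityReport(value, 0.5, warn, msg)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_PARAM_KEYS = tuple(ModelParams.__dataclass_fields__)


def load_config(path) -> Tuple[ModelParams, PerturbationSchedule]:
    """Read a flat YAML mapping of model parameters plus ``perturbations``.

    Unknown keys are errors, to catch typos in parameter names early.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of parameter names")
    pert_raw = raw.pop("perturbations", [])
    unknown = set(raw) - set(_PARAM_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown parameter(s) "
                          f"{sorted(unknown)}; known keys: "
                          f"{sorted(_PARAM_KEYS)}")
    params = ModelParams(**raw)
    entries = []
    for item in pert_raw:
        if not isinstance(item, dict) or set(item) != {"t_on", "param", "factor"}:
            raise ConfigError(f"{path}: each perturbation needs exactly the "
                              "keys t_on, param, factor")
        entries.append(Perturbation(item["t_on"], item["param"],
                                    item["factor"]))
    return params, PerturbationSchedule(entries)


def save_config(path, params: ModelParams,
                schedule: Optional[PerturbationSchedule] = None) -> None:
    data = {k: getattr(params, k) for k in _PARAM_KEYS}
    if schedule and schedule.entries:
        data["perturbations"] = [
            {"t_on": e.t_on, "param": e.param, "factor": e.factor}
            for e in schedule.entries]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def scenario_schedule(name: str, npa_t_on: float = DEFAULT_NPA_T_ON
                      ) -> PerturbationSchedule:
    """Named preset schedules: ``control``, ``npa`` or ``br``."""
    if name == "control":
        return PerturbationSchedule.none()
    if name == "npa":
        return PerturbationSchedule.npa(t_on=npa_t_on)
    if name == "br":
        return PerturbationSchedule.br()
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
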