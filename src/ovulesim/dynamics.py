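"""Core state types and single-step update rules for the 1-D placenta model.

The placenta is modelled as a ring of cells (periodic boundary, each cell has
exactly ``n = 2`` neighbours).  Cell *i* carries an auxin concentration
``a_i`` and a length ``l_i``.  The auxin efflux carrier PIN1 sits on the two
membranes of each cell; its density on the membrane of cell *i* facing
neighbour *j* is ``p_ij``.  Polarization follows the up-the-gradient rule:
PIN1 allocates preferentially toward the neighbour with the higher auxin
level, which destabilises a uniform field into discrete auxin maxima — the
predicted initiation sites of ovule primordia.

Dynamics
--------
Auxin in cell *i* changes as

    da_i/dt = (A - G_a * a_i)
              - E_p * sum_j (p_ij * a_i - p_ji * a_j)
              + D_a * sum_j (a_j - a_i),        j = i +/- 1 on the ring,

i.e. constant synthesis and first-order turnover, PIN1-mediated transport
(the net flux through each interface is antisymmetric, so transport conserves
total auxin), and diffusive exchange between neighbours.

PIN1 relaxes toward an allocation proportional to the neighbours' auxin,

    dp_ij/dt = G_p * (n * p * phi(a_j) / sum_k phi(a_k) - p_ij),
    phi(a) = a,

whose cell total has the stable equilibrium ``n * p``.  In the fast-turnover
limit (``G_p`` large) the allocation is slaved to the auxin field,

    p_ij = n * p * a_j / sum_k a_k,

which is the default ``quasi_steady`` mode; ``full_pin`` integrates the
relaxation explicitly.

Cells grow (exponentially by default, ``dl_i/dt = r * l_i``) and a cell
divides into two equal-length daughters, both inheriting the mother's auxin
concentration, as soon as its length exceeds the threshold ``l_div``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

MODE_QUASI_STEADY = "quasi_steady"
MODE_FULL_PIN = "full_pin"
GROWTH_EXPONENTIAL = "exponential"
GROWTH_LINEAR = "linear"


class DegenerateAllocationError(ValueError):
    """Both neighbours of a cell have zero auxin: PIN1 allocation undefined.

    This signals a dead tissue state rather than being silently split 50/50.
    """


class NumericalInstabilityError(RuntimeError):
    """The explicit integration produced a non-finite value."""

    def __init__(self, message: str, cell_index: Optional[int] = None,
                 step: Optional[int] = None):
        super().__init__(message)
        self.cell_index = cell_index  # 1-based, as reported everywhere
        self.step = step


@dataclass
class ModelParams:
    """Every constant of the transport/growth model plus simulation controls.

    Defaults are the published parameter set: ``dt = 5e-4``, ``D_a = 0.5``,
    ``p = 1``, ``E_p = 1``, ``G_a = 0.1``, ``l_div = 4``, ``r = 0.01`` and an
    initial file of ``N0 = 50`` cells of length 1 with auxin
    ``a_i = base_level + grad_amp * (1 - i/N0)**2 + noise_amp * theta_i``,
    ``theta_i ~ U(0, 1)``.  The synthesis rate ``A`` is not published; it
    defaults to ``G_a * 1.0`` so the uniform equilibrium is ``a* = A/G_a = 1``,
    inside the initial 0.95–1.0 band.
    """

    A: float = 0.1                      # auxin synthesis rate [conc / time]
    G_a: float = 0.1                    # auxin degradation rate [1 / time]
    D_a: float = 0.5                    # neighbour diffusion coefficient [1 / time]
    E_p: float = 1.0                    # PIN1 efflux efficiency [1 / (PIN density * time)]
    p: float = 1.0                      # PIN1 density constant [PIN density]
    G_p: float = 10.0                   # PIN1 turnover rate (full_pin mode) [1 / time]
    n: int = 2                          # neighbours per cell (1-D ring)
    r: float = 0.01                     # cell growth rate [1 / time]
    l_div: float = 4.0                  # division length threshold [cell lengths]
    dt: float = 5e-4                    # explicit Euler step [time]
    N0: int = 50                        # initial cell count
    base_level: float = 0.95            # initial-condition coefficients
    grad_amp: float = 0.03
    noise_amp: float = 0.02
    seed: Optional[int] = 0             # RNG seed for the initial noise
    mode: str = MODE_QUASI_STEADY
    T_end: float = 250.0                # simulation horizon [time]
    growth_law: str = GROWTH_EXPONENTIAL
    auxin_coupled_growth: bool = False  # scale growth rate by a_i / mean(a)

    def __post_init__(self) -> None:
        for name in ("A", "G_a", "D_a", "E_p", "p", "G_p", "r"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0, "
                                 f"got {getattr(self, name)}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.l_div <= 1:
            raise ValueError(f"l_div must be > 1, got {self.l_div}")
        if self.N0 < 3:
            raise ValueError(f"N0 must be >= 3, got {self.N0}")
        if self.n != 2:
            raise ValueError("only n = 2 (1-D ring) is supported")
        if self.mode not in (MODE_QUASI_STEADY, MODE_FULL_PIN):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.growth_law not in (GROWTH_EXPONENTIAL, GROWTH_LINEAR):
            raise ValueError(f"unknown growth_law {self.growth_law!r}")
        if self.T_end <= 0:
            raise ValueError(f"T_end must be > 0, got {self.T_end}")

    def with_updates(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class PinAllocation:
    """PIN1 densities on the two membranes of every cell.

    ``p_left[i]`` faces neighbour ``i-1`` and ``p_right[i]`` faces ``i+1``
    (ring indices).  In ``quasi_steady`` mode these are derived from the auxin
    field; in ``full_pin`` mode they are state variables.
    """

    p_left: np.ndarray
    p_right: np.ndarray

    def __post_init__(self) -> None:
        self.p_left = np.asarray(self.p_left, dtype=float)
        self.p_right = np.asarray(self.p_right, dtype=float)
        if self.p_left.shape != self.p_right.shape:
            raise ValueError("p_left and p_right must have the same shape")
        if np.any(self.p_left < 0) or np.any(self.p_right < 0):
            raise ValueError("PIN densities must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.p_left.size

    def copy(self) -> "PinAllocation":
        return PinAllocation(self.p_left.copy(), self.p_right.copy())


@dataclass
class TissueState:
    """The ordered, periodic file of cells at time ``t``.

    ``a`` and ``l`` are per-cell auxin concentrations and lengths in ring
    order; ``lineage`` holds stable string identifiers where daughters of
    cell ``"7"`` are ``"7.1"`` and ``"7.2"``.  Cell indices reported to users
    are 1-based (cell 1 = base of the placenta).
    """

    t: float
    a: np.ndarray
    l: np.ndarray
    lineage: np.ndarray = field(default=None)  # type: ignore[assignment]
    pins: Optional[PinAllocation] = None       # carried state in full_pin mode

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.l = np.asarray(self.l, dtype=float)
        if self.a.ndim != 1 or self.a.shape != self.l.shape:
            raise ValueError("a and l must be 1-D arrays of equal length")
        if self.a.size < 3:
            raise ValueError("a tissue needs at least 3 cells")
        if np.any(self.l <= 0):
            raise ValueError("all cell lengths must be strictly positive")
        if np.any(self.a < 0):
            raise ValueError("auxin concentrations must be >= 0")
        if self.lineage is None:
            self.lineage = np.array([str(i + 1) for i in range(self.a.size)],
                                    dtype=object)
        else:
            self.lineage = np.asarray(self.lineage, dtype=object)
            if self.lineage.shape != self.a.shape:
                raise ValueError("lineage must match the cell count")

    @property
    def n_cells(self) -> int:
        return self.a.size

    @property
    def total_length(self) -> float:
        return float(self.l.sum())

    @property
    def total_auxin(self) -> float:
        """Total auxin amount, sum_i a_i * l_i."""
        return float((self.a * self.l).sum())

    def midpoints(self) -> np.ndarray:
        """Cell-midpoint coordinates (origin at the base of cell 1)."""
        edges = np.cumsum(self.l)
        return edges - self.l / 2.0

    def copy(self) -> "TissueState":
        return TissueState(self.t, self.a.copy(), self.l.copy(),
                           self.lineage.copy(),
                           self.pins.copy() if self.pins is not None else None)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pin_allocation(a_left: float, a_right: float,
                   params: ModelParams) -> tuple[float, float]:
    """Quasi-steady PIN1 split of one cell between its two membranes.

    Returns ``(p_left, p_right) = n*p*(a_left, a_right) / (a_left + a_right)``;
    the membrane sum is exactly ``n * p`` regardless of the auxin values.
    """
    if a_left < 0 or a_right < 0:
        raise ValueError("neighbour auxin concentrations must be >= 0")
    denom = a_left + a_right
    if denom == 0.0:
        raise DegenerateAllocationError(
            "both neighbour auxin concentrations are zero; "
            "PIN1 allocation is undefined (dead tissue state)")
    np_tot = params.n * params.p
    return np_tot * a_left / denom, np_tot * a_right / denom


def quasi_steady_pins(a: np.ndarray, params: ModelParams) -> PinAllocation:
    """Vectorised quasi-steady allocation for a whole ring of cells."""
    a_l = np.roll(a, 1)    # neighbour i-1 of each cell
    a_r = np.roll(a, -1)   # neighbour i+1
    denom = a_l + a_r
    if np.any(denom == 0.0):
        i = int(np.argmax(denom == 0.0))
        raise DegenerateAllocationError(
            f"cell {i + 1}: both neighbours have zero auxin")
    np_tot = params.n * params.p
    return PinAllocation(np_tot * a_l / denom, np_tot * a_r / denom)


def pin_relaxation_rate(a: np.ndarray, pins: PinAllocation,
                        params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """d p_ij / dt in full_pin mode: relaxation toward the auxin-weighted target."""
    target = quasi_steady_pins(a, params)
    return (params.G_p * (target.p_left - pins.p_left),
            params.G_p * (target.p_right - pins.p_right))


def auxin_derivative(state: TissueState, pins: PinAllocation,
                     params: ModelParams) -> np.ndarray:
    """Per-cell da_i/dt: synthesis/turnover + PIN1 transport + diffusion.

    The transport and diffusion terms are antisymmetric per interface, so the
    derivative sums to ``N*A - G_a * sum_i a_i`` exactly.
    """
    a = state.a
    if pins.n_cells != state.n_cells:
        raise ValueError(f"pins ({pins.n_cells} cells) inconsistent with "
                         f"state ({state.n_cells} cells)")
    a_l = np.roll(a, 1)
    a_r = np.roll(a, -1)
    # efflux through both membranes minus influx from both neighbours
    transport = (a * (pins.p_left + pins.p_right)
                 - np.roll(pins.p_right, 1) * a_l
                 - np.roll(pins.p_left, -1) * a_r)
    diffusion = a_l + a_r - 2.0 * a
    return (params.A - params.G_a * a
            - params.E_p * transport
            + params.D_a * diffusion)


def euler_step(state: TissueState, params: ModelParams) -> TissueState:
    """One explicit (forward Euler) step of the auxin (and PIN1) equations.

    In ``quasi_steady`` mode PIN1 is recomputed from the current auxin field
    before the step; in ``full_pin`` mode the carried PIN1 state advances by
    its own relaxation equation.  Negative concentrations produced by an
    overshoot are clamped to zero with a logged warning.
    """
    if params.dt <= 0:
        raise ValueError(f"dt must be > 0, got {params.dt}")
    dt = params.dt
    if params.mode == MODE_QUASI_STEADY:
        pins = quasi_steady_pins(state.a, params)
        new_pins = None
    else:
        pins = state.pins if state.pins is not None \
            else quasi_steady_pins(state.a, params)
        dpl, dpr = pin_relaxation_rate(state.a, pins, params)
        new_pins = PinAllocation(np.maximum(pins.p_left + dt * dpl, 0.0),
                                 np.maximum(pins.p_right + dt * dpr, 0.0))
    rate = auxin_derivative(state, pins, params)
    a_new = state.a + dt * rate
    if not np.all(np.isfinite(a_new)):
        i = int(np.argmin(np.isfinite(a_new)))
        raise NumericalInstabilityError(
            f"non-finite auxin concentration in cell {i + 1} at t={state.t}",
            cell_index=i + 1)
    neg = a_new < 0.0
    if np.any(neg):
        logger.warning("clamped %d negative auxin concentration(s) to 0 at "
                       "t=%g (first: cell %d)", int(neg.sum()), state.t,
                       int(np.argmax(neg)) + 1)
        a_new = np.where(neg, 0.0, a_new)
    return TissueState(state.t + dt, a_new, state.l.copy(),
                       state.lineage.copy(), new_pins)


def grow_cells(state: TissueState, params: ModelParams) -> TissueState:
    """Advance cell lengths by one step of the growth law.

    Exponential (default): ``l_i <- l_i + dt * r * l_i``; linear:
    ``l_i <- l_i + dt * r``.  With ``auxin_coupled_growth`` the rate is
    additionally scaled by ``a_i / mean(a)``.
    """
    if params.r < 0:
        raise ValueError("growth rate r must be >= 0")
    factor = np.ones_like(state.a)
    if params.auxin_coupled_growth:
        mean_a = state.a.mean()
        if mean_a > 0:
            factor = state.a / mean_a
    if params.growth_law == GROWTH_EXPONENTIAL:
        l_new = state.l + params.dt * params.r * state.l * factor
    else:
        l_new = state.l + params.dt * params.r * factor
    return TissueState(state.t, state.a.copy(), l_new, state.lineage.copy(),
                       state.pins.copy() if state.pins is not None else None)


def divide_cells(state: TissueState, params: ModelParams) -> TissueState:
    """Split every cell longer than ``l_div`` into two equal daughters.

    Daughters are placed in ring order in place of the mother, each of length
    ``l_i / 2`` and carrying the mother's auxin concentration, so total tissue
    length and total auxin amount (sum a_i * l_i) are both preserved exactly.
    The comparison is strict (``l > l_div``).
    """
    dividing = state.l > params.l_div
    if not np.any(dividing):
        return state.copy()
    counts = np.where(dividing, 2, 1)
    a_new = np.repeat(state.a, counts)
    l_new = np.repeat(state.l / counts, counts)
    lineage_new = []
    for lid, div in zip(state.lineage, dividing):
        if div:
            lineage_new.extend((f"{lid}.1", f"{lid}.2"))
        else:
            lineage_new.append(lid)
    pins_new = None
    if state.pins is not None:
        # daughters inherit the mother's membrane densities on the outer
        # faces; the new shared interface starts at the symmetric split
        pl = np.repeat(state.pins.p_left, counts)
        pr = np.repeat(state.pins.p_right, counts)
        idx = np.cumsum(counts) - counts  # first daughter position
        for i in np.flatnonzero(dividing):
            j = idx[i]
            half = params.n * params.p / 2.0
            pr[j] = half
            pl[j + 1] = half
        pins_new = PinAllocation(pl, pr)
    return TissueState(state.t, a_new, l_new,
                       np.array(lineage_new, dtype=object), pins_new)
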