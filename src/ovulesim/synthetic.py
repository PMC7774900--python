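"""Seeded generators for morphometric tables and profile fixtures.

Two kinds of synthetic data make every analysis stage testable without any
measured input:

* placenta measurement tables whose statistical structure follows the
  reported stage course — ovule counts of 4–6 per placenta at stage 9a,
  7–9 at 9b and 10–14 at 9c; shape-class mixtures that shift from all-O1 at
  9a through mixed batches to O2/O3 only by stage 10; alternating
  older/younger batches along the placenta; a ~180 µm stage-9a placenta; and
  first-primordium positions drawn from the lower/middle/top thirds with
  weights 0.455/0.476/0.069;
* tissue states and profile sequences with planted auxin maxima of known
  position and group, used as ground truth for the detection and tracking
  code.

Every generator is a pure function of its parameters and seed, so
regeneration is bit-identical.  Class-conditional aspect-ratio ranges are
chosen strictly inside the default classifier cuts (0.75, 4/3) so that
zero-noise recovery of the generated classes is exact; changing the
classifier thresholds can silently break that correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import TissueState
from .profiles import AuxinProfile

TRUTH_COLUMNS = ["truth_class", "truth_batch", "truth_first"]

#: class-conditional aspect-ratio (height / basal diameter) ranges, strictly
#: inside the default O1/O2/O3 cuts of 0.75 and 4/3
RHO_RANGES = {"O1": (0.2, 0.6), "O2": (0.85, 1.15), "O3": (1.6, 3.0)}


@dataclass(frozen=True)
class StageSpec:
    """Ovule count range and batch composition of one floral stage.

    ``batch_classes[b]`` is the shape class of initiation batch ``b + 1``
    (batch 1 = oldest).  Older batches sit at alternating ranks along the
    placenta; younger batches fill the ranks in between.
    """

    count_range: Tuple[int, int]
    batch_classes: Tuple[str, ...]

    def __post_init__(self) -> None:
        lo, hi = self.count_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid count range {self.count_range}")
        if not self.batch_classes:
            raise ValueError("need at least one batch class")
        for c in self.batch_classes:
            if c not in RHO_RANGES:
                raise ValueError(f"unknown shape class {c!r}")


DEFAULT_STAGES: Dict[str, StageSpec] = {
    "9a": StageSpec((4, 6), ("O1",)),
    "9b": StageSpec((7, 9), ("O2", "O1")),
    "9c": StageSpec((10, 14), ("O3", "O2", "O1")),
    "10": StageSpec((10, 14), ("O3", "O2")),
}

#: per-stage placenta length mean/sd in µm; the stage-9a mean is the
#: measured ~180 µm anchor, later stages are plausible placeholders for an
#: elongating placenta
DEFAULT_PLACENTA_LENGTH = {
    "9a": (180.0, 15.0),
    "9b": (230.0, 20.0),
    "9c": (290.0, 25.0),
    "10": (330.0, 30.0),
}

DEFAULT_THIRDS_WEIGHTS = (0.455, 0.476, 0.069)


@dataclass
class GeneratorParams:
    """Knobs of the morphometric table generator."""

    seed: int = 0
    stages: Dict[str, StageSpec] = field(
        default_factory=lambda: dict(DEFAULT_STAGES))
    placenta_length: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLACENTA_LENGTH))
    noise_sigma: float = 0.05            # multiplicative noise on sizes
    thirds_weights: Tuple[float, float, float] = DEFAULT_THIRDS_WEIGHTS
    alternation: bool = True             # alternate batches along the placenta
    diameter_mean: float = 20.0          # µm, basal diameter scale
    diameter_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        w = np.asarray(self.thirds_weights, dtype=float)
        if w.size != 3 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("thirds_weights must be 3 non-negative values "
                             "summing to 1")


def _batch_pattern(k: int, n_batches: int, anchor_rank: int,
                   alternate: bool, rng: np.random.Generator) -> np.ndarray:
    """Batch label (1-based) per rank 1..k.

    Batch 1 occupies every other rank starting at ``anchor_rank``; the
    remaining ranks cycle through the younger batches.  Without alternation
    the same label multiset is shuffled (keeping batch 1 at the anchor).
    """
    batches = np.zeros(k, dtype=int)
    young = [b for b in range(2, n_batches + 1)] or [1]
    yi = 0
    for rank in range(1, k + 1):
        if (rank - anchor_rank) % 2 == 0:
            batches[rank - 1] = 1
        else:
            batches[rank - 1] = young[yi % len(young)]
            yi += 1
    if not alternate:
        others = [i for i in range(k) if i != anchor_rank - 1]
        perm = rng.permutation(len(others))
        vals = batches[others]
        batches[others] = vals[perm]
    return batches


def generate_placenta_table(gp: GeneratorParams, n_placentae: int,
                            stage: str) -> pd.DataFrame:
    """Measurement table for ``n_placentae`` placentae at one floral stage.

    Output schema is the morphometrics input schema plus ground-truth
    columns ``truth_class`` (generating shape class), ``truth_batch``
    (initiation batch, 1 = oldest) and ``truth_first`` (the single
    first-initiated primordium per placenta, whose placenta third is drawn
    from ``thirds_weights`` and whose position is uniform within that
    third).
    """
    if stage not in gp.stages:
        raise ValueError(f"no stage spec for {stage!r}; known: "
                         f"{sorted(gp.stages)}")
    spec = gp.stages[stage]
    lmean, lsd = gp.placenta_length.get(stage, (180.0, 15.0))
    rng = np.random.default_rng(gp.seed)
    rows: List[dict] = []
    for pi in range(n_placentae):
        k = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
        L = max(float(rng.normal(lmean, lsd)), 10.0 * k)
        # first-initiated primordium: third from the weights, position
        # uniform inside that third
        third = int(rng.choice(3, p=gp.thirds_weights))
        pos_first = float(rng.uniform(third * L / 3.0,
                                      (third + 1) * L / 3.0))
        slots = (np.arange(1, k + 1) - 0.5) / k * L
        drop = int(np.argmin(np.abs(slots - pos_first)))
        others = np.delete(slots, drop)
        others = others + rng.uniform(-0.2, 0.2, size=others.size) * L / k
        others = np.clip(others, 0.0, L)
        positions = np.sort(np.append(others, pos_first))
        rank_first = int(np.searchsorted(positions, pos_first)) + 1
        batches = _batch_pattern(k, len(spec.batch_classes), rank_first,
                                 gp.alternation, rng)
        for rank in range(1, k + 1):
            batch = batches[rank - 1]
            cls = spec.batch_classes[batch - 1]
            lo, hi = RHO_RANGES[cls]
            rho = float(rng.uniform(lo, hi))
            diameter = max(float(rng.normal(gp.diameter_mean,
                                            gp.diameter_sd)), 5.0)
            is_first = rank == rank_first
            if is_first:
                diameter *= 1.15  # the first-initiated primordium leads
            height = rho * diameter
            if gp.noise_sigma > 0:
                diameter *= float(np.exp(gp.noise_sigma * rng.normal()))
                height *= float(np.exp(gp.noise_sigma * rng.normal()))
            rows.append({
                "placenta_id": f"{stage}-{pi + 1}",
                "stage": stage,
                "order_index": rank,
                "basal_diameter": diameter,
                "height": height,
                "position": float(positions[rank - 1]),
                "placenta_length": L,
                "truth_class": cls,
                "truth_batch": int(batch),
                "truth_first": is_first,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profile / trajectory fixtures
# ---------------------------------------------------------------------------

#: smooth unimodal bump over the two cells either side of the centre
_BUMP_OFFSETS = np.arange(-2, 3)
_BUMP_WEIGHTS = np.cos(np.pi * _BUMP_OFFSETS / 5.0)


def generate_profile_fixture(n_cells: int,
                             peak_positions: Sequence[int],
                             peak_height: float = 1.0,
                             seed: int = 0,
                             jitter: float = 1e-3) -> TissueState:
    """Tissue state with planted auxin bumps at the requested cells.

    Baseline auxin 1.0, unit cell lengths, a smooth bump of the given height
    centred on each 1-based cell index, plus tiny seeded jitter.  Peaks
    closer than 3 cells apart on the ring would merge and are rejected.
    With no peaks the state is exactly flat (no jitter), since maxima
    detection is scale-invariant and would otherwise fire on the jitter.
    """
    if peak_height <= 0:
        raise ValueError("peak_height must be > 0")
    peaks = sorted(int(c) for c in peak_positions)
    for c in peaks:
        if not 1 <= c <= n_cells:
            raise ValueError(f"peak position {c} outside 1..{n_cells}")
    for u, v in zip(peaks, peaks[1:] + [peaks[0] + n_cells] if peaks else []):
        if v - u < 3:
            raise ValueError(f"peaks at cells {u} and {v % n_cells or n_cells} "
                             "are closer than 3 cells")
    if not peaks:
        return TissueState(0.0, np.ones(n_cells), np.ones(n_cells))
    rng = np.random.default_rng(seed)
    a = np.ones(n_cells) + jitter * rng.uniform(-1.0, 1.0, size=n_cells)
    for c in peaks:
        idx = (c - 1 + _BUMP_OFFSETS) % n_cells
        a[idx] += peak_height * _BUMP_WEIGHTS
    return TissueState(0.0, a, np.ones(n_cells))


def _ring_bumps(x: np.ndarray, L: float, centres_rel: Sequence[float],
                heights: Sequence[float], width_rel: float) -> np.ndarray:
    v = np.ones_like(x)
    for c, h in zip(centres_rel, heights):
        d = np.abs(x / L - c)
        d = np.minimum(d, 1.0 - d)
        v += h * np.exp(-0.5 * (d / width_rel) ** 2)
    return v


def generate_two_phase_tracks(seed: int = 0, k1: int = 3,
                              frames_per_phase: int = 4,
                              L1: float = 30.0,
                              n_samples: int = 300,
                              new_height: float = 0.6,
                              ) -> Tuple[List[AuxinProfile], pd.DataFrame]:
    """Two-phase profile sequence mimicking group-wise maxima emergence.

    Phase 1 frames carry ``k1`` persistent peaks at equally spaced ring
    positions on a tissue of length ``L1``; phase 2 frames double the tissue
    length and add a new peak at the midpoint between each pair of old
    peaks.  Returns the profiles and a ground-truth table (relative
    position, group) for recovery tests.  With ``new_height = 0`` no second
    group exists.
    """
    if k1 < 2:
        raise ValueError("k1 must be >= 2")
    rng = np.random.default_rng(seed)
    old_rel = [(i + 0.5) / k1 for i in range(k1)]
    new_rel = [(i + 1.0) / k1 % 1.0 for i in range(k1)]
    profiles: List[AuxinProfile] = []
    t = 0.0
    for _ in range(frames_per_phase):
        x = np.linspace(0.0, L1, n_samples)
        v = _ring_bumps(x, L1, old_rel, [1.0] * k1, 0.02)
        v += 1e-4 * rng.uniform(-1, 1, size=x.size)
        profiles.append(AuxinProfile(t, x, v, L1))
        t += 1.0
    L2 = 2.0 * L1
    heights2 = [new_height] * k1 if new_height > 0 else []
    centres2 = new_rel if new_height > 0 else []
    for _ in range(frames_per_phase):
        x = np.linspace(0.0, L2, n_samples)
        v = _ring_bumps(x, L2, old_rel + centres2,
                        [1.0] * k1 + heights2, 0.01)
        v += 1e-4 * rng.uniform(-1, 1, size=x.size)
        profiles.append(AuxinProfile(t, x, v, L2))
        t += 1.0
    truth = pd.DataFrame(
        [{"rel": r, "group": 1} for r in old_rel]
        + [{"rel": r, "group": 2} for r in centres2])
    return profiles, truth
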