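# Methods

## Model

The placenta is idealised as a one-dimensional file of cells with periodic
topology (a ring; every cell has exactly two neighbours).  The state of
cell *i* is its auxin concentration `a_i` (well mixed within the cell) and
its length `l_i`.  PIN1, the auxin efflux carrier, sits on the two
membranes of each cell with densities `p_ij` (facing neighbour *j*).

Auxin changes by three processes:

```
da_i/dt = (A − G_a a_i)                        synthesis and turnover
          − E_p Σ_j (p_ij a_i − p_ji a_j)      PIN1-mediated transport
          + D_a Σ_j (a_j − a_i)                diffusive exchange
```

The transport flux through each interface is antisymmetric, so transport
and diffusion conserve the summed concentration; `Σ_i da_i/dt =
N·A − G_a·Σ_i a_i` holds identically and is asserted in tests.

PIN1 polarises **up the gradient**: its allocation relaxes toward a split
proportional to the neighbours' auxin,

```
dp_ij/dt = G_p (n p φ(a_j) / Σ_k φ(a_k) − p_ij),    φ(a) = a,
```

whose per-cell total has the stable equilibrium `n p`.  In the
fast-turnover limit (`G_p` large) the allocation is slaved to the auxin
field, `p_ij = n p a_j / Σ_k a_k`, with `Σ_j p_ij = n p` exact; this
`quasi_steady` mode is the default.  A `full_pin` mode integrates the
relaxation explicitly (default `G_p = 10`) for model exploration; a test
pins it to the quasi-steady limit at large `G_p`.

Cells grow exponentially, `dl_i/dt = r l_i` (a linear law and an optional
auxin-coupled modifier `× a_i/mean(a)` are selectable but off by default),
and a cell divides into two equal-length daughters carrying the mother's
concentration as soon as `l_i > l_div` (strict inequality).  Division
preserves total length and total auxin amount `Σ a_i l_i` exactly.
Transport and diffusion coefficients are per-cell-interface constants and
do not scale with cell length — a deliberate simplification consistent
with the dimensionless parameter set; consequently the pattern's preferred
spacing is set in units of *cell number*, not physical length.

### Why patterns form, and why groups

Linearising around the uniform state `a* = A/G_a` gives the growth rate
`λ(k) = −G_a + 2(1 − cos k)(E_p cos k − D_a)` for a perturbation of
wavenumber *k* (in cells⁻¹).  With the default parameters the band around
`cos k = 3/4` (wavelength ≈ 9 cells) is unstable, so a 50-cell file
supports 5–6 maxima — the first group.  Growth does not change the cell
count, but each synchronous division wave doubles it; the pattern, frozen
in cell-index space, then has ~18-cell gaps in which new maxima grow — the
second group, appearing between older maxima.  This is the mechanism the
test suite probes qualitatively (group counts, birth epochs, flanking).

## Parameters

| name | meaning | unit | default |
| --- | --- | --- | --- |
| `A` | auxin synthesis rate | conc·time⁻¹ | 0.1 |
| `G_a` | auxin turnover rate | time⁻¹ | 0.1 |
| `D_a` | neighbour diffusion | time⁻¹ | 0.5 |
| `E_p` | PIN1 efflux efficiency | (PIN·time)⁻¹ | 1 |
| `p` | PIN1 density constant | PIN | 1 |
| `G_p` | PIN1 turnover (full-PIN mode) | time⁻¹ | 10 |
| `r` | cell growth rate | time⁻¹ | 0.01 |
| `l_div` | division threshold | cell length | 4 |
| `dt` | Euler step | time | 5·10⁻⁴ |
| `N0` | initial cell count | — | 50 |
| `T_end` | horizon | time | 250 |

All values except `A`, `G_p` and `T_end` are the published set.  `A` is
chosen as `G_a · 1` so the uniform equilibrium is `a* = 1`, inside the
initial 0.95–1.0 band (the up-the-gradient instability rate is invariant
under rescaling `a*`, so this choice only fixes the scale).  `T_end = 250`
covers the establishment of the first group (by t ≈ 25), two synchronous
division waves (`ln(l_div)/r ≈ 138.6` and ≈ 207.9; all cells start at the
same length and grow at the same relative rate, so they divide in the same
step) and the growth of later-group maxima.

The initial field is `a_i = 0.95 + 0.03 (1 − i/N0)² + 0.02 θ_i` with
`θ_i ~ U(0,1)` drawn once per cell from the seeded generator: a slightly
auxin-richer base plus frozen noise that seeds the instability.  Cell
indices are 1-based in all reported output; cell 1 is the base.

## Numerics

The coupled equations are advanced by explicit (forward) Euler with the
published step.  An advisory stiffness check warns when
`dt (G_a + 2 D_a + 2 E_p n p) ≥ 0.5` (the default gives 2.6·10⁻³) but
never blocks execution.  Per step the order is transport → growth →
division check.  Negative concentrations from an overshoot are clamped to
zero with a logged warning (the default parameters never trigger this,
which a test asserts); non-finite values abort with the offending cell and
step.  The default inner loop is a numba-compiled scalar kernel; a
pure-numpy generic path covers the full-PIN and auxin-coupled variants and
machines without numba, and a regression test holds the two paths
together at 10⁻¹².  Timed perturbations are multiplicative, permanent once
applied, and restricted to `E_p`, `r`, `A`, `D_a`.

## Profile analysis

Snapshots become spatial profiles by cubic-spline interpolation through
the cell midpoints (cumulative-length coordinate).  End conditions are
not-a-knot on the unwrapped coordinate — matching how the placenta is
displayed as a line even though the dynamics are periodic — but one ghost
knot from the ring is appended beyond each end so the evaluated span
[0, L] is interior to the knots: bare cubic extrapolation past the
outermost midpoints is wildly unreliable.  The spline passes exactly
through every midpoint.

Maxima are interior local maxima with topographic prominence at least
`min_prominence_frac` (default 0.05) of the profile's range, computed on
three wrapped periods of the samples so ring wrap-around is handled;
detection is therefore invariant to shifting or uniformly rescaling the
field.  Because the criterion is *relative*, the earliest frames — where
the field is frozen initial noise — yield many shallow maxima; these die
within a few frames and are separated from real pattern maxima by the
track-stability flag below.  A small-amplitude but well-shaped pattern
remains detectable; detection says nothing about absolute auxin levels.

Tracking links maxima of consecutive frames by nearest relative position
(`|Δ(x/L)|`, ring metric, tolerance `match_tol = 0.02`), tolerating up to
2 undetected frames.  Group assignment uses the run's division waves as
epoch boundaries: tracks born before the first wave are group 1, tracks
first seen between waves *k* and *k+1* are group *k+1*.  A track is
*stable* if it is still detected in the last frame of its birth epoch;
noise tracks from the early frames fail this, first-group maxima satisfy
it.  When no division times are supplied (synthetic fixtures), frame-0
tracks are group 1 and later births group 2.  The `flanking_check`
statistic is the fraction of group ≥ 2 tracks whose nearest tracked maxima
on both sides (ring metric, at the birth frame) are distinct tracks of a
strictly older group — the quantitative form of "new primordia arise
between older neighbouring ones".

## Perturbation scenarios

**NPA (polar-transport inhibition).**  `E_p` is rescaled by 0.05 at
`t_on = 130`, once every first-group maximum is established but before the
first division wave.  With transport knocked down, no mode of the
linearised system grows (`E_p cos k < D_a` for all *k*), so existing
maxima are not self-sustaining: they decay toward the uniform state while
keeping their positions, and remain detectable until the slower-decaying
long-wavelength residual overtakes them — roughly 50–70 time units.  The
scenario is therefore read out at `T_end = 200`, a window that spans the
first division wave and the epoch in which control runs initiate their
second group.  Within it, no new stable maxima arise and the established
ones persist; treating much earlier instead aborts the weakest,
still-emerging maxima.  This matches the experimental observation window
(days after spraying), not an asymptotic state: run long enough, the
transport-free model relaxes to uniformity, which is a known limitation of
a pure auxin-field model — real primordia are committed structures whose
growth no longer depends on the auxin maximum that induced them.

**BR (enhanced brassinosteroid signalling).**  The preset scales the
growth rate `r` by 1.5, giving a placenta that elongates faster, divides
more often and keeps initiating new maxima.  Faster elongation alone does
*not* increase the number of maxima at a fixed horizon: the count is set
by the unstable wavelength in cell-index space and by the instability's
growth rate, and division waves arriving faster than new maxima can grow
leave the count unchanged.  The enlarged primordium number of
BR-enhanced tissue is reproduced instead by the mutant's other phenotype —
a placenta that is already larger when patterning starts: raising the
initial cell count (e.g. `N0 = 65` vs 50) robustly increases the number of
initiated maxima, which the scenario tests assert.

## Synthetic measurement tables

The generator emulates the reported stage course: ovule counts per
placenta drawn uniformly from 4–6 (stage 9a), 7–9 (9b) and 10–14 (9c and
10); batch composition all-O1 at 9a, O2+O1 at 9b, O3+O2+O1 at 9c and
O3+O2 at stage 10, with older batches at alternating ranks along the
placenta; placenta length ~N(180, 15) µm at 9a (the measured anchor; later
stages use plausible placeholder means of 230/290/330 µm); the
first-initiated primordium's placenta third drawn with weights
0.455/0.476/0.069 (lower/middle/top) and its position uniform within that
third.  Shape follows class-conditional aspect ratios ρ = height/diameter
drawn from U(0.2, 0.6) for O1, U(0.85, 1.15) for O2 and U(1.6, 3.0) for
O3 — strictly inside the classifier's default cuts (0.75 and 4/3), so
zero-noise recovery is exact by construction; multiplicative lognormal
noise (`σ = 0.05` default) on height and diameter perturbs ρ by ~7%
(√2·σ), leaving ≥ 95% recovery with the widest leak at the O2 edges.
Ground-truth columns (`truth_class`, `truth_batch`, `truth_first`) ride
along for recovery tests.

What the generator does **not** emulate: measurement correlations within a
placenta, stage-dependent diameter growth, partially initiated boundaries
("insufficient space" cases), or any imaging noise structure — so passing
recovery tests validates the analysis code, not the biology of real
tables.

## Morphometrics conventions

Shape classes cut the aspect ratio at 0.75 (≤ → O1, small bump) and 4/3
(≥ → O3, finger), symmetric about ρ = 1 on the log scale; both cuts are
configurable because the underlying descriptions are qualitative.
Placenta thirds are half-open: `[0, L/3)` lower, `[L/3, 2L/3)` middle,
`[2L/3, L]` top, base = lower.  The O1 ratio is reported pooled and
per-placenta (mean ± s.d.); the alternation index is the fraction of
adjacent ovule pairs (ordered from the base) with differing shape class.
All tables are plain CSV with a documented header.

## Known limitations

* One-dimensional, compartment-based; no apoplast, influx carriers,
  mechanics, or 2-D/3-D geometry.
* Transport does not scale with cell length, so elongation without
  division does not change the pattern.
* Auxin maxima decay when transport is inhibited (see the NPA scenario);
  primordium commitment is outside the model.
* Growth-rate scaling alone cannot change the maxima count; placenta-size
  effects enter through the initial cell count.
* Group labels depend on the declared division waves and the detection
  thresholds; they are a defined, reproducible proxy, not an observable.
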