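# Methods

## Coordinate frames and heading smoothing

Input tracks are per-bird time series of 3D positions (metres, shared
local tangent frame) on a fixed sampling grid (default 5 Hz). Timestamps
are snapped to integer ticks of the nominal period with a 1 ms tolerance;
intervals must be integer multiples of the period (gaps are allowed and
simply yield no derived rows — there is no interpolation).

A bird's flight direction at fix *t* is smoothed over three consecutive
fixes: the horizontal displacement into the fix gives an angle α, the
displacement out of it gives β, and the heading γ is their **circular
mean** — the arctangent of the summed unit vectors. A plain arithmetic
mean of angles would be wrong near the ±π wrap (e.g. +175° and −175° must
average to 180°, not 0°). The smoothing window is fixed at three fixes;
the first and last fix of each bird, and fixes flanking a gap, have no
heading and are dropped. Only horizontal displacements enter the heading
and the rotation; the vertical channel is handled purely by subtraction.

For a dyad (follower *k*, leader *j*) the follower's coordinates are
translated so the leader is at the origin, then rotated in the horizontal
plane so the leader's γ maps onto +y. This yields `e|w` (lateral, + =
right of track), `n|s` (+ = ahead) and `u|d = z_j − z_k`. The sign of
`u|d` is a pure convention: every consumer of the vertical channel
(co-planarity membership, FNN filter) is symmetric in it. The transform
is an isometry, which the test suite checks to 1 nm on random
configurations.

Degenerate headings (zero horizontal displacement, or exactly antiparallel
displacements whose unit vectors cancel) raise an error in the scalar API
and are silently treated as "heading undefined" in the vectorised
all-pairs path.

## The fuzzy engine

Membership functions are continuous piecewise-linear maps defined by
ordered anchors, with constant plateaus outside the anchored range. This
restriction is deliberate: the wake geometry is specified entirely by
trapezoid/triangle breakpoints, and piecewise linearity makes complement
sets exact (`1 − m` is again piecewise linear on the same anchors) and
evaluation a single `np.interp`.

Rules are conjunctions of (variable, term) clauses. The AND operator is
the **minimum t-norm** (product is available via configuration for
sensitivity analysis); OR and NOT are provided as maximum and complement
but the in-wake rule base does not use them. The crisp output is the
0-order Takagi–Sugeno defuzzification Σ wᵢ·cᵢ / Σ wᵢ over rule strengths
wᵢ and constant consequents cᵢ.

When no rule fires at all the output is defined as 0 ("not in wake"),
with a separate `zero_fire` flag so callers can distinguish "nothing
fired" from "a veto rule fired". With the default rule base this happens
only for a follower ahead of a co-planar, laterally aligned leader — a
configuration every rule is indifferent to — and the not-in-wake reading
is the only sensible one.

The engine is verified against an independent pure-Python evaluator
(explicit piecewise expressions and loops, no shared code) to 1e−12 on
random inputs and 1e−6 on a dense lattice.

## The in-wake rule base

Anchor geometry (metres), chosen for a 1.5 m-wingspan bird:

- `wingtip_aligned`: 0 on [−0.8, 0.8] (the downwash corridor directly
  behind the body), rises linearly to 1 at ±1.3 — a 20 cm wingtip
  overlap — and falls to 0 at ±1.8, where the wingtips no longer overlap
  the vortex region. The peak is a point by default; a config option
  widens it into a plateau.
- `close`: 0 at 0, peak at −0.1 (the wake optimum sits just behind the
  leader), linear decay to 0 at −5 where the vortices are spent.
- `too_close`: triangular spike, zero at 0 and −0.1 with peak at −0.05.
  Its exact apex is a free choice (only "very fast between 0 and −0.1" is
  specified); by construction it does not affect the optimum at −0.1.
- `distant`: complement of `close` on the decaying limb — 0 for
  `n|s ≥ −0.1`, linear 0→1 to −5, saturated at 1 beyond. This makes rules
  1 and 4 compete smoothly and produces the gradual posterior decay of
  the response surface.
- `same_plane`: triangular, peak 1 at 0, zero at ±0.75 (half a wingspan);
  `different_plane` is its complement.

All `bird_ns` sets are zero for non-negative `n|s`, so the output is
identically 0 for any follower not strictly behind the leader. The
response surface inherits left/right and up/down mirror symmetry from the
anchors, and its global maximum on the co-planar plane sits at
(±1.3, −0.1) — both properties are asserted in tests and recomputed by
the acceptance script.

## Leader assignment

Per follower per snapshot, all other birds are candidates — no hard
distance prefilter, since the fuzzy sets already zero out implausible
geometry. The candidate with the highest defuzzified output wins, with
deterministic tie-breaking by smaller 3D distance then lexicographic id.
The follower is *in wake* iff the winner's output exceeds τ.

τ defaults to 0 (in-wake means any positive degree of upwash use). A
stricter cut (e.g. 0.5) suppresses the high-frequency leader switching
that a permissive threshold produces in dense flocks, and is exposed as a
first-class parameter.

When not in wake, the record falls back to the nearest bird **in front of
the follower, in the follower's own frame** (`n|s > 0` there; no range or
co-planarity filter), or zeros if nobody is in front. Note the frame
flip: in-wake records report the follower's position in the leader's
frame, not-in-wake records report the front bird's position in the
follower's frame.

## FNN baseline

The frontal nearest neighbour of a bird is the nearest candidate that is
ahead (`n|s > 0`), strictly co-planar (|`u|d`| < 0.75) and within 6 m
horizontal range (inclusive, matching the printed operators). "Nearest"
is ranked by horizontal distance by default — consistent with the
horizontal range condition — with 3D ranking available via configuration.

## Flock analytics

- **Bouts** are maximal runs of constant binary state (in-wake vs not);
  by default an in-wake bout also ends when the leader changes, which
  resolves the sub-second switching dynamics. Grid gaps terminate runs.
  Durations are `samples × Δt`.
- **Alone time** splits not-in-wake snapshots into "nobody in front" and
  "somebody in front but no wake exploited"; the two proportions sum to
  the total alone proportion.
- **Leader preference**: observed per-leader proportions of in-wake
  snapshots, against a bootstrap null in which every in-wake *bout*
  redraws its leader uniformly among the other N−1 birds. Bouts, not
  snapshots, are the resampling unit because consecutive 5 Hz snapshots
  are strongly autocorrelated; resampling snapshots would shrink the null
  band dishonestly. CIs are empirical 2.5/97.5 percentiles (linear
  interpolation). Calibration on a planted no-preference flock (30
  birds, 1000 replicates) gives 95 % ± 2 % coverage.
- **Subgroups** are weakly connected components of the per-snapshot
  follower→leader graph. Weak connectivity ignores direction, so the
  decomposition is well-defined even if a directed 2-cycle arises (each
  bird's frame is its own, so mutual in-wake claims are geometrically
  possible); cyclic snapshots are detected and reported rather than
  forbidden. Singletons are excluded from the size distribution by
  default (a flag includes them).
- **Model agreement** is the fraction of comparable snapshots where both
  models name the same leader. The default denominator is snapshots where
  *both* models name one; "either" and "all" denominators are available
  since the choice is not canonical.

## Synthetic flocks

The generator is kinematic, not behavioural: a lead bird flies a constant
speed (10 m/s) heading random walk (sd 0.01 rad/sample), and each planted
follower is *placed* at its wake station behind its current leader —
lateral ±1.3 m, 1 m behind by default (anywhere in the plausible
[−2, −0.3] band works), co-planar — rotated into the flock heading, plus
white Gaussian noise per axis (optionally AR(1) to mimic GNSS
smoothness). Solo birds fly with the flock heading tens of metres outside
any wake region. Leader switches redraw the leader with a per-sample
probability; when a follower's new leader has not been placed yet within
the same time step, the leader's previous position is advanced by the
lead bird's current step (the flock moves together), which keeps the
recursion stable.

This emulates the *spatial* statistics the models consume and provides
exact ground truth. It does not emulate flapping kinematics, aerodynamic
coupling, banking during turns, or GNSS dropouts — so passing recovery
tests demonstrates that the inference recovers planted geometry under
noise, not that real birds behave like the generator.

With the default 5 cm noise, the planted leader is recovered in ≥ 95 % of
snapshots on V and echelon flocks of 5–10 birds (60 s at 5 Hz); recovery
degrades monotonically with noise. The no-preference variant redraws each
follower's leader at geometric bouts (mean 1 s) and moves followers by
first-order pursuit (gain 0.35/sample) so tracks stay continuous through
switches.

## Problem sizes and determinism

The test suite and acceptance script run on deliberately modest problem
sizes — flocks of 3–30 birds, 10–120 s at 5 Hz, 1000 bootstrap
replicates, 1 cm response-surface grids — chosen so each check exercises
the full pathway while the whole suite completes in seconds. Every
stochastic component takes an explicit seed (`numpy.random.default_rng`);
identical inputs, configuration and seed yield byte-identical outputs,
which the CLI tests assert.

## Known limitations

- The FIS is knowledge-based; no membership learning from data is
  provided or planned.
- Flapping-phase synchronization between leader and follower is outside
  the model: a bird in the right position is assumed able to exploit the
  upwash.
- Turning flight compresses the inner-wing wake geometry; the anchors
  assume straight flight, and the three-fix heading only smooths, it does
  not model curvature.
- The empirical flight statistics quoted in the literature for a specific
  29-bird flock depend on that deposited dataset; this package reproduces
  the computation pathway, and will reproduce those numbers only when run
  on those CSVs.
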