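# flockwake

Knowledge-based fuzzy inference for characterizing **in-wake flight in bird
line formations** from high-precision 3D trajectories.

Birds flying in V- or line formations can save energy by riding the upwash
shed outboard of a leading bird's wingtips. Whether a bird is actually *in
wake* is not a crisp property: the vortex field fades gradually in every
direction. `flockwake` models this with a 0-order Takagi–Sugeno fuzzy
inference system (FIS) over the follower's position in the leader's flight
frame, and derives flock-level behaviour from the resulting per-snapshot
leader assignments. It is written for movement ecologists working with
GNSS tracks of flocks sampled at a fixed rate (nominally 5 Hz).

## The model

For every ordered dyad (follower *k*, leader *j*) and snapshot *t*, the
follower's position is expressed in the leader's frame as

- `e|w` — lateral offset (m), positive right of the leader's track,
- `n|s` — anteroposterior offset (m), positive ahead of the leader,
- `u|d` — vertical offset (m), `z_j − z_k`,

using a three-fix circular-mean smoothed heading for the leader. Three
linguistic variables with piecewise-linear fuzzy sets encode the wake
geometry of a bird with a 1.5 m wingspan:

| variable | term | shape |
|---|---|---|
| `bird_ew` | `wingtip_aligned` | 0 for \|e\|w\| ≤ 0.8, peak 1 at ±1.3 (20 cm wingtip overlap), 0 at ±1.8 |
| | `wingtip_misaligned` | pointwise complement |
| `bird_ns` | `close` | 0 at 0, peak at −0.1, decays to 0 at −5 |
| | `too_close` | narrow spike inside [−0.1, 0] (collision risk) |
| | `distant` | ramps 0→1 from −0.1 to −5, saturated beyond |
| `bird_plane` | `same_plane` | peak 1 at 0, 0 at ±0.75 (half a wingspan) |
| | `different_plane` | pointwise complement |

Five rules map these onto crisp consequents `in_wake = 1` /
`not_in_wake = 0`; the defuzzified output is the firing-strength-weighted
mean, i.e. the degree to which the follower exploits the upwash. One rule
asserts in-wake flight (aligned AND close AND co-planar); the other four
veto it (misaligned, too close, distant, different plane). A bird exploits
at most one upwash at a time, so per snapshot the candidate leader with
the highest output wins; if even the winner's output is not above the
threshold τ (default 0), the bird is recorded against the nearest bird in
front, or as alone when nobody is in front.

A frontal-nearest-neighbour (**FNN**) baseline — nearest bird with
`n|s > 0`, \|`u|d`\| < 0.75 m, horizontal range ≤ 6 m — is included for
comparison, along with agreement statistics and the positional
distributions of each model's chosen leader.

Flock-level analytics: behavioural **bouts** (run lengths of constant
state/leader), **alone-time** budgets, **leader preference** with a
non-parametric bootstrap null (each in-wake bout's leader redrawn
uniformly among the other N−1 birds), and per-snapshot **formation
subgroups** as weakly connected components of the follower→leader graph.

A synthetic flock simulator (`flockwake.simulate`) plants followers at
wake-optimal stations behind switching leaders with Gaussian noise and
emits exact ground truth, so the whole pipeline is testable end to end.

## Worked example

Simulate a noisy 8-bird V formation (60 s at 5 Hz, 5 cm positional noise,
occasional leader switching, one solo bird) and run both models:

```sh
flockwake simulate --out-dir sim --seed 1 --n-birds 8 --template v \
    --duration 60 --noise-sd 0.05 --switch-prob 0.03 --solo-fraction 0.15
flockwake compare --positions sim/positions.csv --out-dir out --seed 1
flockwake analyze --assignments out/assignments_fis.csv --out-dir ana \
    --seed 1 --bootstrap-reps 1000
```

prints (stderr log abbreviated):

```
agreement 0.7705
INFO flockwake: bouts: 526, mean 0.91 s
```

and writes, among others, `ana/bouts.csv`, `ana/alone.csv`,
`ana/preference.csv` and `ana/subgroup_sizes.csv`. For this run the bouts
average 0.91 ± 3.36 s (median 0.20 s) — leader switching keeps in-wake
episodes short — the birds spend on average 38.8 % of snapshots not
in-wake, and dyads are the most common subgroup:

```
 size  count  proportion
    2    124    0.264392
    3     84    0.179104
    4     84    0.179104
    ...
```

`ana/preference.csv` gives each follower's observed proportion of in-wake
time behind every potential leader with its 95 % bootstrap null band, e.g.
bird `b01` spent 55.1 % of its in-wake time behind `b00` against a null
interval of [0.026, 0.573]. The FIS and the FNN baseline agree on the
leader's identity in 77 % of the comparable snapshots here; they diverge
exactly where a near bird sits in the downwash while a farther bird
occupies the wake station.

The defuzzified response surface itself can be exported with
`flockwake heatmap --out-dir out --plane ud --value 0 --grid-res 0.01`;
its global maximum sits 0.1 m behind the leader at ±1.3 m lateral offset.

## Layout

- `flockwake.frames` — trajectories, heading smoothing, leader-relative frames
- `flockwake.fuzzy` — generic piecewise-linear fuzzy engine (Takagi–Sugeno)
- `flockwake.wake_model` — the in-wake rule base and leader assignment
- `flockwake.fnn` — frontal-nearest-neighbour baseline
- `flockwake.analysis` — bouts, alone time, preference bootstrap, subgroups, agreement
- `flockwake.simulate` — synthetic flocks with planted ground truth
- `flockwake.io` / `flockwake.cli` — CSV/JSON I/O and the `flockwake` CLI

See `docs/methods.md` for the modelling assumptions and numerical choices.
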