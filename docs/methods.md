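# Methods

## Model

The matrix is the set of integer cubic-lattice sites `(x, y, z)` with
`x² + y² + z² ≤ R²`, centred on a lattice site at the origin (the
`(2R+1)³` bounding cube has side equal to the sphere's diameter). The
centre-on-site convention is a choice; the alternative (centre on a cell
corner) changes the site count `MS` by a few per mille at the radii used
here and nothing qualitative. Lengths are in lattice constants (lu), times
in Monte Carlo time units (tu): the mean time for one particle to attempt
one move.

`N0 = round(C0·MS)` particles (round half away from zero, clamped to ≥ 1)
are placed uniformly at random on distinct sites, all covalently bonded at
t = 0. One Monte Carlo step:

1. pick one of the `Nt` remaining particles uniformly at random;
2. advance the clock by `1/Nt`, with the `Nt` in force at pick time — a
   release in the same step counts from the next step on;
3. if the particle is bonded, draw `u ~ U(0,1)`; if `u < kb` the bond
   breaks (the particle does **not** also move in this step — the two
   branches are mutually exclusive);
4. if the particle is free, choose one of its six neighbours with
   probability 1/6: outside the sphere → released and removed permanently
   (perfect sink, no re-entry); occupied → the move is rejected and the
   particle stays (no retry of another neighbour); empty → it moves.

Because every particle is picked at unit rate regardless of `Nt`, the
number of cleavage trials a bonded particle has experienced by time t is
Poisson(t) to O(1/Nt), and its survival probability is
`E[(1−kb)^K] = exp(−kb·t)` exactly: first-order kinetics emerge from the
scheme rather than being imposed. `kb = 1` is the scheme's upper limit
(detachment certain at first pick); any positive `kb ≤ 1` is admissible.

Out of scope by design: matrix swelling, surface erosion and bulk
degradation; second-order or other non-first-order cleavage kinetics;
non-spherical geometries; physical (SI) units for the diffusion
coefficient.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `R` | sphere radius (lu) | 20 | full-scale study geometry; analysis runs here use R = 8–10 (see below) |
| `C0` | initial load fraction | 0.5 | occupied fraction of the `MS` sites |
| `kb` | cleavage rate constant (1/tu) | 1.0 | per-pick detachment probability, (0, 1] |
| `n_realizations` | ensemble size | 100 | the study convention is 100–300 |
| `max_time` | safety cap (tu) | none | capped runs are flagged truncated, never silently averaged |
| `n_grid`, `grid_kind` | recording grid | 512, log | see below |
| regime thresholds | `high=0.99`, `low=0.3`, `completion=0.95` | — | heuristic, exposed as arguments |

## Numerical choices

* **Event recording.** A trajectory stores `(t, Nt, Nb)` only at changes —
  at most `2·N0 + 1` rows — so memory stays bounded even for `kb = 1e−4`
  runs with ~10⁸ picks. Curves are left-continuous step functions,
  resampled onto a common grid: t = 0 plus `n_grid` logarithmically spaced
  points ending exactly at the ensemble's largest terminal time (every
  realization contributes 0 beyond its own terminal time). A realization
  count-weighted linear grid is available via `grid_kind="linear"`.
* **Release time by integration** is the trapezoid rule applied to
  `⟨Nt⟩/N0` on that grid. The exact event-based equivalent — the mean of
  the individual particles' release times — is kept on the result
  (`mean_release_times`) and the two agree to ~1% at the default grid
  density; the tests assert this.
* **Weibull fit.** `1 − exp(−(t/τ)^b)` is fitted to the ensemble-mean
  release profile by unweighted least squares over the full grid
  (`scipy.optimize.curve_fit`), initial guesses τ = the integral estimate,
  b = 1, bounds τ > 0, b ≥ 10⁻³. The mean release time of the fitted
  profile is `τ·Γ(1 + 1/b)` — the mean of the Weibull distribution; this
  closed form is used wherever a fit-based time is reported. Profiles must
  be nondecreasing, lie in [0, 1], span < 10% to > 90% release and contain
  ≥ 10 points; anything else is rejected rather than fitted.
* **Free-drug fraction.** `⟨Nf/Nt⟩` is the mean of per-realization ratios
  over realizations that still contain particles (NaN once all are empty),
  not the ratio of means — it is the per-realization plotted quantity and
  avoids 0/0 at the tail.
* **Regime classifier.** Operates on that curve restricted to the part of
  the release before `completion` (default 95%) of the drug has left; the
  terminal tail, carried by a handful of particles, is shot-noise
  dominated. Diffusion-controlled: reaches `high` and stays; reaction-
  controlled: never exceeds `low`; otherwise crossover. The thresholds are
  operational stand-ins for the qualitative steady-state signatures
  (saturation at 1 versus a low plateau) and are configurable; there is no
  sharp boundary between the regimes.
* **Reproducibility.** Site order is lexicographic; per-realization streams
  are spawned as `SeedSequence(master_seed).spawn(n)`, each split again
  into a placement stream and a dynamics stream (the latter seeds the
  compiled kernel). Identical (config, seed) gives bit-identical output;
  CSVs are written at 17 significant digits and parsed back with
  round-trip float precision.
* **Implementation.** The hot loop is a numba-compiled kernel over flat
  occupancy/position arrays with swap-removal; a pure-Python `mc_step` on
  the same state implements the identical rule set and is what the unit
  tests inspect step by step (including an occupancy-level excluded-volume
  audit). The two are cross-checked statistically on single-particle exit
  times.

## Problem sizes

Analysis and validation run at reduced geometry — R = 8 for the
cleavage-rate sweep (MS = 2109), R = 10 for the first-order check
(MS = 4169), 50–100 realizations — where the full sweep over three decades
of `kb` completes in seconds while every qualitative feature of the
R = 20 study (regimes, crossover, the `t_diff + 1/kb` law) is already
present. The simulator accepts the full R = 20, `kb = 1e−4`, 100–300
realization configuration unchanged; such runs are hours-scale jobs.

## What the synthetic conditions do and do not show

The generator *is* the model: initial placement, cleavage and hopping are
the processes under study, so there is no separate synthetic-data layer.
What the lattice model abstracts away from real formulations: continuum
positions and polydispersity, drug–polymer interactions beyond site
exclusion, concentration-dependent diffusivity, swelling/erosion of the
matrix, and any physical calibration of lu and tu. Passing tests show the
stochastic scheme realises its intended kinetics (exact exponential
detachment, exact absorbing-walk exit statistics, conservation) and that
the crossover law describes the simulated system; they do not by
themselves validate the model against experimental release data.

## Validation oracles

* Sphere enumeration versus a brute-force triple loop (R ≤ 6).
* Single-particle exit times versus the exact absorbing Markov chain
  (`(I − Q)E = 1`; e.g. 12/5 tu from the centre at R = 1), 10⁴ runs per
  start site, 3-standard-error bands.
* `⟨Nb(t)⟩/N0` versus `exp(−kb·t)` within 3× the binomial standard error
  of a mean over `N0·n_realizations` cleavage histories.
* `τ·Γ(1 + 1/b)` versus numerical integration of the Weibull survival
  curve (property-based).
* Noiseless Weibull profiles over τ ∈ [1, 10⁴], b ∈ [0.4, 2.5] recovered
  to < 10⁻⁴ relative error.

## Known limitations

* The trapezoid integral inherits ~1% grid bias at default density; use
  `mean_release_times` when exactness matters.
* The regime classifier's thresholds are heuristic; near the regime
  boundaries the label depends on them (that reflects a genuinely smooth
  crossover, not a defect).
* Sampling criteria phrased as 3σ bounds (the first-order check, the
  per-site Markov comparisons) are sup-statistics over many correlated
  points; occasional seed-dependent excursions just past the bound are
  expected at the few-percent level.
* With `n_realizations = 1` standard errors are undefined (NaN), and
  truncated ensembles refuse release-time estimation and classification
  rather than extrapolating.
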