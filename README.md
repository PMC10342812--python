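# conjugate-release

Kinetic Monte Carlo simulation and analysis of drug release from spherical
polymer–drug conjugate matrices.

In a polymer–drug conjugate the drug molecules are covalently linked to the
polymer network and must be detached — by hydrolysis, enzymatic cleavage,
photolysis, … — before they can diffuse out of the matrix. Release is
therefore shaped by the competition between two stochastic processes:

* **bond cleavage**, a first-order reaction with rate constant `kb`
  (units 1/tu), giving a bonded population `Nb(t)/N0 = exp(−kb·t)`;
* **excluded-volume diffusion** of the detached molecules, simulated as a
  random walk on a cubic lattice inside a sphere of radius `R` (lattice
  units), with an absorbing boundary: a particle stepping outside the
  sphere is released and removed.

At each Monte Carlo step one of the `Nt` particles still inside is picked
uniformly at random and the clock advances by `1/Nt` tu, so each particle
attempts on average one event per time unit. A bonded particle detaches
with probability `kb`; a free particle hops to one of its six neighbours
(blocked if the target is occupied — double occupancy is forbidden). The
fractional release `1 − Nt/N0` is averaged over an ensemble of independent
realizations.

The characteristic release time `t_R` — computed both by numerical
integration of `⟨Nt⟩/N0` and from a stretched-exponential (Weibull) fit
`1 − exp(−(t/τ)^b)` with mean time `τ·Γ(1 + 1/b)` — obeys the simple
interpolation law across the whole diffusion-controlled → reaction-controlled
crossover:

```
t_R = t_diff + 1/kb
```

where `t_diff` is the purely diffusional release time (all particles free
at t = 0) and `1/kb` the mean bond lifetime. The package also classifies
the release regime from the free-drug fraction `Nf(t)/Nt`: it saturates at
1 when diffusion limits release, stays low when the reaction does, and does
neither in the crossover regime.

## Worked example

```python
from conjugate_release import (SimConfig, run_ensemble, release_time_estimate,
                               mean_time_integral, classify_regime,
                               predict_release_time_eq2)

diff = run_ensemble(SimConfig(R=8, C0=0.5, n_realizations=100, seed=1,
                              diffusion_only=True))
t_diff = mean_time_integral(diff)
print(f"t_diff               = {t_diff:.1f} tu")

res = run_ensemble(SimConfig(R=8, C0=0.5, kb=0.01, n_realizations=100, seed=1))
est = release_time_estimate(res)
print(f"t_R (integration)    = {est.t_integral:.1f} tu")
print(f"Weibull fit          : tau = {est.tau:.1f} tu, b = {est.b:.3f}")
print(f"t_R (Weibull mean)   = {est.t_weibull:.1f} tu")
print(f"t_diff + 1/kb        = {predict_release_time_eq2(t_diff, 0.01):.1f} tu")
print(f"regime               = {classify_regime(res)}")
```

prints

```
t_diff               = 30.7 tu
t_R (integration)    = 137.4 tu
Weibull fit          : tau = 147.6 tu, b = 1.387
t_R (Weibull mean)   = 134.7 tu
t_diff + 1/kb        = 130.7 tu
regime               = crossover
```

At `kb = 0.01` the mean bond lifetime (100 tu) and the diffusional escape
time (30.7 tu) are comparable, so the measured release time (137 tu, by
either estimator) sits well above both limits and close to their sum — the
crossover regime. At `kb = 1` the same sphere releases in ≈ 31 tu
(diffusion-controlled); at `kb = 0.001` in ≈ 1045 tu ≈ 1/kb
(reaction-controlled).

## Command line

```sh
conjugate-release simulate --R 20 --C0 0.5 --kb 0.01 --reps 100 --seed 7 --out fig_data
conjugate-release simulate --R 20 --C0 0.5 --diffusion-only --reps 100 --seed 7 --out reference
conjugate-release sweep --R 8 --reps 100 --kb-values 1,0.1,0.01,0.001 --out sweep --plot
conjugate-release analyze my_profile.csv --time-col time --frac-col release_frac
conjugate-release fixtures --out fixtures/
```

`simulate` writes the ensemble curves (time, ⟨Nt⟩/N0, ⟨Nb⟩/N0, ⟨Nf/Nt⟩,
release fraction, standard errors) as CSV plus a JSON manifest that
reproduces the run bit-exactly; `sweep` tabulates `t_R(kb)` against
`t_diff + 1/kb` with regime labels. Parameters may also come from a flat
`key = value` config file (flags override it). The default full-scale
geometry is `R = 20`, `C0 = 0.5`; runs with `kb = 1e-4` at that scale take
hours, while the `R = 8` sweep above finishes in seconds.

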