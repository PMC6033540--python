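# oridyn

Stochastic well-mixed modeling of eukaryotic DNA replication kinetics:
why the rate of replication-origin firing rises and falls as a universal
bell over S-phase, and how its maximum is set by two measurable numbers —
the replication fork speed and the density of licensed origins.

## The model

Before S-phase, a finite set of *potential origins* (p-oris) is licensed
at localized chromosomal positions with density ρ₀ = N_p-ori(0)/L.  A
limiting pool of N_DT *firing factors* is loaded with an exponentially
relaxed timescale τ.  Replication proceeds by three rules:

1. **Bimolecular firing.** In each time step dt, every free factor
   (N_FD(t) of them) fires one of the N_p-ori(t) unreplicated origins
   with probability 1 − (1 − k_on·dt)^N_p-ori(t), creating two divergent
   forks; each fork carries one half of the factor.
2. **Fork propagation and passivation.** Forks move at constant speed v;
   any p-ori overrun by a fork is inactivated (passivated).
3. **Termination and recycling.** Converging forks annihilate, and the
   two halves reform a free factor; forks reaching a chromosome end are
   discarded.

The observable is the firing rate per length of unreplicated DNA,

    I_S(t) = N_fired(t, t+dt) / (L_unrep(t) · dt).

Its shape is controlled by the competition between the time to fire an
origin, t_c = 1/(k_on·N_FD), and the time to replicate the DNA between
neighboring origins, t_r = d/v.  The p-ori density over unreplicated DNA
is conserved while N_FD(t) < N_FD\* = v/(k_on·d); once recycling drives
N_FD past this threshold the density collapses and I(t) turns over,
giving the bell.  At the turnover, with d ≈ 1/ρ₀ (exact for periodic
origin spacing),

    I_max = k_on · ρ₀ · N_FD\*  ≈  v · ρ₀²,

a parameter-free scaling law relating the peak firing rate to fork speed
and origin density.  A genome split into early/late-replicating halves
with ρ_early ≫ ρ_late instead obeys the bound I_max ≲ 0.5·v·ρ_early².

The package provides origin-map construction (random-uniform, periodic,
or OriDB-style tab-separated files with Confirmed/Likely/Dubious status
categories), the fixed-time-step stochastic simulator, ensemble
observables (pooled I(t) with bootstrap errors, I_max, normalized p-ori
density and free-factor curves, passivation/activation ratio,
replication-time distribution, activated-origin density), the
closed-form layer (N_FD\*, v·ρ₀², regime classification, the
(L, N_DT, k_on) → (αL, αN_DT, k_on/α) rescaling), and a CLI.

## Worked example

Strong-interaction regime on one 3000-kb chromosome with periodically
placed origins (ρ₀ = 0.28 /kb, v = 0.6 kb/min, k_on = 6×10⁻³ /min,
N_DT = 165, τ = 3 min).  With `red.yaml`:

```yaml
v: 0.6
kon: 6.0e-3
ndt: 165
genome_source: periodic
length_kb: 3000.0
rho0: 0.28
tau_load: 3.0
n_runs: 100
bin_width: 0.5
seed: 42
out_dir: red_out
```

```text
$ oridyn theory --config red.yaml
rho0 = 0.28 /kb (840 origins over 3000.0 kb)
NFD* = 28 firing factors
predicted Imax = v*rho0^2 = 0.04704 /kb/min (47.04 /Mb/min)
regime at NFD=NDT=165: density-depleting

$ oridyn ensemble --config red.yaml
100 runs; replication time 24.9 ± 1.0 min
Imax = 0.06962 /kb/min (69.62 /Mb/min) at t = 19.2 min
wrote: red_out/kinetics.tsv, red_out/replication_times.txt, red_out/per_run.tsv, red_out/manifest.yaml
```

Reading the numbers: N_FD\* = 28 ≪ N_DT = 165 puts the system deep in
the density-depleting (bell-shaped) regime.  The ensemble completes
S-phase in 24.9 ± 1.0 min and the pooled I(t) peaks late in S-phase at
≈ 70 /Mb/min — the order of magnitude set by v·ρ₀² = 47 /Mb/min, with
the simulated maximum overshooting the closed-form estimate because the
free-factor count keeps climbing past N_FD\* while origins remain (see
`docs/methods.md`).  `kinetics.tsv` holds the pooled curves
(t, I, I_stderr, normalized density, normalized free factors,
passivation/activation ratio); `manifest.yaml` holds every parameter and
the master seed, from which the run is reproducible bit for bit.

Other entry points: `oridyn simulate` (one S-phase), `oridyn fixture`
(synthetic origin-map files in the OriDB-like dialect), and the library
API (`oridyn.run_ensemble`, `oridyn.estimate_imax`, …).

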