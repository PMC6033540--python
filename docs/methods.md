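# Methods

## Model and assumptions

`oridyn` implements a 1D nucleation-and-growth (KJMA-type) description of
S-phase. Chromosomes are continuous 1D segments in kb; potential origins
(p-oris) are points licensed before S-phase begins; replication state is a
set of disjoint replicated intervals ("bubbles") whose moving edges are
the forks. The system is *well mixed*: a free firing factor sees every
unreplicated p-ori with the same rate constant k_on, irrespective of 3D
position. Firing is bimolecular (factor + p-ori), each fork sequesters
half a factor, and termination (fork merger) reassembles and frees one
factor. The total factor count N_DT is conserved apart from halves lost
on forks that run off chromosome ends.

The fixed-time-step loop advances in increments dt with the order:

1. factor arrivals (loading) are added to the free pool;
2. each free factor independently attempts a firing with probability
   1 − (1 − k_on·dt)^N_p-ori, with N_p-ori frozen at the step start;
   successful attempts claim distinct uniformly random unreplicated
   origins (attempts beyond the available origins are no-ops);
3. every fork advances by v·dt; newly covered p-oris are passivated;
   converging forks whose swept intervals touch or overlap are removed
   pairwise (replication capped at the midpoint of the gap remaining at
   step start) and one factor is freed per merger; forks crossing a
   chromosome boundary are discarded.

The run ends when no unreplicated DNA remains; that time is the
replication (S-phase) time. Within-step origin depletion is ignored in
the firing probability (it is second order in dt), and a freshly created
fork pair can merge with an opposing fork in the same step.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| v | fork speed | kb/min | required |
| k_on | productive-interaction rate per factor per p-ori | 1/min | required |
| N_DT | total firing factors (Poisson mean in `poisson` mode) | count | required |
| τ (`tau_load`) | exponential loading timescale | min | 0 (instant) |
| dt | time step | min | 0.01 |
| ρ₀ | initial p-ori density (placement schemes) | 1/kb | required |
| `bin_width` | observable binning | min | 0.5 |
| `recycle_at_ends` | re-pair half factors lost at chromosome ends | flag | off |

dt = 0.01 min keeps k_on·dt ≪ 1 for every parameter set used here and
makes the per-step fork displacement v·dt a small fraction of typical
origin spacings; a warning is emitted when v·dt exceeds half the minimum
spacing. Halving dt changes ensemble means by less than the Monte-Carlo
error (verified by test). Internally everything is kb and min; /Mb/min
display conversion is provided.

## Origin maps

Three constructors: (i) *uniform* — round(L·ρ₀) i.i.d. uniform positions,
redrawing the measure-zero duplicates, re-sampled for every simulated
S-phase; (ii) *periodic* — exactly one origin uniform in each consecutive
1/ρ₀ segment (the trailing partial segment stays empty), also re-sampled
per run; (iii) *file-based* — a tab-separated dialect (`chrom start_kb
end_kb name status`, optional `#chrom <name> <length_kb>` headers,
status ∈ Confirmed/Likely/Dubious) with positions fixed across runs.
Intervals collapse to midpoints by default (the unbiased point choice;
`interval_to_point="start"` is available since the convention behind
published origin lists is not settled). Coordinates are continuous,
0-based, half-open [0, L) — no lattice, avoiding discretization
artifacts. The rDNA locus receives no special handling.

## Observables and estimators

The firing rate per unreplicated length is estimated per time bin as a
ratio of sums (Σ firings)/(Σ L_unrep·dt), pooled across runs the same
way. Ratio-of-sums keeps late-S-phase bins finite where per-run
denominators vanish; a completed run simply stops contributing.
Uncertainties come from a run-level bootstrap (200 resamples, seeded).
I_max is the maximum of the pooled curve over bins whose mean
unreplicated fraction exceeds 5%, a guard against small-count/
small-denominator noise at the very end of S-phase. The
passivated/activated ratio is reported per bin by default (a cumulative
mode exists); bins with zero activations are flagged undefined, never
imputed as zero. Ensembles derive per-run seeds deterministically from
one master seed (`numpy.random.SeedSequence`), so every published number
is regenerable from its manifest.

## Regimes and the scaling law

With d the mean unreplicated inter-origin distance (d = 1/ρ₀ exactly for
periodic spacing), the density of p-oris over unreplicated DNA is
conserved while N_FD < N_FD\* = v/(k_on·d) and collapses above it. The
closed-form peak estimate I_max = k_on·ρ₀·N_FD\* = v·ρ₀² evaluates the
bimolecular rate exactly at the threshold crossing. In simulation the
pooled maximum systematically exceeds this estimate whenever N_DT ≫
N_FD\*: after the crossing the free pool keeps growing faster than the
origin density falls, so I(t) = k_on·N_FD·ρ keeps rising for a while
(e.g. 1.5× v·ρ₀² at the strong-interaction point v = 0.6, k_on = 6e-3,
ρ₀ = 0.28, N_DT = 165 — which is also where the simulated peak matches
the experimentally reported embryonic I_max of ~70 /Mb/min). Conversely,
near the regime edges (N_FD\* comparable to N_DT, or densities so low
that the threshold is only crossed in the terminal collapse) the
measured maximum falls below the estimate. v·ρ₀² is therefore an
order-of-magnitude law — excellent on a log-log diagonal across decades,
but not a 30%-accurate pointwise predictor across the whole density
range, and the test suite records this honestly: the mid-regime sweep
points agree within 30%, the edge points do not. The same idealization
affects the passivation/activation switch: the per-bin ratio crosses 1
at the N_FD\* crossing (where I(t) ≈ v·ρ₀²), which precedes the actual
pooled-curve maximum by a few minutes in the strong-interaction regime.

## Synthetic data and what the tests do (and do not) show

The fixture generator writes origin maps with the real 16 budding-yeast
chromosome lengths and the real category counts (410 Confirmed, 216
Likely, 203 Dubious = 829), but *synthetic uniform-random positions* —
it reproduces the file dialect and map structure, not real mapped
coordinates, and is labelled synthetic. Completion-time statistics are
sensitive to the largest origin-free gaps (especially near chromosome
ends, where real maps have subtelomeric origins but uniform placement
often does not), so the yeast S-phase duration measured on a synthetic
map runs ~10–25% longer, with a wider spread, than the values obtained
with curated coordinates; the mean fired-origin count is much less
position-sensitive. The yeast acceptance check therefore passes its
fired-count band but can exceed its duration bands; running it with a
real exported origin map (via `read_origin_file`) is the definitive
check. Embryonic-style results (activated density, regime shapes,
rescaling invariance) re-sample positions every run and carry no such
fixture dependence.

## Numerical choices and degenerate inputs

Converging forks merge when their swept intervals touch or overlap
(≥, not >); merged coverage is the interval union, so replicated length
never exceeds the closed gap. Chromosomes are laid end-to-end on one
global axis separated by 1-kb inert walls, letting the whole genome
advance with a handful of vectorized array operations per step; forks
clip exactly at the walls. Half factors from end-discarded forks are
lost by default — the model credits factor release only at mergers — and
`recycle_at_ends` re-pairs them for sensitivity analysis; the loss is
at most two halves per chromosome per S-phase. Loading is per-factor
i.i.d. exponential by default; a deterministic-count mode
round(N_DT·(1−e^(−t/τ))) exists for variance-reduction comparisons.
N_DT = 0, or a chromosome with no origins, can never finish: the run
detects the stall (no forks, no free or pending factors, or no origins
left) and raises instead of looping to `max_time`.

## Known limitations

No 3D diffusion or spatial heterogeneity of factors; no fork stalling or
checkpoint signalling beyond the interpretation of joint (v, k_on)
rescaling; no position-resolved I(x, t) output (per-origin event logs
are recorded to enable it); no fitting machinery — parameter values are
set by hand as in the underlying experimental comparisons.
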