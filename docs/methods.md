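# Methods

## Model

The model treats layer 3 of primate prefrontal area 10 as a porous medium.
A cubic tissue block of side 64 µm is discretized into 1-µm³ voxels; the
extracellular dopamine concentration `C(x, t)` is carried per voxel in nM
referred to the extracellular fluid (a voxel's water volume is
`α·1 µm³` with volume fraction `α = 0.23`). The dynamics are linear:

    ∂C/∂t = D_eff ∇²C − k(t)·C + Σ_sites quantal source

with hindered diffusion `D_eff` and uniform first-order reuptake `k`.
Because the system is linear in the source, every volume-mean observable
has a closed form (see *Well-mixed oracle*), which the stochastic engine
must reproduce — this dual route is exploited throughout the test suite.

### Assumptions

* Release sites are statistically independent points, one voxel each
  (boutons ≈ 0.9 µm ≈ one voxel); no axonal arbor structure, no
  inter-bouton correlation, no short-term facilitation/depression.
* Reuptake is spatially uniform and strictly first-order (no transporter
  saturation/Michaelis–Menten; the linear regime is appropriate at
  cortical nM levels and transporter densities, and a *complete* block is
  modelled simply as `k = 0`).
* `α` and the tortuosity are homogeneous and isotropic; receptors do not
  buffer free dopamine.
* Boundaries are periodic by default (see *Numerical choices*).

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| ρ | release-site density | 2·10⁻⁴ (52 sites realized) | µm⁻³ |
| α | extracellular volume fraction | 0.23 | — |
| λ | tortuosity (metadata) | 1.54 | — |
| D_free | free diffusion coefficient | 763 | µm²/s |
| D_eff | effective diffusion coefficient | 322 | µm²/s |
| Q | dopamine per vesicle (6.5·10⁻²⁰ L × 0.25 M) | 1.625·10⁻²⁰ | mol |
| f_tonic | tonic firing rate | 5.6 | Hz |
| f_phasic | burst firing rate | 15 (alt. 26, 0) | Hz |
| p | release probability per spike | 0.5 | — |
| k | reuptake rate constant | 1.5 | s⁻¹ |
| K_d(high/low) | receptor affinity states | 10 / 1500 | nM |
| dt | time step | 5·10⁻⁴ | s |

The engine consumes `D_eff` directly; `D_free` and the tortuosity are kept
as metadata and validated for consistency (`D_free/λ² = 321.7 ≈ 322` to
0.1%). Depleted innervation (Parkinsonian-like, ≈70% bouton loss) is
`ρ = 0.61·10⁻⁴ /µm³`, realizing 16 sites.

Derived scales worth keeping in mind: one vesicle lifts its voxel by
`Q/(α·10⁻¹⁵ L) = 7.07·10⁴ nM`; the uptake screening length is
`√(D_eff/k) = 14.7 µm`, so the 64-µm periodic box holds ~4 screening
lengths per axis.

## Numerical choices

* **Scheme.** Per step: (1) instantaneous quantal injections, (2) forward-
  Euler diffusion with the 7-point Laplacian, (3) exact integration of the
  clearance sub-step (`C ← C·e^{−k·dt}`). Splitting the linear clearance
  out keeps uptake-only decay exact to machine precision (the pure-decay
  test demands 10⁻⁶ relative over 2000 steps) while the overall scheme
  remains first-order in `dt`, like a plain Euler update. Injection order
  matters only at O(dt).
* **Stability.** `dt ≤ dx²/(6·D_eff) = 5.176·10⁻⁴ s`; the engine refuses
  larger steps (CLI exit code 3). The default `dt = 5·10⁻⁴ s` sits just
  under the bound; the update is then a convex combination of neighbour
  values times a decay factor, so non-negativity is preserved exactly.
* **Boundaries.** Periodic by default, reflecting available. The choice is
  deliberate: the screening length (14.7 µm) is not small against the box,
  so absorbing faces would depress volume means by ~10–20%, while the
  periodic volume mean matches the well-mixed balance exactly — which is
  what the reference summary values require. Periodicity also makes the
  mass ledger exact: per step, (total) = (previous)·e^{−k dt} + injections,
  and the ledger (injected − taken up vs. present) closes to round-off
  (tested ≤ 10⁻⁹ relative).
* **Event sampling.** Bernoulli per site per step with probability
  `f(t)·p·dt` (≤ 6.5·10⁻³ at the maximal 26 Hz), indistinguishable from
  Poisson thinning at these rates; refused if `f·p·dt ≥ 1`. All randomness
  flows from `numpy` SeedSequence spawns, so site sets, cohorts and event
  streams are bit-reproducible per seed.
* **Realized site counts.** A finite box contains an integer number of
  sites, `round(ρV)`; both the placement and the closed forms use it
  (52/262144 µm⁻³, not the nominal 2·10⁻⁴), as do cohort sizes
  (round-half-up: 10% of 52 → 5).
* **Kernel.** The stencil is JIT-compiled (numba); an independent
  `np.roll` implementation in the test suite pins its output to 10⁻¹²,
  and linearity in Q is exact (binary scaling), tested as bit equality.

## Well-mixed oracle

Ignoring diffusion (exact for volume means under periodic boundaries):

* steady state `C_ss = ρ f_tonic p Q/(α k)` → 26.16 nM (16 sites: 8.05 nM);
* change after a `T = 150 ms` window in which a fraction φ of sites fires
  at `f_ph`: `ΔC = φ·(f_ph−f_t)/f_t · C_ss · (1−e^{−kT})` → +4.42 nM at
  15 Hz/50%, +9.60 at 26 Hz/50%, −2.64 for a 50% pause;
* reuptake-block ramp slope `ρ f_tonic p Q/α` → 39.24 nM/s, i.e. ~25 s
  from baseline to 1 µM.

The oracle is *only* valid for volume means; local values near sites are
far above it (the single-site steady profile is the screened point source
`S/(4πD_eff α r)·e^{−r/λ}` with `S = f p Q`, which the engine reproduces
within discretization error of ~15% for r = 2–10 µm).

## Ensemble design and problem sizes

Headline quantities are Monte-Carlo averages. The dominant error in the
150-ms change scores is the Bernoulli event count in the window (per-branch
SD ≈ 1–2 nM), so the ensembles branch: per placement seed the 4-s tonic
run-in (8000 steps) is computed once, and each condition re-runs only the
150-ms window (300 steps) with fresh cohort and event randomness.
The acceptance script uses 16 placement seeds × 20 branches per condition
(sized so the Monte-Carlo standard error — floored by the shared
instantaneous-baseline term, ≈0.38 nM/√n_seeds — stays well below the
published values' spread); the test suite's full condition grid uses
10 × 10. The reuptake-block ramp
uses 10 seeds of a 3.5-s run with the block at t = 1 s; slope uncertainty
is reported as the across-seed standard error and stochastic checks are
asserted at 2-SE tolerances.

## What the generator does and does not emulate

The synthetic tissue reproduces the *statistical* geometry of cortical
dopamine innervation (density, uniform random placement — the
minimum-image nearest-neighbour spacing averages 9.5 µm, matching the
Poisson expectation `0.554·ρ^{−1/3}`) and the firing statistics of
midbrain dopamine neurons. It does not emulate axonal arborization,
correlated multi-bouton release, heterogeneous transporter placement,
receptor-mediated buffering, or degradation pathways. Passing tests
therefore validate the diffusion–uptake–release physics and its
measurements, not the full biological variance structure.

## Known limitations

* **Instantaneous snapshots are shot-noise dominated near events.** A
  fresh vesicle puts 7·10⁴ nM into one voxel, decaying to the bulk level
  within ~10 ms. Volume means and mean absolute changes are unbiased by
  this (linearity), but statistics that are *nonlinear* in the field are
  not: the volume-averaged per-voxel **relative** change after a burst
  evaluates to ≈ 20% on instantaneous snapshots, versus ≈ 15% for the
  expectation field (release replaced by its mean flux) — fresh-plume
  voxels contribute large ratios on bulk baselines. Similarly, the
  instantaneous field maximum is set by the most recent event (thousands
  of nM) rather than by the time-averaged site plume (~100–250 nM).
  Reported relative-change and min/max statistics must therefore be read
  as properties of the instantaneous quantal field; any temporally
  smoothed readout (as a slow sensor would provide) gives systematically
  smaller values. `dopadiff profile` and the expectation-field control in
  the engine tests quantify the smooth limit.
* Steady state is operationalized as t = 4 s of tonic firing (six uptake
  time constants, <0.3% from the asymptote); there is no convergence
  detection.
* The pause protocol uses rate 0 Hz; rebound or autoreceptor effects are
  out of scope, as are receptor-state trafficking dynamics (occupancy is
  a static equilibrium map `C/(C+K_d)`).
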