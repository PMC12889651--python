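# Methods

## The estimator

Well-tempered metadynamics deposits Gaussian hills along a collective
variable *s* every `pace` dynamics steps; the height of each new hill is
scaled by exp(−V(s,t)/((γ−1)kT)), so the bias V(s,t) converges instead of
growing without bound. The reversible-work estimator

c(t) = (1/β) log [ ∫ ds e^{γβV(s,t)/(γ−1)} / ∫ ds e^{βV(s,t)/(γ−1)} ]

is the time-dependent free-energy offset of the tempered ensemble. Three
exact properties anchor the implementation and are asserted in the tests:
c = 0 when V ≡ 0; c = V₀ when V is constant; and min_s V ≤ c(t) ≤ max_s V
for any V, because the ratio of integrals is a weighted average of
e^{βV}. Adding a constant to V shifts c by exactly that constant.

The CTMD score of a ligand pose is **min over replicas of the terminal
c(t)**. "Terminal" is a deliberate reading: the minimum *within* a run is
degenerate (c(0) = 0 always), so the minimum is taken across independent
replicas evaluated at their final hill time, with no terminal-window
averaging. Scores are in kT; only their ordering across ligands is used.

## The toy model

Real CTMD biases the ligand-RMSD of a docked pose. The desk-scale stand-in
is a 1D non-negative displacement coordinate with

- a Gaussian well of depth D (kT) and width 0.5 at the origin — the bound
  pose; D is the latent "stability" the method must recover,
- a half-harmonic wall (k = 50 kT per unit², onset at s = 3.0) — the
  finite simulation box / maximum displacement,
- a reflecting boundary at s = 0 — RMSD cannot be negative. Hills are
  *not* mirrored across the boundary; the bias is a plain Gaussian sum,
  the simplest consistent choice.

Dynamics are overdamped Euler–Maruyama (s′ = s + F·dt/friction +
√(2·kT·dt/friction)·ξ): with no inertia in the CV statistics to preserve,
an inertial integrator would add parameters without adding discrimination.
The unbiased harmonic limit is an Ornstein–Uhlenbeck process, which the
tests use as the sampling oracle (stationary variance kT/k).

The `rmsd` helper computes plain displacement RMSD with no rotational or
translational superposition. Alignment conventions differ between
production protocols and are irrelevant to the 1D toy, so the simplest
definition is exposed and documented rather than a guessed alignment.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| γ (bias factor) | 10 | — | common well-tempered choice; tempering strong enough to converge in 1000 hills |
| w0 (initial hill height) | 1.2 kJ/mol ≈ 0.48 kT | kJ/mol in files, kT internally | conventional gentle hill |
| hill σ | 0.02 | CV units | ≪ well width so the well fills smoothly |
| pace | 500 steps | — | walker diffuses ~a well width between deposits |
| dt, friction, kT | 1e−3, 1, 1 | toy units | diffusion constant 1; 5e5 steps ≈ 500 diffusion times |
| n_steps | 5·10⁵ (→1000 hills) | steps | long enough for shallow wells to empty and deep wells to fill |
| replicas | 3 | — | the standard protocol size; min over 3 is already conservative |
| quadrature grid | [0, 3.81], 1000 pts | CV units | wall onset + biased wall excursion (~0.6, measured) + 3σ; hills outside trigger a warning |

Energies are internally in kT; HILLS files follow the PLUMED kJ/mol
convention and convert at the file boundary using T (kT at 300 K =
2.494 kJ/mol). Both c(t) integrals are evaluated by trapezoid quadrature
in log space (log-sum-exp with the trapezoid weights folded in), so βV of
several hundred per grid point stays finite. Doubling the grid changes
c(t) by < 1e−4 kT on all fixtures; agreement with a 100×-finer Simpson
evaluation is < 1e−5 kT. c(t) is *not* asserted monotone in t — pointwise
bias growth does not force monotone c(t) for arbitrary hill placements —
though simulator-generated series are observed to climb.

Ties in all rankings are broken deterministically (score descending, then
ligand id ascending, then subsample replicate index), so every pipeline
output is bit-reproducible from its seed.

## The synthetic screen

`gen_library` draws well depths from normal distributions truncated at
zero: binders 8 ± 1 kT, non-binders 2 ± 1 kT, in a 5:27 composition
(≈16% hit rate, the realistic regime the subsampling protocol targets).
Each ligand gets `n_replicas` independent runs (replica seed = the
ligand's seed base + replica index). The compiled inner loop keeps the
bias force on a grid updated analytically per deposition; hill heights use
the exact hill-sum bias at the deposition point, so the HILLS record is
free of grid error.

What the generator emulates: a latent stability ordering, replica-to-
replica stochasticity, realistic binder/non-binder compositions, and the
HILLS-file interface of production runs. What it does not: docking-pose
errors, multi-dimensional escape paths, chemotype-dependent diffusion,
receptor flexibility, or any force-field error. Passing tests therefore
show that the estimator and protocol recover a planted stability signal
through the full pipeline — not that any particular protein system will
enrich.

With the default separation the pipeline ranks essentially perfectly
(screen EF30 at the 10/3 ceiling, depth–score Spearman ≈ 0.97); the
decision-relevant regime in practice is noisier. The null screen (all
depths zero) averages EF30 ≈ 1, with substantial per-screen quantization:
a 5/32 screen takes EF30 values in steps of 2/3, so a 5-screen mean has a
standard deviation near 0.3 even at perfect calibration.

## Degenerate inputs and edge cases

Empty hill lists are valid everywhere and give c ≡ 0 (a ligand whose
replica deposited nothing scores 0, the floor). `depth_sd = 0` collapses
the depth distributions to their means. Subsampling with k larger than
the binder pool is allowed (sampling is with replacement); duplicate draws
are kept as distinct rows sharing a score. EF is undefined without
binders and raises. Hills within 3σ of the grid's upper edge trigger a
truncation warning; the lower edge at s = 0 is exempt when the grid
starts there, since that is the physical boundary of the non-negative CV,
not a quadrature cutoff.

## Known limitations

The toy CV is one-dimensional; nothing here probes CV quality, which
dominates real applications. The c(t) integration domain must be chosen
to cover the deposited bias (configurable; warned about, not inferred).
BEDROC's discrete-N formula can exceed [0, 1] by O(1/N) at extreme
compositions. The simulator supports only the Gaussian-well potential in
its compiled path; the double-well and harmonic forms are available for
unbiased dynamics and estimator tests.
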