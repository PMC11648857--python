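# Methods

## Model and sampling scheme

The dynamics couple N predators (consumers) to M prey (resources) through
linear consumption with per-pair yields, optionally extended by
cross-feeding production P and higher-order prey regulation H of predator
growth. The moments of the mechanistic parameters are quoted before the
diversity scalings — C and P elements carry a 1/M factor, H a 1/M^{3/2}
factor — so that per-capita totals stay of constant order as M grows; this
is what makes the large-community limit well defined and puts the reduced
interaction eigenvalues at magnitude ~1/M against order-one effective prey
self-regulation.

Sampling works backwards from feasibility: mechanistic parameters and an
interior fixed point (S\*, R\*) are drawn first, then mortalities δ_i and
supply parameters (K_α or κ_α) are solved in closed form so that the fixed
point is exact. The residual of the full right-hand side at (S\*, R\*) is
checked against a tolerance of 1e−10 (in practice it is at machine
precision, ~1e−16, since the solve is exact algebra). Draws with
non-positive solved mortalities or with logistic carrying capacities below
R\*_α are rejected and redrawn, up to 100 retries before the specification
is declared infeasible; a permissive flag keeps negative mortalities for
algebraic studies, since the stability analysis itself does not require
δ > 0. Negative sampled yields are always kept — they model toxic prey and
are part of the ensemble.

Fixed-point abundances default to uniform draws on [0.5μ, 1.5μ] per level
(relative half-width 0.5, configurable). An equal-abundance mode
(S\* ≡ μ_S, R\* ≡ μ_R) exists because the analytic correlation estimate is
derived under equal abundances; validation tests use it, while phase
diagrams use the heterogeneous default to show the criterion's robustness.
Supply coefficients g_α (logistic) and l_α (chemostat) default to 1: only
the solved K_α/κ_α enter fixed-point consistency, and unit coefficients
keep the effective prey self-regulation of order one, which the reduction
argument needs.

All randomness flows from one root seed through `numpy.random.SeedSequence`
spawn keys: every community, sweep cell and classification run has a
deterministic child stream, so any single result can be regenerated in
isolation and whole tables are bit-identical across reruns regardless of
execution order.

## Stability three ways

1. **Direct spectrum.** The block Jacobian is assembled in closed form and
   its eigenvalues computed densely. The verdict uses a marginality
   tolerance of 1e−9 × the matrix max-norm; eigenvalues within that
   magnitude of zero are counted as zero modes. When predators lack
   self-regulation and N > M, the Jacobian has exactly N − M structural
   zero eigenvalues (its rank is at most 2M); these are removed by count —
   an algebraic fact, not a tolerance choice — before the verdict, since
   numerical round-off can scatter them slightly off zero. Verdicts on
   sampled communities default to the full Jacobian; the reduced-matrix
   route is a cross-check because the identity-self-regulation
   approximation is exact only in the large-community limit (the measured
   disagreement rate on mid-size panels is below 5%).

2. **Exact reduction.** Forcing the prey block to −a_eff·I makes the
   characteristic polynomial factor exactly into |M − N| degenerate modes
   plus quadratics λ(λ + a_eff) = λ_i driven by the eigenvalues of ΛVᵀ
   (N ≤ M) or VᵀΛ (N > M); the implementation reproduces a dense
   eigensolver to ~1e−14 on communities re-solved for identity prey
   self-regulation. At ties (N = M) either reduced matrix is valid (ΛVᵀ is
   used); the two share nonzero spectra exactly (AB vs BA).

3. **Random-matrix criterion.** With paired Gaussian matrices of element
   variance 1/M and aligned-element correlation −ρ, the eigenvalues of
   ΛVᵀ fill an ellipse centred at −ρ(1 + N/M) with real semi-axis
   √(N/M)(1 + ρ²). The variance normalization is fixed by requiring the
   degenerate case ρ = 1, N = M to reproduce the known [−4, 0] support of
   minus a Wishart spectrum, and the semi-axis convention (half-axis, not
   full axis) is fixed by requiring the ellipse edge to cross zero exactly
   at ρ = √(N/M) — the same point where the universal criterion
   ρ ≥ min(√(N/M), √(M/N)) and the diversity bounds N ≤ Mρ², N ≥ M/ρ²
   flip. This three-way mutual consistency is asserted in a unit test, and
   the boundary prediction is checked against sampled products at
   N = 200, M = 400 to within 0.05.

The printed forms of the criterion, the diversity bounds and ρ_est are
implemented with the radical signs that make these three formulations
mutually consistent (plain-text renderings of such formulas commonly drop
them); the consistency test is the guard.

## Dynamics and classification

Integration uses LSODA with rtol 1e−7 / atol 1e−10, in segments (default
25 over t_max = 1e4 for raw trajectory work; classification uses 40
segments over t_max = 4e5). After each segment, species below an
extinction floor of 1e−8 × the level's mean fixed-point abundance are
clamped to zero; zero is treated as absorbing for predators always (their
dynamics are multiplicative) and for prey only under logistic growth
without cross-feeding, since chemostat supply or production can legally
re-seed a prey. Early stopping triggers when every time-derivative falls
below 1e−9 × the abundance scale — deliberately stricter than the
convergence-drift threshold (1e−6) because the slowest linear modes decay
at rates ~1/M, and the final state must settle to well inside the
classifier's return tolerance before the run ends. The classification
horizon t_max = 4e5 is chosen as a multiple of that slowest timescale
(~1/|spectral margin| ≈ 1e4 at M = 64).

Trajectory summaries use the trailing 20% of stored times: *fluctuating*
means some surviving species has coefficient of variation above 1e−3
there; *converged* means relative drift below 1e−6 (or the integrator's
early-stop certificate). Classification runs n_init = 10 (tests and the
acceptance panel use 4–5) independent initial conditions resampled
uniformly on the fixed-point sampling ranges. Labels: S_f if every run
returns to the original fixed point (relative L∞ within 1e−3) with all
species surviving; F if any run fluctuates or fails to converge —
precedence F over the partial-coexistence labels, because one persistent
fluctuation already demonstrates loss of global fixed-point stability;
otherwise final states are projected onto principal components explaining
99% of variance and single-linkage merged at 5% of the mean state norm:
one cluster is GS_p, more are AS_p. All thresholds are exposed in control
dataclasses and recorded in outputs.

## Sweeps and the three-level experiment

Phase tables record the unstable fraction per grid cell with binomial
standard error √(f(1−f)/n) and the per-cell seed. The fast `jacobian`
mode reads stability from the community-matrix spectrum; the slow
`classification` mode counts every non-S_f label as unstable; the two
agree within pooled errors on validation grids.

The three-level experiment is a direct random-Jacobian assembly rather
than a mechanistic ODE: a block-tridiagonal matrix over bottom (M),
middle (N1) and top (N2) levels with correlated interface pairs at
correlation −ρ for both interfaces, element variance 1/(source-level
size) by analogy with the two-level normalization, per-level diagonal
self-regulation (defaults 1, 0, 1 — the middle level follows the
consumer-resource convention of no self-regulation), and structurally
zero top–bottom blocks. This construction is an interpretation: it
specifies the experiment only at the level of block statistics, which is
exactly the level at which the diversity-difference claim is made.
Instability peaks where M + N2 ≈ N1, and curves collapse against
(M + N2)/N1. When the middle level outnumbers its neighbours
(N1 > M + N2) its zero self-regulation implies N1 − (M + N2) structural
zero modes, handled by the same count-based exclusion as the two-level
case.

## What the generator does and does not emulate

The ensemble captures the statistical structure that drives the
diversity–stability phenomenology: 1/M-scaled consumption with adjustable
variation, i.i.d. Gaussian yields (including negative values), optional
cross-feeding and higher-order regulation, and both supply models. It
does not emulate invasion by species absent from the fixed point, spatial
structure, environmental stochasticity, intralevel interactions, or
correlated (non-i.i.d.) parameter structure beyond what H induces.
Passing tests therefore demonstrate the mechanism under the stated
statistical assumptions, not the behavior of any particular empirical
food web.

## Problem sizes

Default experiment sizes are chosen so a full validation pass runs on a
single CPU in minutes: 200-community fixed-point panels at 8×12; the
reduction oracle at up to 64×64; ρ_est Monte Carlo with ~1e4 aligned
pairs per setting; Marchenko–Pastur checks at N = 200, M = 400 with 10
replicates; the reentrant sweep at M = 24 with 50 communities per cell;
the classification panel at M = 64, N = 32 with ~30 communities × 4
initial conditions; the three-level grid at N1 = 32 with 20 draws per
cell. These are deliberate scale-downs of the same experiments at larger
sizes; the phenomenology (reentrant shape, peak locations, boundary
crossings) is already sharp at these sizes, while boundary *widths*
remain finite-size fuzzy — crossings are therefore compared within
multiplicative slack rather than pointwise.

## Known limitations

- ρ_est is derived under equal abundances; applied to heterogeneous fixed
  points it is an approximation (flagged in `CriterionResult`), validated
  numerically rather than proven.
- The criterion ignores outlier eigenvalues from nonzero matrix means;
  they are observed to be negative (non-destabilizing) but not treated
  analytically.
- Non-negligible predator self-regulation ε is supported in the sampler
  and Jacobian but the analytic criterion carries no ε correction; for
  large ε the criterion is conservative.
- Behavior labels at finite t_max can misread extremely slow transients
  as fluctuations; the horizon is sized against the slowest linear
  timescale, and label stability across classification seeds is measured
  (≥90% on test panels) rather than assumed.
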