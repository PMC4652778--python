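# Methods

## The problem

A purine base in duplex DNA can swap its Watson–Crick (WC) pairing for a
Hoogsteen (HG) pairing by rotating ~180° about its glycosidic bond, from the
*anti* to the *syn* conformer. Because the rotation is sterically hindered
inside the stacked helix, it can couple to base flipping — a transient
excursion of the base toward the major or minor groove. `hgflip` implements
the analysis layer of a two-dimensional umbrella-sampling study of this
transition: reaction-coordinate evaluation, bias bookkeeping, reweighting of
biased ensembles into a free-energy surface, characterization of the
transition pathways on that surface, convergence diagnostics, and the
nucleoside self-association analysis used to sanity-check base-stacking
energetics. The molecular-dynamics engine itself is out of scope; a
synthetic sampler produces statistically equivalent inputs with known ground
truth.

## Reaction coordinates

* **χ (glycosidic angle)** — the dihedral O4′–C1′–N9–C4 of the purine.
  *anti* is defined on [−180°, −90°), *syn* on [−90°, 90°]; (90°, 180°) is
  labeled `other`. All angles live on the canonical range [−180°, 180°),
  with +180° represented as −180° so histograms never double-count the seam.
* **CPDb (base-flip pseudodihedral)** — the dihedral P1–P2–P3–P4 of four
  centers of mass: the base pairs flanking the flipping pair (P1), two
  backbone phosphate groups bracketing it (P2, P3), and the five-membered
  ring of the flipping purine (P4). Flipping into the major groove gives
  CPDb > 0, into the minor groove CPDb < 0. The atom membership of P1–P3 is
  configurable (`PseudoatomSpec`); the default collects heavy atoms only,
  since deposited structures often lack hydrogens. The sign convention
  depends on the P2/P3 ordering — swapping the two phosphate groups negates
  the angle — so the package treats the order as part of the definition and
  documents that the mirror test fixes the chirality contract.

Dihedrals use the projection (atan2) formulation with the right-hand rule
about the b→c axis; collinear or coincident defining points raise a
degenerate-geometry error rather than returning noise.

## Umbrella windows and bias model

Windows tile the rectangle −100° ≤ CPDb ≤ 100° (13 evenly spaced centers,
endpoints included) × the full χ circle (24 centers, 15° apart), 312 windows
in total. The bias at window (i, j) is

    U_ij(CPDb, χ) = k_CPDb (CPDb − CPDb⁰_i)² + k_χ (χ − χ⁰_j)²

with defaults k_CPDb = 100 and k_χ = 50 kcal/mol/rad² and no ½ prefactor
(a `half_k` flag supports the other convention). Displacements are
minimal-image wrapped, so the bias is 360°-periodic in both arguments. The
force constants are interpreted per rad² — the common bias-engine
convention, and the one whose window widths (σ ≈ 3–4°) are consistent with
15–17° center spacing; per-deg² is available via `per_deg2`.

## Reweighting (WHAM)

The 2D surface is estimated with the self-consistent weighted-histogram
equations on a 5° × 5° grid (χ periodic): bin probabilities
p_l = n_l / Σ_i N_i e^{βf_i} c_il and shifts e^{−βf_i} = Σ_l c_il p_l, with
c_il the Boltzmann factor of window i's bias at bin l's center. Rather than
iterating the fixed point from scratch, the equivalent convex likelihood is
minimized with L-BFGS (analytic gradient, log-sum-exp throughout), then
polished with direct fixed-point sweeps until the residual — the maximum
change of any window shift under one sweep — is below 10⁻⁷ kcal/mol
(`max_iter` caps the sweeps; a non-converged result is flagged, never
silently accepted). F = −k_B T ln p is referenced so the lowest sampled bin
is zero; bins with zero reweighted counts are masked and stay masked through
every downstream statistic.

A per-bin quadrature of the bias Boltzmann factor is available
(`n_quad > 1`) but is off by default: with stiff restraints it pairs badly
with the piecewise-constant density assumption of the histogram equations
and measurably biases basin gaps at 5° bins, whereas bin-center evaluation
recovers the designed landscape within tolerance.

Samples are equally weighted; no autocorrelation (statistical-inefficiency)
correction is applied. R = 1.9872041 × 10⁻³ kcal/mol/K; default T = 300 K.

## 1D profiles

Three reductions of F(CPDb, χ) are provided, mirroring how 2D landscapes of
this kind are usually summarized:

* the **effective marginal** F(χ) = −RT ln ∫ P(χ, CPDb) dCPDb (bin-width
  quadrature, masked bins contribute zero probability), and the analogous
  F(CPDb);
* the **fixed-flip slice** F(χ | CPDb = 0), the rotation profile in the
  absence of base flipping;
* the **lowest-path profile**, the minimum of F over the other axis per bin.

All are min-referenced to zero over their sampled range.

## Basins, transition states, pathways

Minima are bins strictly lower than all sampled 8-neighbors (χ wraps);
minima within one bin merge, keeping the lower (ties broken
lexicographically). Labeling: WC = lowest *anti* minimum with |CPDb| ≤ 20°,
HG = lowest *syn* minimum in the same band, LS = any *syn* minimum with
CPDb < −40° (the minor-groove locally stable intermediate); everything else
is `other`.

Transition states are located by minimax (lowest-saddle) paths on the
8-connected bin graph rather than Hessian-based saddle search: bins are
inserted in order of increasing F into a union–find structure, and the
threshold at which the two basins join is the saddle energy; a path is then
recovered on the sub-grid below the threshold. This is robust to estimation
noise; its resolution is one bin.

The six-route taxonomy crosses rotation direction with flip amplitude.
Clockwise (R) is defined as net decreasing χ travel from WC to HG (through
the ±180° seam); counterclockwise (L) passes through χ ≈ −90°/0°. Direction
is enforced by cutting the χ column bisecting the opposite corridor.
Small-flip routes (R1, L1) are minimax paths confined to |CPDb| ≤ 20°.
Opening routes must perform the rotation while flipped out: outside χ
corridors of ±25° around the two basins, only bins with CPDb ≥ +60° (major
groove: R2, L2) or ≤ −60° (minor groove: R3, L3) are allowed. The 20°/60°
cutoffs are the standard small/large flipping thresholds for this system;
the basin-corridor half-width (25°) is the one genuinely free parameter of
the operationalization and is exposed as an argument. Every local maximum
of a path's energy profile (prominence ≥ 0.5 kcal/mol) is reported as a
sub-transition state — minor-groove routes typically carry two, flanking
the LS intermediate. ΔG between basins is the difference of their minimum
bin values; barriers are TS minus basin.

## Convergence diagnostic

For each requested fraction f the surface is re-estimated from the first
⌈f·n⌉ samples of every window and compared with the full-data surface: RMS
over bins sampled in both, after aligning the two surfaces by their mean
difference on the common bins. The comparison threshold reported alongside
is k_B T (0.596 kcal/mol at 300 K): a cumulative series whose final-quarter
RMS is below thermal noise is considered converged.

## Aggregation analysis (equal-K model)

Two molecules aggregate when their centers of mass are within 3.5 Å
(minimum image in orthorhombic boxes); clusters are connected components of
the contact graph. The osmotic coefficient of a frame is
φ = (number of clusters)/(number of molecules) — the molal bookkeeping
reduces to this ratio because the kg-solvent factor cancels. Under the
equal-K model (one association constant for every oligomerization step),
(1 − φ)/φ² = K_A·m_T; K_A is fit as the unweighted least-squares slope
through the origin, and the inverse map is
φ = (−1 + √(1 + 4K_A m_T))/(2K_A m_T).

## The synthetic generator

**Model landscape.** F(CPDb, χ) = V_flip(CPDb) + h(CPDb)·W(χ) + wells, with
W a periodic cubic spline through control points (the rotation profile at
CPDb = 0), V_flip a cubic spline (the flipping profile at the WC χ), and
h(CPDb) = 0.6 + 0.4·exp(−(CPDb/35°)²) a coupling factor making rotation
cheaper once the base is flipped out. A Gaussian well adds the minor-groove
intermediate at (−57.3°, 51.2°); a quadratic wall beyond |CPDb| ≈ 120°
closes the sampled range. The defaults are design targets, not claims about
real DNA: basin gap ΔG(WC→HG) = 4.4 kcal/mol (calibrated at construction by
adjusting the HG well knot until the fine-grid gap matches within 0.02
kcal/mol), small-flip route barriers ≈ 11 kcal/mol and opening routes
≈ 12.7–13 kcal/mol (all route saddles at *syn* χ), and 1D opening barriers
of ≈ 8.0 (major) / 8.3 (minor) kcal/mol. What passing recovery tests shows
is that the estimator and path analysis faithfully recover a landscape of
this shape from biased sampling at these noise levels — not that real DNA
has these numbers.

**Window sampler.** Metropolis Monte Carlo directly in (CPDb, χ) space on
F + U_window: normal proposals (default σ = 4°/5°, acceptance ≈ 0.4–0.5 on
the default landscape), 1000 equilibration steps from the window center,
then every 5th step kept until 3000 samples per window (16 000 steps). MC in
collective-variable space produces exactly the statistical object the
estimator consumes; it does not emulate the kinetics, solvent coupling, or
hidden-variable autocorrelation of real MD — which is why the convergence
diagnostic on synthetic data converges faster than a real trajectory would.
Per-window random streams are seeded from (master seed, window id), so
results are identical whether windows run singly or batched, and
bit-reproducible across runs. Zero acceptance during equilibration raises a
step-size error.

**Well-tempered walker.** A toy metadynamics run deposits Gaussian hills
(w₀ = 1 kcal/mol, every 50 MC steps, widths 10°) with heights scaled by
exp(−V/k_BΔT), bias factor γ = (T + ΔT)/T = 15. The bias accumulates on a
2.5° grid (nearest-node lookup), which is ample for its only job here:
demonstrating coverage of the window grid (the fraction of the 312 window
cells visited) and the well-tempered height decay.

**Aggregation data.** For each molality, cluster sizes are drawn i.i.d.
from the equal-K geometric distribution (P(i) = (1 − x)x^{i−1},
x = K_A·[monomer]) until a frame holds at least 16 molecules, keeping the
last cluster whole; the per-point φ is pooled clusters over pooled
molecules, which Wald's identity makes an unbiased estimate of the model φ.
An optional geometric mode realizes each frame as coordinates in a periodic
box (clusters on a jittered lattice, members within 1.2 Å steps) so that
the 3.5 Å criterion reproduces the drawn distribution exactly.

## Numerical choices and problem sizes

* WHAM: 5° bins, tol 10⁻⁷ kcal/mol, L-BFGS + fixed-point polish; typical
  full-suite solve converges in a few hundred effective iterations.
* The shipped study size — 312 windows × 3000 samples — recovers the
  designed surface with RMSE ≈ 0.22 kcal/mol (bins with F_true < 12), ΔG
  within ≈ 0.2 and the lowest route barrier within ≈ 0.35 kcal/mol across
  seeds, and keeps a full pipeline run in a few minutes on one core.
* Basin merge radius 1 bin; minimax ties resolved by insertion order of
  equal-F bins (lexicographic).
* Degenerate inputs fail loudly: empty ensembles, bins not covering
  samples, fully-masked slice rows, disconnected basins, φ = 0 transforms.

## Known limitations

* Bin-center bias evaluation and 5° bins limit saddle placement to one bin;
  barriers inherit that resolution.
* No autocorrelation correction: error bars of recovered quantities are
  not reported, only point estimates against known truth.
* The route taxonomy assumes exactly one WC and one HG basin; surfaces
  without an *anti* minimum only warn.
* The CPDb sign convention is a definition (P2/P3 order), not derived from
  groove geometry; applying the package to a real duplex requires checking
  the sign on a known structure once.
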