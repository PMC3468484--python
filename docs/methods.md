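# Methods

## Model

Antibody synthesis, assembly and secretion are modelled as deterministic
mass-action kinetics in molecules per cell, with time in hours. Species are
heavy- and light-chain mRNA (H.RNA, L.RNA), free chains (H, L), the
off-pathway light-chain dimer (LL), the half-antibody (HL), the heavy-chain
dimer and its single-light-chain adduct (HH, HHL), the assembled antibody
(LHHL), and four cumulative extracellular pools (mAb_ex, HL_ex, LL_ex,
L_ex). Three topologies are built from one reaction catalogue:

| constant | reaction | rate law | units |
|---|---|---|---|
| K1, K3 | ∅ → mRNA | K | molecules·h⁻¹ |
| K2, K4 | mRNA → ∅ | K·[mRNA] | h⁻¹ |
| K5, K8 | mRNA → mRNA + chain | K·[mRNA] | molecules·RNA⁻¹·h⁻¹ |
| K7 | H + L → HL | K·[H][L] | molecule⁻¹·h⁻¹ |
| K10 | 2 L → LL | K·[L]²/2 | molecule⁻¹·h⁻¹ |
| K16 | 2 HL → LHHL (HL route) | K·[HL]²/2 | molecule⁻¹·h⁻¹ |
| K19 | 2 H → HH (HH route) | K·[H]²/2 | molecule⁻¹·h⁻¹ |
| K21, K22 | HH + L → HHL, HHL + L → LHHL | K·[·][L] | molecule⁻¹·h⁻¹ |
| kexp_* | species → extracellular pool | K·[·] | h⁻¹ |
| µ | dilution of every intracellular species | µ·[·] | h⁻¹ |

Homodimerisations are written on the monomer-consumption convention: a
reaction 2X → X₂ with constant K consumes monomer at K·[X]² and forms dimer
at K·[X]²/2. This convention is what makes the dimerisation constants
recoverable from measured panels as K = 2·(q + µ·[dimer])/[monomer]².

The HL topology (11 states) carries K7+K16; the HH topology (13 states)
carries K19/K21/K22 with the half-antibody retained as a terminal,
exported by-product formed by K7 — the half-antibody is abundantly measured
and secreted in every line, so a heavy-dimer assembly route must still
account for its formation; it simply is not on the productive path there.
The combined topology is the union, with the LHHL-formation flux split
between routes by a `route_fraction` φ (default 0.5: the data cannot
distinguish any proportion, so the representative member of the family has
both routes equally active; φ = 0 and φ = 1 reproduce the pure topologies
exactly).

Assumptions inherited from the modelling setting: cells in mid-exponential
batch culture are at an intracellular steady state (constant growth and
productivity); intracellular protein turnover is negligible against
pathway flux; extracellular pools neither degrade nor feed back; no
stochastic kinetics.

## Steady-state inference

With zero protein turnover, the measured secretion rates (qmAb, qHL, qLL,
qL) and growth dilution are the only mass outflows, so species balances
propagate backwards from the exports: LHHL-formation flux = qmAb + µ·[LHHL],
HL consumption = 2×(LHHL formation via K16) + qHL + µ·[HL], and so on up to
the translation and transcription fluxes. Constants are flux/abundance
ratios. Censoring conventions:

* abundances below the 10⁵ molecules/cell detection limit contribute **zero
  dilution flux** but stand in **at the limit as divisors** where a constant
  needs them;
* censored secretion rates are imputed **at the detection limit** (a line
  that visibly grows and secretes has bounded-but-nonzero exports; imputing
  zero would zero its export constants and make any downstream perturbation
  analysis degenerate). `censored_q="zero"` switches to zero-imputation;
* every constant whose computation touched a censored input is flagged
  `censored_derived` — such values are bounds, not estimates, and are
  excluded wherever constants are pooled across lines.

**Sub-detection intermediates.** When HH/HHL are censored, (K19, K21=K22)
cannot be identified: any point of a one-parameter family (parametrised by
the assumed steady [HHL]) reproduces the panel exactly, because the chain
2H → HH → HHL → LHHL only needs to carry the right flux. The fit evaluates
the squared relative residuals of all measured quantities at the full model
steady state over a deterministic log grid of [HHL] levels (capped by the
detection limit and by the LHHL pool), refines with bounded scalar
minimisation, and breaks the tie on the flat zero-residual manifold with a
negligible (1e-12-weighted) regulariser toward [HHL] = limit/2. K21 = K22
is a structural tie, matching the equal printed values of the two
light-chain-addition constants.

**Combined-model pseudo-inverse.** The steady-state balances are linear in
the 14 unknown constants, giving a 13×14 system per line whose raw columns
span ~14 decades (singular values from ~10¹⁴ down to order 1) — the
estimation problem is genuinely ill-conditioned, which is reported as the
condition number of the raw design matrix. For the numerical solve the
columns are equilibrated to unit norm first; without equilibration the SVD
cutoff silently truncates the molecules-scale transcription columns.
Minimum-norm pseudo-inversion resolves the route split: with HH/HHL absent
the HH-route columns vanish and the solution coincides with the direct HL
sub-model inference.

## Engineering model and observability

The linear model is the analytic Jacobian A at the fixed point (bilinear
terms contribute e.g. ∂(K7·H·L)/∂H = K7·L), with output rows built from the
export constants (each q is kexp × one state). Extracellular columns of A
are structurally zero — cumulative pools never feed back — so A is block
triangular. Step-response tests integrate the nonlinear model and the
linear model under the same rate-constant step and report per-species
maximum relative divergence.

Two observability questions are kept distinct:

1. **Sensor question** (`observability`): given sensors on a state subset,
   the Kalman matrix O = [C; CA; …; CAⁿ⁻¹] is formed (rows normalised to
   unit ∞-norm), its rank computed by SVD with tolerance
   σ_max·n·eps·10³ (exposed, because h⁻¹-scale spreads make rank decisions
   tolerance-sensitive), and qmAb is reconstructible iff its output
   direction lies in O's row space.
2. **Determination question** (`minimal_observable_set`): which initial
   states does the output trajectory actually depend on? A subset S
   determines the output iff every column of O outside S is numerically
   zero; the search is exhaustive over subsets, smallest first,
   lexicographic in state order.

The default output is the full secretion block (all four q's — the
quantities the assay actually measures). With it, the minimal determining
set of the 13-state combined model is exactly the nine intracellular
species. With qmAb as the sole output the count drops to eight: LL is an
absorbing by-product that never re-enters the assembly chain, so it cannot
influence qmAb — structurally true in this network, and the reason the
single-output reading is not the default.

## Pathway analyses

Flux maps are normalised per line to the largest single reaction flux.
Export partition: productive = qmAb, non-productive = qL + qLL + qHL;
cross-line variability is compared by coefficients of variation.
Parameter clustering uses distance 1 − Spearman ρ across lines (ranks with
average tie-breaking), average linkage, rows sorted alphabetically for
deterministic leaf order, flat clusters at a configurable cut (default
0.5). Constant rows (the all-censored HH/HHL) have undefined ρ and are
dropped with a warning. Cluster "significance" is an empirical permutation
p-value (999 row-rank shuffles, seeded) of the mean within-cluster
distance — an interpretation, since no specific test is canonical here.
With only four lines Spearman ρ takes few values; the clustering is a
rank-pattern summary, not an inferential claim.

Perturbation scans multiply one production constant (K1/K3/K5/K8) over a
21-point log grid in [0.1, 10] and re-solve the steady state (warm-started
from the previous multiplier; non-converged points are flagged and
returned as NaN). At steady state K1 and K5 scans are equivalent: only the
product K1·K5 enters the protein-level balances.

## Naive-line prediction

A reduced panel is the nine intracellular abundances plus growth rate.
Missing pieces are transferred from training lines:

* export constants and translation constants pool as **geometric means over
  lines whose defining measurement was uncensored** (constants flagged
  `censored_derived` are bounds and are excluded); arithmetic-mean and
  most-productive-line estimators are available;
* production fluxes for the new line follow from its abundances plus the
  transferred export constants; implied mRNA = production flux / pooled
  translation constant; K1 = (µ + K̄2)·[H.RNA]_implied, likewise K3. All
  intermediates are returned in the diagnostics for audit;
* K8 for each sub-model is the light-chain production flux divided by the
  geometric-mean training L.RNA (K8 is only identifiable jointly with an
  assumed transcript level); the combined estimate is the arithmetic mean
  of the HL and HH estimates. Chain conservation makes those two coincide:
  either route consumes exactly two light chains per assembled antibody.

The **nonlinear prediction** solves the fully parameterised model for its
steady state and reads qmAb = kexp_mAb·[LHHL]. The **linear route** takes a
single first-order (Newton) step from each training line's operating point
under the new parameter set and reads the same output, aggregated by
median across training lines. It is included as a control: first-order
extrapolation across constants that vary by orders of magnitude between
lines is not a credible predictor, and the package reports it as such
rather than hiding it.

## Culture measurements

IVC is the trapezoidal time integral of viable cell concentration (interval
average × width; window endpoints interpolated linearly, which is exactly
trapezoid-consistent). q_P = Δ(cumulative product)/ΔIVC over a window
defaulting to 0–96 h (day 0 to day 4 of the constant-productivity phase).
Note the protocol-inherent bias: trapezoids over daily samples of an
exponential VCC overestimate IVC by ≈(µΔt)²/12, biasing q_P low by ~2–6%
for µ = 0.02–0.036 h⁻¹ — sampling twice daily keeps it under 1.5%. mRNA
decay constants come from OLS on log(level) vs time over the 0–6 h arrest
window; non-decaying series return k = 0 (half-life ∞) with a warning.

## Synthetic data

A virtual line is a rate-constant set drawn log-uniformly within
per-constant ranges bracketing the four measured NS0 lines (and, for the
HH-chain constants, the wider ranges reported for CHO systems); K21 = K22
is kept tied as in the fitted models. Its "measurement" is the exact model
steady state and secretion rates, corrupted by multiplicative log-normal
noise (default CVs 20% protein, 25% mRNA, 15% q — quantitative
western/qPCR-scale error, a calibration choice of this package) and
left-censored at 10⁵ molecules/cell. Censoring is decided on the noiseless
value (the limit is an assay property); deciding on the noisy value is a
flag. One global seed; per-line substreams derive from a CRC32 hash of the
line name, so panels are reproducible item-by-item.

What the generator emulates: the measurement structure of a steady-state
panel (scales, multiplicative noise, left-censoring, censored HH/HHL).
What it does not: model misspecification (real assembly has more steps and
real turnover is not exactly zero), correlated assay errors, growth-phase
drift, or biological replicate variance. Passing recovery tests therefore
demonstrate the *inference machinery* is correct and noise-robust, not
that the model is biologically complete.

## Numerical choices

* `simulate`: Dormand–Prince RK45, rtol 1e-8, atol 1 molecule (method
  switchable; LSODA recommended for fitted HH chains, whose light-chain
  addition rates create ~10⁻⁷ h timescales).
* `steady_state`: damped Newton (analytic Jacobian, backtracking line
  search, non-negativity clamp) from a closed-form cascade guess or a
  supplied warm start; on stall, LSODA integration over 10/µ h and
  re-polish, horizon ×10 up to 2×10⁵ h. Convergence:
  max |dx/dt|/(|x|+1) < 1e-9 over intracellular states. Extracellular
  pools are cumulative and returned as zeros (their slopes are the q's).
* Degenerate inputs: all-zero inflows give the zero fixed point; µ = 0
  with inflow and no outflow raises; negative states raise (integration
  contract).
* Problem sizes: the packaged study is 4 training lines × 3 topologies;
  the synthetic recovery study uses 100 seeded lines per noise level
  (seconds on one CPU); observability search enumerates ≤ 2¹³ subsets.

## Limitations

* The apparent constants lump many elementary steps; they parameterise the
  observed steady state and support flux/sensitivity reasoning, but have
  no claim to elementary-rate meaning.
* K19/K21/K22 (and the HL/HH route split in the combined model) are not
  identifiable from panels with sub-detection intermediates; the package
  returns a deterministic representative of the valid family and flags it.
* With four cell lines, clustering and rank correlations are descriptive.
* The naive-line prediction depends on the export-constant transfer rule;
  the geometric mean over uncensored training lines is the default and the
  alternatives are exposed, because no canonical rule exists for n = 3
  usable lines.
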