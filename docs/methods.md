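# Methods

This note documents the models implemented in `m6afold`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Two-state melting thermodynamics (`m6afold.melt`)

A melting transition is treated as two-state. For a bimolecular,
self-complementary duplex the folded fraction is

    f_duplex(T) = 4e / (1 + 4e + sqrt(1 + 8e)),   e = exp[(1/T_m − 1/T)·ΔH/R]

which is an algebraically exact, numerically stable rearrangement of the
textbook root expression (the rearrangement avoids catastrophic
cancellation as e → 0 and overflow as e → ∞; the exponent is additionally
clipped at ±500). For a unimolecular hairpin

    f_hairpin(T) = e / (1 + e)

evaluated with the overflow-safe logistic. Both satisfy f(T_m) = ½ exactly
and are monotone decreasing in T for ΔH < 0. R = 0.0019872 kcal mol⁻¹ K⁻¹.

Fitting: nonlinear least squares (`scipy.optimize.least_squares`) for
(T_m, ΔH), with a deterministic multi-start — T_m initialized at the
observed signal midpoint and ±5 K, ΔH at −40 kcal/mol scaled by
{0.5, 1, 2}; lowest residual wins, ties broken by start order. Raw
absorbance traces are fitted with jointly estimated linear folded/unfolded
baselines (four extra parameters), A(T) = (b_f + m_f T)·f + (b_u + m_u T)·(1 − f);
folded-fraction data are fitted directly. Whether experimental absorbance
traces should be baseline-corrected before a two-state fit is
instrument-dependent, so both modes are provided and the choice is explicit.

Derived quantities: ΔS = ΔH/T_m (hairpin) or ΔH/T_m − R ln(C_T/2) (duplex,
C_T the total strand concentration, typically 3 µM here), and
ΔG(T) = ΔH − T·ΔS. Two algebraic consequences are asserted in tests:
ΔG(T_m) = 0 for hairpins and ΔG(T_m) = R·T_m·ln(C_T/2) for duplexes.
The default evaluation temperature is 310.15 K (37 °C).

Methylation contrasts are reported signed, ΔΔX = X(methylated) −
X(unmodified), with **negative ΔΔG meaning methylation stabilizes**.
Uncertainties: standard deviation across replicate fits when ≥ 3 replicates
are provided, otherwise a seeded parametric bootstrap (500 resamples by
default) on the fit residual scale; ΔΔ uncertainties combine in quadrature.

## Binding isotherms (`m6afold.binding`)

One-site binding with ligand depletion uses the quadratic-root bound
fraction in conjugate form,

    f_b = 2·L_t / (R_t + L_t + K_D + sqrt((R_t + L_t + K_D)² − 4·R_t·L_t)),
    A_t = A + (B − A)·f_b.

The discriminant is provably nonnegative, f_b ∈ [0, 1], A_t(0) = A and
A_t → B at saturation — these limits are what fix the formula's form, and
they are asserted numerically. Two independent sites use the free-ligand ≈
total-ligand approximation (valid because the labeled RNA is at 2 nM, far
below the fitted constants; a flag is raised if R_t > 0.01·K_D1):

    A_t = (A + B·L/K_D1 + C·L²/(K_D1·K_D2)) / (1 + L/K_D1 + L²/(K_D1·K_D2)),

a convex combination of the free (A), singly bound (B) and doubly bound (C)
anisotropies.

Fitting is deterministic multi-start least squares in log₁₀-K space; the
two-site model parameterizes log₁₀(K_D2/K_D1) ≥ 0, which fixes the
K_D1 ≤ K_D2 labeling convention. Model choice uses the small-sample
corrected Akaike criterion (AICc) — the one- and two-site curves are not
nested in their parameterization, and AICc penalizes the two extra
parameters. Weak binders whose fitted K exceeds the highest titrated
concentration are flagged as lower bounds, not point estimates; flat
titrations are flagged K_D-unidentifiable. The intensity QC follows the FP
convention that total fluorescence should vary little across the titration:
ratio = (I_max − I_min)/I_min, pass below a configurable threshold
(default 0.10; a ~5% variation is the benchmark good regime).

## Folding engine (`m6afold.energy`, `m6afold.fold`)

The energy model is a deliberately *simplified* Turner-style
nearest-neighbor parameterization, shipped as a versioned, serializable
table (`m6afold-simple-nn-1`): stacking energies keyed by the unordered
pair-type pair (AU/GC/GU — orientation-collapsed, which enforces
strand-reversal symmetry), hairpin/bulge/internal-loop penalties by length
with 1.08·ln(n/n_max) kcal/mol extrapolation, a ±|n₁−n₂| internal-loop
asymmetry term, an affine multiloop cost (3.4 + 0.4/branch +
0.1/unpaired), a 0.5 kcal/mol terminal penalty on helix-closing AU/GU
pairs, and length-1 bulges retaining the flanking stack. Allowed pairs are
AU/UA, GC/CG, GU/UG; hairpin loops need ≥ 3 unpaired nt; lonely pairs are
permitted by default (a filter toggle exists). Reproducing any specific
published energy table is explicitly out of scope — externally predicted
structures can be imported (dot-bracket/CT) and drive the classifier
directly, so the survey machinery is predictor-agnostic.

Energies are integer centi-kcal/mol internally, making energy-window
thresholds and ensemble set-comparisons exact.

MFE uses Zuker-style interval dynamic programming (pair matrix V,
multiloop-segment matrix M with ≥ 1 branch, exterior matrix W).
Suboptimal enumeration is Wuchty-style: recursive generators mirror the DP
decompositions, prune with exact DP lower bounds, and — because every
generator realises a *unique* decomposition of its structure class — the
union of yields is complete and duplicate-free by construction. Percent
windows use threshold = MFE + |MFE|·(p/100), stated explicitly because a
percentage of a negative energy is otherwise ambiguous. A configurable
structure-count guard (default 50 000) raises rather than truncating
silently. Ties are broken by sorting on (energy, dot-bracket string); since
'(' precedes '.', this prefers 5ʹ-most pairing deterministically.

The brute-force enumerator recursively builds every valid non-crossing pair
set (guarded to ≤ 22 nt) and scores each with an independent
loop-decomposition walk of the pair set — a second path to the same
energies that serves as the oracle for the DP and for subopt completeness
(set equality is asserted on seeded random sequences).

With the lonely-pair filter enabled, the MFE search widens the enumeration
window until a lonely-pair-free structure appears (the empty structure at
0 kcal/mol guarantees termination); this costs an enumeration and is a
convenience toggle, not the default path.

## Motif classification (`m6afold.motifs`)

Categories are mutually exclusive and exhaustive by construction of the
decision procedure (property-tested by exhaustive enumeration over all
structures of random short sequences):

1. **Pairing.** If the focal A is paired, its partner defines AU (partner
   U) vs AY (any other base — only produced by predictors that emit
   non-canonical pairs). If unpaired, *mismatch imputation* applies: an A
   immediately adjacent to a canonical pair and facing exactly one unpaired
   nucleotide across that pair (a 1-nt internal-loop face, i.e. the facing
   position's neighbors are both paired) is treated as mismatched with that
   position. This operationalizes the standard workaround for predictors
   that reject mismatches; when both neighbors qualify the 3ʹ pair wins
   (the motif's stacking partner). An imputed partner that happens to be U
   is classified as AU by partner base. Otherwise: **unpaired**.
2. **Junctional test.** The (possibly imputed) pair (i, j) is junctional
   iff either flanking stack is broken — inner (i+1, j−1) or outer
   (i−1, j+1) not paired to each other (chain ends count as broken). G–U
   wobbles count as canonical throughout. Non-junctional → duplex.
3. **Bulge side.** Among the unpaired runs flanking the pair, precedence is
   5ʹ-of-A > 3ʹ-of-A > partner-side (the 5ʹ bulge is the motif of
   interest; the A-side over partner-side order follows from that, and
   5ʹ/3ʹ cannot tie because the A-side run on the side of the adjacent
   helix is empty). Any run of ≥ 1 unpaired nt counts as a bulge — apical
   and multibranch loops included — and the run length is recorded so
   stricter definitions can filter downstream. A junctional pair with no
   unpaired flank at all (e.g. a helix end at the molecule boundary) stays
   in the duplex category with the junctional flag set.

Sequence direction, not strand, defines 5ʹ/3ʹ: the rules work identically
for a focal A on either side of the pair.

### ΔΔG offset tables and re-ranking

`M6APenaltyTable` carries signed per-category ΔΔG offsets (negative =
stabilizing) measured at 37 °C on designed hairpin constructs: with Mg²⁺ —
fiveB_AU −0.9, duplex_AU +0.6, AU_threeB +1.2, unpaired +0.7,
partner_bulge +0.4 kcal/mol; without Mg²⁺ — fiveB_AU −0.3, duplex_AU +0.8,
partner_bulge +1.4, with the 3ʹ-bulge and unpaired values carried over
where behaviour was similar across conditions. Categories without a
measured contrast default to 0. `rerank_with_m6a` adds each structure's
category offset to its energy and re-sorts, reporting whether the MFE
identity changed — modeling how methylation can promote a higher-energy
5ʹ-bulge structure to most-stable (with the default table a duplex-MFE is
overtaken when the junctional alternative lies within 1.5 kcal/mol).
Applying hairpin-derived offsets to arbitrary contexts is an
approximation; results carry an `approximate` flag.

## Surveys (`m6afold.survey`)

MFE mode counts each site once by the category of its lowest-energy
structure (counts sum to n). Threshold mode counts a site toward the
fiveB_AU / fiveB_AX populations if *any* structure within MFE + threshold
shows the motif, matching the "number of sequences predicted to form the
motif in the output structures / total sequences" convention; fractions
are therefore monotone non-decreasing in the threshold, and
fiveB_AX ≥ fiveB_AU always (AX = AU ∪ AY). Default windows are 41 nt with
the site A at position 21 (variants such as 31 nt with the A at position
11 are parameters); sites too close to a transcript end are skipped and
tallied, not fatal. Minus-strand sites are extracted from the reverse
complement with flipped coordinates. Control sites are uniform draws of
A-centered windows rejected while they contain any DRACH match
([AGU][AG]AC[ACU]).

Published transcriptome-scale percentages for this kind of survey depend
on the external site list and on the exact energy tables of the predictors
used; this package reproduces the *procedure* and its order/monotonicity
properties at desk scale, and ingests external predictions for users who
have them.

## Synthetic data (`m6afold.simulate`)

Generators are pure functions of a (seed, n, σ) spec. Melting curves are
drawn from the two-state models on an 81-point 15–95 °C grid with i.i.d.
Gaussian noise (σ = 0.01 folded-fraction units by default); titrations from
the binding isotherms at R_t = 2 nM with σ = 0.002 anisotropy units — no
noise model being dictated by the assays, i.i.d. Gaussian is the neutral
choice. Transcripts are uniform-composition (GC fraction exposed) with
DRACH 5-mers planted at recorded, non-overlapping positions. Motif windows
come from eight hand-designed templates whose engine-MFE structure *is* the
designed structure (asserted in tests) and realise one category each;
`gen_motif_transcriptome` embeds them between poly-A spacers (inert: A's
cannot pair each other, and any A·U helix they could form against loop
nucleotides costs more in loop penalties than it gains), so windows cut
around the planted sites re-fold to their labels — the basis of the
end-to-end recovery test.

What the generators do **not** emulate: real transcriptome sequence
statistics (composition bias, repeats, isoforms), site-calling errors from
antibody/crosslinking protocols, instrument drift or correlated noise in
melting/FP measurements, and multi-state melting. Passing tests therefore
demonstrate correctness of the *computational* chain under its stated
assumptions, not robustness to those experimental artifacts.

## Problem sizes and determinism

The validation suite uses sizes chosen to make the oracles exact and the
statistics tight: brute-force cross-checks on 100 random sequences ≤ 18 nt
(complete subopt equality ≤ 14 nt), 200-replicate Monte-Carlo recovery for
melting and one-/two-site binding fits, 50 replicate pairs per ΔΔG
contrast, and 100 seeded model-comparison replicates. All randomness flows
through explicit integer seeds; identical configs produce byte-identical
survey outputs.

## Known limitations

- The energy model ranks structures plausibly but is not calibrated to any
  measured parameter set; absolute energies (and hence percent-window
  semantics) differ from production folders. Import adapters are the
  intended route when fidelity matters.
- No pseudoknots, no partition function / pair probabilities, no dangles,
  no coaxial stacking.
- Mismatch imputation only recognizes 1-nt internal-loop faces; wider
  loops classify as unpaired, and multibranch-loop mismatches are not
  imputed.
- The two-site binding model inherits the free-ligand approximation; very
  tight binders at higher RNA concentrations would need a
  depletion-corrected form, which is out of scope.
- ΔΔG offsets are context-transferred constants, not sequence-dependent
  nearest-neighbor corrections.
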