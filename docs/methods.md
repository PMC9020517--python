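# Methods

This note documents the models behind `phosphoubl`, the parameters
that matter, the design choices made where the design was genuinely
open, and what the synthetic-data generators do and do not emulate.

## Conformational-exchange model

S65-phosphorylated Ub and NEDD8 interconvert slowly (on the NMR
chemical-shift time scale) between a relaxed state (m), close to the
unmodified protein, and a retracted state (n) in which the C-terminal
β5-strand slips one register toward the core. In slow exchange each
backbone amide contributes one cross-peak per state, so state-resolved
peak lists — not spectra — are the package's primary input. Peaks that
cannot be ascribed to a single coherent set (for pNEDD8 the D21/I36/G47
pattern) carry an `ambiguous` label and are excluded from all
state-specific analyses.

### Weighted chemical shift perturbations

Δω = √[ ((Δ¹H)² + (Δ¹⁵N)²/25) / 2 ] in ppm. The 1/25 weight maps the
wider ¹⁵N dispersion onto the ¹H scale. Classification thresholds are
the profile mean and the mean plus one standard deviation, computed
over observed residues only; missing residues (prolines, unassigned,
exchange-broadened) are recorded as absent, never as zeros. The SD is
the sample (n−1) deviation by default — the conservative choice at
panel sizes of a few dozen residues — with the population convention
available via `ddof=0`. Assignment transfer between near-identical
spectra (e.g. pUb → its phosphonate analog ⁿʰpUb) uses globally optimal
bipartite matching under the same weighted metric rather than greedy
nearest-neighbor matching, which makes the transfer deterministic and
order-independent; the default dissolution cutoff of 0.15 ppm
(weighted scale) is an exposed parameter, chosen as roughly half a
typical well-resolved peak separation.

### State populations

For each residue with resolved m/n peaks, f_n = I_n/(I_m + I_n) from
signal heights (heights, not volumes — heights are what peak-picking
software exports reliably for partially overlapping peaks, and the two
conformers of one residue have near-identical linewidths). A
construct-level estimate averages f_n over a fixed panel of
well-separated pairs — 17 residues each for pNEDD8, pUb, and ⁿʰpUb,
shipped as package data and validated against the mature sequences at
import. Averaging per-residue fractions (rather than pooling summed
heights) treats each resolved pair as an independent estimate of the
same population; the pooled mode is available as an option. The
reported "±" is the cross-residue sample SD; the SEM is reported
alongside since printed uncertainties on populations can denote either
spread.

### ZZ-exchange kinetics

The simulator propagates two-site longitudinal exchange with
equilibrium populations (p_A relaxed, p_B retracted), detailed-balance
rates, and a shared longitudinal relaxation rate R1:

    I_AA(t) = A p_A (p_A + p_B e^{−k_tot t}) e^{−R1 t}
    I_BB(t) = A p_B (p_B + p_A e^{−k_tot t}) e^{−R1 t}
    I_AB(t) = I_BA(t) = A p_A p_B (1 − e^{−k_tot t}) e^{−R1 t}

The fit model is the relaxation-compensated ratio
R(t) = I_AB I_BA / (I_AA I_BB − I_AB I_BA), which cancels the
amplitude and the shared R1 exactly; its closed form under this model
is R(t) = 4 p_A p_B sinh²(k_tot t / 2) (verified in the test suite
against matrix-exponential propagation to 1e−10). In the small-t limit
R → k_AB k_BA t², so the conventional quadratic fit R = k_conf² t²
measures the **geometric mean of the forward and backward rates**.
The package adopts that operational definition: `simulate_zz` is
parameterized by k_conf = √(k_AB k_BA), with
k_tot = k_conf / √(p_A p_B). At near-equal populations this
coincides with the per-direction rate to better than 1%.

One numerical consequence matters at the mixing times modeled here
(20–100 ms): the quadratic approximation's relative error grows as
(k_tot t)²/24, which for k_conf = 8.3 s⁻¹ reaches ≈ +12% at the 100 ms
point and biases the straight-line fit of √R vs t by ≈ +9%. The
default fitting method therefore inverts the exact closed form
instead: the populations are read off each timepoint from
magnetization conservation (I_AA + I_AB ∝ p_A, I_BB + I_BA ∝ p_B),
asinh-linearization √(R/(4 p_A p_B)) = sinh(k_tot t/2) turns the decay
into a straight line through the origin, and k_conf = √(p_A p_B)·k_tot.
This estimator is exact on noise-free model data at any mixing time.
The literal quadratic fit remains available (`method="linear"`, and a
`nonlinear` variant on R itself) for comparison with analyses that use
the approximation directly; a unit test characterizes its bias.
Timepoints whose ratio denominator is non-positive (a noise artifact
when cross-peaks are large) are dropped and counted, never clipped.
The headline uncertainty is the cross-residue SD over the six-residue
panel (L2, I13, Y45, T55, L67, H68); per-residue OLS standard errors
are kept as a secondary diagnostic. An unequal-R1 mode (numerical
matrix exponential) exists for robustness studies; with distinct R1
values the ratio is only approximately relaxation-compensated.

## AE-MS differential enrichment

Input: a protein × (group, replicate) intensity matrix — seven groups
in the modeled design (Ub, pUb, ⁿʰpUb, NEDD8, pNEDD8, ⁿʰpNEDD8, bead
control), six replicate columns each (three biological × two
technical, treated as six independent columns, matching the 4-of-6
valid-value filter). Stages, each a separately callable function:

1. **preprocess** — drop decoy ("reverse") and contaminant rows; log2;
   keep proteins observed in ≥ `min_valid` (default 4) replicates of at
   least one group (per-group reading; a per-matrix mode is a one-line
   change via the filter but was not requested by any workflow here).
2. **impute** — missing values drawn per column from
   N(μ_c − 1.2·σ_c, (0.3·σ_c)²), μ_c/σ_c from the observed values of
   that column: the missing-not-at-random assumption that undetected
   proteins sit just below that sample's detection limit. Per-column
   orientation matches the common practice for sample-wise detection
   limits; seeded and reproducible.
3. **anova_s0** — moderated one-way ANOVA across all groups,
   F′ = MS_between / (√MS_within + s0)², s0 = 1 on the log2 scale.
   This is a multi-group generalization of the SAM fudge factor: it
   damps proteins whose absolute between-group spread is small even if
   their within-group variance is tiny. The exact moderated statistic
   used by the original desktop software is not published; s0 = 0
   recovers the plain F, and the permutation machinery is statistic-
   agnostic. The null distribution comes from column→group label
   permutations preserving group sizes — enumerated exhaustively
   whenever the number of distinct assignments is ≤ `n_perm` (making
   toy cases deterministic and oracle-checkable), otherwise `n_perm`
   (default 1000) seeded draws. q-values are SAM-style: expected false
   positives at each observed statistic divided by the number of
   observed statistics at least as large, monotonized by a cumulative
   minimum from the least significant side; significant ⇔ q ≤ FDR
   (default 0.02).
4. **bead_filter** — after averaging replicates per group, significant
   proteins whose control mean strictly exceeds every bait mean are
   removed (resin binders).
5. **cluster_and_zscore** — the group-mean matrix of significant
   proteins is row-z-scored (mean 0, SD 1) and rows/columns are
   clustered agglomeratively with distance 1 − Pearson correlation and
   average linkage; row cluster ids come from cutting the dendrogram
   at a configurable count.
6. **correlation_and_venn** — bait × bait Pearson correlation over the
   significant set, and a two-family partition: a protein's family
   enrichment factor is the maximum over that family's baits of
   (bait mean − control mean); a positive factor for exactly one of
   the Ub/NEDD8 families makes it family-exclusive, positive for both
   makes it shared.

All group means use imputed values, so the bead filter, correlation
and family partition see the same complete matrix as the test
statistic.

## Targeted pS65 quantification

Per technical replicate, peptide areas are divided by the mean area of
the NEDD8-derived peptides that do not span S65 (pull-down-yield
baseline), then the unmodified and phosphorylated areas of the
S65-spanning tryptic peptide (ILGGSVLHLVLALR, residues 61–74) are
rescaled to sum to 100%. The baseline cancels exactly in the
percentage (asserted in tests); it matters only for the reported
baseline-normalized areas. Which peptides form the baseline is
input-driven (`is_s65_site` flag), not recomputed from digestion
rules, so any user-declared target list works. Condition fold changes
are ratios of means over biological replicates — unpaired by default,
since stress and mock treatments are separate transfections — with a
paired per-replicate mode available.

## Synthetic-data generators

Each generator draws from the forward model its analysis stage
assumes, with the true parameter recorded, so noise-free generation is
recovered exactly and noisy generation within quantifiable bands.

* **Scenarios** (packaged as data): pNEDD8 — 45% relaxed,
  k_conf 8.3 s⁻¹; pUb — 56% relaxed, 2 s⁻¹; ⁿʰpUb — 12% retracted
  (the phosphonate's higher pKₐ leaves fewer molecules doubly
  deprotonated at physiological pH, disfavoring the retracted form),
  rate also 2 s⁻¹ since no separate measurement exists for the analog.
  Default height noise: 5% multiplicative log-normal.
* **Peak lists** — reference shifts drawn uniformly over the amide
  region (7.0–9.5 / 105–130 ppm); retracted-state offsets planted
  large (bounded away from the background) on residues 60–72 and the
  two S65 hydrogen-bond partners (K4, Y45), relaxed-state offsets
  small and local to the phosphosite, so CSP profiles reproduce the
  β5-slippage signature by construction. A configurable residue subset
  appears in only one state and three residues are emitted as
  state-ambiguous, mirroring realistic incomplete assignments.
  Heights realize the scenario's population ratio before noise.
* **ZZ fixtures** — `simulate_zz` over the six-residue panel at
  t = 20/40/60/100 ms, per-residue amplitudes and noise streams.
* **AE-MS matrices** — log2 intensities Gaussian around per-protein
  base levels (mean 25, SD 2); planted classes (defaults: 126
  Ub-exclusive, 58 shared, 36 NEDD8-exclusive interactors, 30 bead
  binders, 250 background, plus flagged decoy/contaminant rows)
  receive a +4 log2 enrichment in their preferred groups; additive
  Gaussian replicate noise (SD 0.3 log2); missing-not-at-random
  dropout with logistic probability in the true log2 intensity
  (midpoint 22, scale 1), the same assumption the down-shifted
  imputation encodes.
* **Targeted tables** — five biological replicates per condition in
  technical duplicates (first two) or triplicates, pS65 fraction 2%
  mock vs 3% stress (a 1.5-fold elevation at a realistic low
  phospho-stoichiometry; the generators' fold, not the absolute
  stoichiometry, is the tested quantity), multiplicative log-normal
  area noise.

Noise conventions: multiplicative log-normal (unit mean) for peak
heights and peptide areas — positive quantities whose error scales
with signal — and additive Gaussian in log2 space for protein
intensities.

**What the generators do not emulate:** spectral overlap and peak
collisions, field- or temperature-dependent shift changes, correlated
(structured) noise between replicates, ionization-efficiency
differences between peptides, protein-level intensity distributions
with heavy tails, or partial dephosphorylation of baits during
enrichment. Passing closed-loop tests therefore demonstrates
correctness of the estimators under their stated models, not
robustness to every artifact of real spectra or LC-MS runs.

## Numerical choices and degenerate inputs

* Thresholds use strict inequalities; a flat CSP profile classifies
  every residue as below-mean.
* Exhaustive permutation enumeration switches on automatically when
  the multinomial assignment count is ≤ `n_perm`.
* Proteins with zero variance everywhere get statistic 0 (the s0 term
  keeps the denominator finite).
* Constant rows cannot be z-scored; the staged function raises, while
  the end-to-end pipeline skips clustering and records the fact (this
  arises only for noise-free synthetic matrices).
* Residue panels are validated against the hard-coded mature
  sequences at import; a panel/sequence mismatch is a packaging error
  and fails loudly.
* Problem sizes in the test suite (500-protein matrices, 200-draw
  permutation nulls, 200-repeat Monte-Carlo loops) were chosen as the
  smallest sizes at which the Monte-Carlo error is comfortably below
  the tested tolerances.

## Known limitations

* The ZZ model assumes a shared R1; strongly different longitudinal
  rates between conformers bias the ratio (an unequal-R1 simulation
  mode exists to quantify this, but the fit does not model it).
* The S0-moderated statistic is this package's concrete
  interpretation of a commercial tool's unpublished test; q-values
  are oracle-tested against brute-force permutation but are not
  guaranteed to match that tool's output numerically.
* The family (Venn) partition keys on positive enrichment factors;
  under replicate noise the max-over-baits factor is generous toward
  "shared" labels. Exact planted-composition recovery is therefore a
  noise-free property.
* Peak heights are treated as arbitrary units throughout; no attempt
  is made to model absolute intensity calibration of deposited
  spectra.
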