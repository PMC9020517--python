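# phosphoubl

Quantitative analysis of S65-phosphorylated ubiquitin (pUb) and NEDD8
(pNEDD8) for structural biologists and proteomics researchers studying
the "modified modifier": phosphorylation of Ub/Ubl proteins themselves.

Both pUb and pNEDD8 exist in a slow conformational equilibrium between
a near-native **relaxed** state (m) and a **retracted** state (n) in
which the C-terminal β5-strand slips toward the protein core. This
package implements, as a tested reusable library plus CLI, the
quantitative analyses that characterize this equilibrium and its
functional consequences:

* **CSP mapping** — weighted chemical shift perturbations between
  ¹H–¹⁵N correlation spectra,
  Δω = √[ ((Δ¹H)² + (Δ¹⁵N)²/25) / 2 ] (ppm), with mean / mean+SD
  threshold classification and optimal-assignment transfer between
  near-identical spectra.
* **State populations** — the retracted fraction from relative peak
  heights, f_n = I_n / (I_m + I_n), averaged over packaged 17-residue
  panels of well-separated cross-peak pairs for pNEDD8, pUb, and the
  non-hydrolyzable phosphonate analog ⁿʰpUb.
* **ZZ-exchange kinetics** — two-site longitudinal-exchange simulation
  and fitting of the interconversion rate k_conf from the
  relaxation-compensated ratio
  R(t) = I_AB·I_BA / (I_AA·I_BB − I_AB·I_BA) ≈ k_conf² t²
  over mixing times 20/40/60/100 ms (plus an exact closed-form
  inversion that removes the small-t approximation bias).
* **AE-MS enrichment statistics** — the staged Perseus-style workflow
  for bait/control protein intensity matrices: decoy/contaminant
  filter → log2 → 4-of-6 valid filter → down-shifted normal imputation
  (width 0.3, shift 1.2) → S0-moderated permutation ANOVA (FDR 0.02,
  S0 1) → bead-control filter → row z-score → correlation clustering →
  bait correlation and Ub/NEDD8 family (Venn) partition.
* **Targeted pS65 quantification** — baseline-corrected, 100%-normalized
  relative intensity of the pS65-containing NEDD8 tryptic peptide and
  stress/mock condition fold changes.

Every stage has a ground-truth synthetic-data generator
(`phosphoubl.simulate`), so the full pipeline is testable without
spectrometer or mass-spectrometer data.

## Worked example

Simulate the pNEDD8 scenario (45% relaxed state, k_conf = 8.3 s⁻¹,
5% multiplicative height noise) and re-measure both quantities:

```sh
phosphoubl simulate --scenario pnedd8 --outdir demo --seed 0
phosphoubl populations --pairs demo/conformer_pairs.tsv \
    --residue-set pnedd8 --out demo/populations.tsv
phosphoubl zzfit --series demo/zz_series.tsv --out demo/zzfit.json
```

The populations report (`demo/populations.report.json`) contains

```json
"headline": {
  "mean_fn": 0.5516,
  "mean_relaxed": 0.4484,
  "n_residues": 17,
  "sd_fn": 0.0206,
  "sem_fn": 0.0050
}
```

i.e. a mean relaxed-state population of 44.8% over the 17-residue
panel — the generator's true 45% recovered to within the noise — and
the ZZ fit report gives

```
k_conf_mean 8.28  k_conf_sd 0.29
```

recovering the true interconversion rate of 8.3 s⁻¹ with a
cross-residue spread set by the 5% height noise.

The same library calls are available in Python:

```python
from phosphoubl import SCENARIOS, make_two_state_peaklists, population_summary
from phosphoubl.populations import RESIDUE_SETS

_, _, pairs = make_two_state_peaklists(SCENARIOS["pnedd8"], seed=0)
est = population_summary(pairs, RESIDUE_SETS["pnedd8"])
print(f"relaxed state: {100 * est.mean_relaxed:.1f} +/- {100 * est.sd_fn:.1f} %")
```

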