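# Methods

## The selection model

The package models a two-step substrate-mediated selection of a
DNA-encoded library: (1) kinase treatment phosphorylates members that can
serve as substrates; (2) an anti-phosphotyrosine antibody pull-down
captures phosphorylated members, which are then PCR-amplified and
sequenced. Member identity is carried by a DNA barcode ("gene") with one
20-base codon per combinatorial cycle. The library is doubly redundant:
every cycle-1–3 building block has two codons, one per lineage (A/B), and
cycle-4 caps are singly encoded, so each molecule maps to exactly two
genes. The redundancy acts as an internal replicate: when sampling is
adequate the two encodings rank the same molecules highly; when the
selection is undersampled they disagree.

The generative chain, per gene *i*:

1. **Abundance.** log₁₀ relative abundance ~ Normal(0, σ₁₀) truncated at
   ±τ (renormalised to frequencies). Defaults σ₁₀ = 0.5/1.96 ≈ 0.2551 and
   τ = 1.0 are calibrated so the central 95% interval spans one log₁₀ unit
   (the "95% within a 10-fold window" regime) and the max/min disparity
   is bounded at 100-fold. These are the translation-QC statistics the
   analysis side checks with `abundance_qc`.
2. **Activity.** Each phenol-capped molecule is a substrate with
   probability π (default 0.02); active members draw a relative
   specificity *x* (k<sub>cat</sub>/K<sub>m</sub> normalised to the
   LYNtide reference peptide = 1) from a log-normal with median 10⁻² and
   log₁₀-spread 0.5 — typical hits sit one to three orders of magnitude
   below an optimised peptide substrate. Non-phenol members are inactive
   by default (the phenol is the phospho-acceptor).
3. **Phosphorylation.** p_phos = 1 − exp(−x·dose), first-order in
   exposure. "Full phosphorylation" of the reference substrate is defined
   as 99% completion, so the unit exposure is ln(100); the library
   selection used ~10× that, hence the default dose 10·ln(100) ≈ 46.05.
   Under this calibration a member showing ~1% conversion at library dose
   has x ≈ 2.2×10⁻⁴.
4. **Capture.** p_cap = p_ab·p_phos + β·(1 − p_phos). Defaults
   p_ab = 0.09 (the dope-in recovery) and β = 0.09/2600 ≈ 3.46×10⁻⁵
   (back-solved as recovery/enrichment from the dope-in calibration).
   Antibody affinity is uniform across phospho-members (saturating
   antibody); PCR is unbiased, absorbed into the sequencing multinomial.
5. **Sampling.** captured_i ~ Binomial(pre_i, p_cap_i), then reads ~
   Multinomial(depth, captured/Σ) — sequencing depth is a free parameter
   (the experiment's depth is not known), so all depth-dependent results
   are reported as simulation properties, not as reproduced magnitudes.

Dope-ins are tracked members with their own activity channel; qPCR is a
linear standard curve Ct = intercept + slope·log₁₀(copies) with
slope = −log₂10 at 100% efficiency; read emission is substitution-only
with constant placeholder qualities.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: abundance
spread, two-lineage redundancy, activity-dependent capture against a
uniform background, finite-depth sampling, dope-in spiking, and
substitution sequencing errors. It does **not** model PCR bias or
chimeras, indels, antibody affinity variation between phospho-members,
bead capacity, or carrier effects — so passing tests demonstrate the
correctness and calibration of the analysis chain under the stated
mechanism, not robustness of the wet-lab protocol to those nuisances.

## Analysis definitions

- **Fold enrichment.** E_i = [(c_sel,i+α)/(T_sel+αG)] /
  [(c_ref,i+α)/(T_ref+αG)] with pseudocount α = 1 by default (α = 0
  reduces exactly to the frequency-ratio definition and is used in
  oracle tests). G is the design's gene count plus any tracked extras.
  The reference is the sequenced unselected pool; `marginal_ref` mode
  instead estimates reference abundances as T·∏ per-cycle codon marginal
  frequencies, which assigns expected counts to genes unobserved in the
  reference.
- **Ranking tie-break** is (E desc, selected count desc, gene id asc) —
  documented, stable, order-invariant.
- **Molecule merge.** Default geometric mean of the two lineage
  enrichments: symmetric, and it penalises single-lineage spikes, which
  is precisely the use of redundancy as a noise filter. `max` and
  `sum_counts` are available.
- **Concordance.** Per-lineage top-k overlap plus a Spearman rank
  correlation computed by the explicit average-rank Pearson formula.
  Only molecules with selected-read evidence in a lineage are eligible
  for that lineage's top-k; a deterministic tie-break among no-evidence
  members would otherwise fabricate overlap. Expected chance overlap for
  independent rankings is k²/N, which is why the non-concordance
  property is evaluated at full library scale (N = 415,292, where
  k²/N ≈ 0.1) rather than on a scaled-down library.
- **10-fold window QC** is log-centred on the median abundance (the
  window's anchor is otherwise arbitrary).
- **Families** are maximal groups identical at three positions and
  varying at one cycle (min size 3); varying a cycle-1–3 position keeps
  the cap fixed, matching the "lines" reading of synthon-space plots.
  The hit filter is E_combined ≥ 10, boundary inclusive, optionally
  intersected with family membership.
- **Decoding.** Nearest codon per variable segment across both lineages,
  default mismatch budget 2 with a unique-best requirement; with
  d_min = 8 any budget < d_min/2 guarantees the true codon is the unique
  nearest for in-budget errors. Lineage consistency across cycles 1–3 is
  enforced (the pools were physically separate); conflicts are counted,
  not salvaged. The budget/d_min bound is enforced when decoding against
  a design, while `match_codon` itself accepts any budget so tie
  behaviour can be probed directly.

## Fitting contracts

All fitters are deterministic: a coarse log-grid over the nonlinear
parameter (K_m, K_d, or IC50×Hill) with closed-form linear parameters at
each grid point, then bounded `scipy.optimize.least_squares` refinement
at xtol = ftol = gtol = 10⁻¹⁴. No randomised restarts. Non-convergence
(e.g. flat dose-response data) is a flagged result. Standard errors come
from the Jacobian-based asymptotic covariance. The Hill coefficient is
fitted within [0.3, 5] rather than fixed at 1; the FP isotherm is the
tracer-dilute hyperbola; NADH conversions use ε = 6220 M⁻¹cm⁻¹ at 340 nm
and 1 cm path length by default. ADP-detection luminescence is treated
as proportional to ADP with the scale absorbed into V_max unless an
enzyme concentration is supplied for k_cat calibration.

Noiseless synthetic data is recovered to < 10⁻⁶ relative error for every
characterised constant; at 5% noise the K_m estimator shows < 5% mean
bias with ~90% coverage of 2×SE intervals over 50 seeded replicates, and
every fit matches a dense brute-force grid oracle.

## Scenario orchestration and problem sizes

A single config seed fans out to per-stage sub-seeds (first words of
`numpy.random.SeedSequence(seed).generate_state`, masked to 31 bits), so
stages are independently re-runnable and a manifest reproduces all
stochastic outputs bit-for-bit.

The packaged scenarios are scaled for desk use: `paper_like` runs a
10×10×10×4 library (8,000 genes) at count level with a 300,000-copy
dope-in, and `caii_validation` a 12×12×12×4 library with a planted
cycle-3 pharmacophore captured at 0.05 vs 10⁻⁵ background. Full-scale
(47×47×47×4, 415,292 molecules) count-level simulations are used where
scale matters: the validation-selection top-400 purity check and the
undersampling non-concordance property. Read-level (FASTQ) simulation is
exercised on small designs; count-level mode produces identical
downstream statistics without materialising reads.

## Known limitations

- The printed full library complexity (5.5×10⁵) is not exactly the
  product 47³×4 = 415,292 and the per-cycle monomer split is not public;
  library size is therefore config-driven, never hard-coded.
- The actual experimental codon sequences are not public; codons are
  generated greedily at pairwise Hamming ≥ 8 from a seed, and explicit
  tables can be supplied instead.
- Wet-lab enrichment magnitudes depend on unprinted parameters
  (sequencing depth, antibody bead capacity); the package reproduces
  them qualitatively (strong dope-in enrichment, background-limited
  non-concordance) rather than numerically.
- Indel errors, quality-aware matching, UMI handling, tight-binding IC50
  corrections, and bisubstrate kinetic mechanisms are out of scope.
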