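# delsub

Simulation and analysis of **substrate-mediated selections of DNA-encoded
chemical libraries (DELs)**, modelled on a tyrosine-kinase (c-Src)
substrate selection of a peptidomimetic DEL.

In a substrate-mediated selection, DNA-linked library members are treated
with a kinase and ATP; phosphorylated members are captured with a broad
specificity anti-phosphotyrosine antibody and identified by sequencing
their DNA barcodes. The approach enriches for *enzymatic turnover* rather
than mere binding, but its readout is shaped by encoding redundancy,
nonspecific capture background, and sequencing undersampling. This package
implements the full computational chain around such an experiment, for
chemists and computational biologists who want to design, simulate, decode
and analyse these selections:

- **`delsub.design`** — the genetic contract of a doubly redundant DEL:
  building blocks per cycle, two orthogonal codon tables (lineages A/B,
  pairwise Hamming ≥ 8) for cycles 1–3 and a shared cycle-4 table, the
  180-mer read layout (five common + four variable 20-mers), molecule and
  gene enumeration, and mole↔copy conversions.
- **`delsub.simulate`** — a forward generative model of the selection:
  truncated log-normal gene abundances (calibrated so ~95% of genes fall
  in a 10-fold window with ≤100-fold max disparity), latent per-molecule
  relative specificity *x* (k<sub>cat</sub>/K<sub>m</sub> normalised to a
  reference peptide), phosphorylation probability 1 − e<sup>−x·dose</sup>,
  antibody capture p<sub>cap</sub> = p<sub>ab</sub>·p<sub>phos</sub> +
  β·(1 − p<sub>phos</sub>), binomial capture, multinomial sequencing,
  dope-in spiking, FASTQ emission with substitution errors, qPCR Ct
  curves, and synthetic assay tables.
- **`delsub.decode`** — FASTQ → gene count tables by nearest-codon
  matching under a mismatch budget, with typed rejections and the
  conservation guarantee assigned + rejected = total.
- **`delsub.enrich`** — pseudocounted fold enrichment
  E = [(c_sel + α)/(T_sel + αG)] / [(c_ref + α)/(T_ref + αG)], codon-
  marginal abundance estimation, abundance QC, geometric-mean merge of the
  two redundant encodings, top-k concordance (undersampling diagnostic),
  synthon composition and cube coordinates, structural family ("line")
  detection, the ≥10-fold hit filter, and dope-in calibration metrics.
- **`delsub.kinetics`** — deterministic grid-initialised least-squares
  fits: Michaelis–Menten (v = V<sub>max</sub>S/(K<sub>m</sub>+S)),
  four-parameter logistic IC50, hyperbolic fluorescence-polarization
  binding, NADH-coupled rate/equivalents via Beer–Lambert
  (ε = 6220 M⁻¹cm⁻¹), specificity-constant comparisons, and ΔΔCt qPCR
  quantification.
- **`delsub.pipeline` / `delsub` CLI** — end-to-end scenarios
  (simulate → decode → enrich) with deterministic seed fan-out and a run
  manifest; packaged `paper_like` and `caii_validation` scenarios.

## Worked example

```bash
python examples/05_assay_fits.py
```

```
reference peptide : K_m = 18.0 µM, k_cat = 2.0/s
DEL hit           : K_m = 13.0 µM, k_cat = 1.5/s
specificity ratio : 1.04 (within 10-fold: True)
FP binding        : K_d = 7.5 µM
inhibition        : IC50 = 8.1 µM
NADH equivalents  : 1.0 ADP per compound (~1 = single-turnover phosphotransfer; >>1 = ATPase activation)
qPCR enrichment   : 2,600-fold from a ddCt of log2(2600)
```

Noiseless synthetic assay data generated at each ground-truth constant is
refit exactly: the Michaelis constants and turnover numbers of the
reference peptide and a DEL-derived substrate, the lead compound's
binding constant by fluorescence polarization, and its inhibitory IC50.
The specificity ratio compares k<sub>cat</sub>/K<sub>m</sub> between two
substrates; NADH equivalents near 1 indicate genuine phosphotransfer
while large excesses flag ATPase activation; the qPCR line converts a
ΔΔCt into fold enrichment.

The selection simulation itself (`examples/02_selection_simulation.py`)
spikes a reference-peptide dope-in into a scaled library and recovers the
capture calibration it was simulated with — 9% recovery, and
recovery/enrichment back-solving the nonspecific background:

```
dope-in pre fraction : 2.17e-03
dope-in enrichment   : 229-fold
dope-in recovery     : 9.0%
implied background   : 3.94e-04
```

Other examples cover library design and copy-number arithmetic (`01`),
read decoding with rejection accounting (`03`), and the full enrichment /
concordance / family / hit analysis (`04`).

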