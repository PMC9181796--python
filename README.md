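# splitrootseq

Split-root RNA-seq analysis: classifying **local** versus **systemic**
nutrient-resupply responses from bulk count data.

## The problem

In a split-root experiment a plant's root system is divided between two
compartments. Starve the whole plant of a nutrient (here: sulfate in rice),
then resupply only one compartment, and the two root halves disentangle two
signalling routes: genes that recover only in the half that actually
receives sulfate respond to a **locally** perceived signal, while genes
that recover only in the half left deficient must be driven by a
**systemic**, shoot-relayed signal. The experimental design has nine sample
groups — shoots: control `CK_Sh`, deficient `S0_Sh`, homogeneous resupply
`SR_Sh`, heterogeneous resupply `SP_Sh`; roots: `CK_R`, `S0_R`, whole-root
resupply `SR_R`, and the two split halves `SPSR_R` (resupplied) and
`SPS0_R` (still deprived) — with replicated RNA-seq in each.

`splitrootseq` implements the full downstream analysis as a tested Python
library:

- **Simulator** — negative-binomial counts, NB(μ, μ + φμ²), for the
  nine-group design with planted, labelled response classes, so every stage
  can be verified against ground truth.
- **Quantification & QC** — FPKM
  (`count / (length_kb × library_millions)`) and within-group replicate
  correlation on log₁₀(FPKM + 1).
- **Differential expression** — a fully specified two-group NB Wald test:
  median-of-ratios size factors, method-of-moments common dispersion,
  `log2fc = log2((μ̂_A + ½)/(μ̂_B + ½))`, model-based SE, BH FDR. DEG
  thresholds: |fold change| ≥ 2, p < 0.05, FDR < 0.01.
- **Response classifier** — set algebra over DEG sets. With
  R = (S0_R/CK_R up) ∩ (SR_R/S0_R down) the recovered deficiency-induced
  genes, the root classes are
  - A local = R ∩ SPSR↓ − SPS0↓
  - B systemic = R ∩ SPS0↓ − SPSR↓
  - C both = R ∩ SPSR↓ ∩ SPS0↓
  - D none = R − SPSR↓ − SPS0↓

  (E–H mirror the deficiency-suppressed branch; shoots split into
  hetero-responsive vs homogeneous-only using SR_Sh and SP_Sh.)
- **Enrichment** — one-sided hypergeometric over-representation of GMT
  terms with BH FDR ≤ 0.05 per category, top-N selection and the
  (up − down)/total direction score.
- **Pipeline** — one TOML config (or `PipelineConfig`) drives
  simulate/load → QC → DE → classify → enrich → report; also exposed as a
  thin `splitrootseq` CLI (`simulate`, `qc`, `de`, `enrich`, `validate`,
  `run`).

## Worked example

```python
from splitrootseq import (ContrastSpec, SimulationDesign, call_degs,
                          classify_root, run_contrast, set_sizes, simulate_counts)
from splitrootseq.classify import ContrastSets

design = SimulationDesign(n_genes=6000, effect_log2fc=3.0, dispersion=0.1,
                          base_mean_log_range=(2.0, 3.5), seed=11, shoot_fraction=0.0)
cm, truth = simulate_counts(design)

names = ("S0_R/CK_R", "SR_R/S0_R", "SPSR_R/S0_R", "SPS0_R/S0_R")
sets = {}
for name in names:
    spec = ContrastSpec.parse(name)
    sets[name] = ContrastSets.from_degsets(*call_degs(run_contrast(cm, spec), spec))
print(set_sizes(classify_root(*(sets[n] for n in names))))
```

prints

```
{'root.down.unrecovered': 122, 'root.down.E': 60, 'root.down.F': 30,
 'root.down.G': 60, 'root.down.H': 90, 'root.up.unrecovered': 124,
 'root.up.A': 60, 'root.up.B': 30, 'root.up.C': 60, 'root.up.D': 90}
```

— the design planted exactly 60/30/60/90 up-regulated local/systemic/both/
none genes in roots (1% / 0.5% / 1% / 1.5% of 6,000, times the root-tissue
share), and the pipeline recovers every set; 99.2% of labels agree with the
planted truth (`examples/04_classify_responses.py`). The
`examples/` directory has one short narrative script per capability.

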