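# pdsgscreen

A tested, reusable implementation of a five-stage screen for **prognostic
dosage-sensitive genes (PDSGs)** from paired gene-level somatic copy-number
alteration (SCNA), expression and survival data, together with the
downstream SCNA co-alteration and differential co-expression analyses and a
synthetic cohort generator that makes the whole pipeline testable without
any data download.

## The scientific problem

Somatic copy-number alterations are pervasive in tumors, but most altered
genes are passengers. A gene is *dosage-sensitive* when its expression
tracks its DNA copy number (the gene dosage effect), and dosage-sensitive
genes whose alteration also predicts patient survival are strong driver and
biomarker candidates. The screen takes three aligned inputs — a continuous
GISTIC2-style SCNA matrix, an FPKM expression matrix, and overall-survival
times with event indicators — and filters genes through five stages. For a
gene and threshold *x* > 0, samples split into copy-number amplified
(CNAS, SCNA ≥ *x*), deleted (CNDS, SCNA ≤ −*x*) and non-altered
(CNNS, |SCNA| < *x*) classes; classes below 10 samples are not evaluable.

1. **Differential expression** — Wilcoxon rank-sum of expression in CNAS
   (resp. CNDS) vs CNNS at *x* = 0.3; keep genes with *p* < 0.01,
   Benjamini–Hochberg FDR < 0.1 and fold change FC > 1.2
   (deleted side: FC < 1/1.2).
2. **Concordance** — the direction of the expression change must match the
   copy-number change (up with amplification, down with deletion).
3. **Cox screen** — univariate Cox proportional hazards with the continuous
   SCNA value as covariate; keep genes with Wald *p* < 0.05.
4. **Stability sweep** — raise *x* from 0.1 to 0.5 in steps of 0.02
   (21 thresholds); at each threshold run a log-rank test of the altered
   class vs CNNS; a gene is a *stable* prognosis-sensitive gene when
   *p* < 0.05 at strictly more than half the grid (>10 of 21 thresholds).
5. **Dosage-effect score** — the Pearson correlation *r* between SCNA and
   FPKM across all samples (equal to the simple-regression R); stable genes
   with *r* ≥ 0.3 and *p* < 0.05 are the PDSGs.

Downstream, the package computes the pairwise SCNA correlation matrix of
the PDSGs (co-alteration: genes on one amplified segment correlate near 1)
and a **differential co-expression network**: a PDSG–partner pair is an
edge when |*r*| > 0.5 in one of the PDSG's sample classes and |*r*| < 0.1
in the other, exported as SIF/GraphML for Cytoscape.

## Worked example

`examples/06_full_screen.py` simulates the default synthetic cohort (400
samples, 1000 genes, one 6-gene co-amplified block carried by ~1/12 of
samples, expression coupled to copy number, hazard ratio 2 at SCNA = 1)
and runs the full screen:

```
stage survivors:
  evaluable genes          6
  DE + concordance (1-2)   6
  Cox p < 0.05 (3)         6
  stability sweep (4)      6
  dosage score (5) = PDSG  6
PDSGs: G0000, G0001, G0002, G0003, G0004, G0005
  G0000: dosage-effect score r = 0.608 (p = 7.3e-42)
  G0001: dosage-effect score r = 0.572 (p = 3.8e-36)
  ...
```

Only the six planted block genes have ≥10 altered samples (evaluable), and
all six pass every stage: they are differentially expressed where
amplified, prognostic under Cox, stable across the threshold grid, and
their dosage-effect scores sit near the design target of 0.6. The other
examples exercise each capability separately (simulation and co-alteration,
the DE stage, Cox + stability sweep, score concordance between two cohorts,
and the differential co-expression network).

A thin CLI wraps the same library calls:

```bash
pdsgscreen simulate --seed 0 --out sim/
pdsgscreen run-all --scna sim/scna.tsv --expr sim/expr.tsv \
    --clinical sim/clinical.tsv --out run/
```

writing `de.tsv`, `cox.tsv`, `stability.tsv`, `dosage.tsv`, `pdsg.txt`,
`edges.tsv`, `network.sif`, `network.graphml`, `coalteration.tsv` and a
`manifest.json` with config, input digests and stage survivor counts.
Identical inputs and seed give a byte-identical run directory.

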