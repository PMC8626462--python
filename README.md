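# bafmap

Analysis pipeline for mapping mammalian SWI/SNF (mSWI/SNF) subcomplex
genomic occupancy and its consequences in fusion-positive rhabdomyosarcoma
(FP-RMS) — for computational biologists working with ChIP-seq peak sets,
spike-in (ChIP-Rx) count tables, pooled CRISPR screen counts, qPCR Ct
tables and proximity-proteomics intensity matrices.

FP-RMS is driven by the PAX3-FOXO1 fusion transcription factor, which
maintains a proliferative, differentiation-blocked state together with the
core regulatory transcription factors (CRTFs) MYOD1, MYOG and MYCN.  The
mSWI/SNF chromatin remodeling family occurs as three subcomplexes sharing
the BRG1 ATPase but distinguished by diagnostic subunits: canonical BAF
(DPF2), PBAF (PBRM1) and ncBAF (BRD9).  This package implements the
quantitative procedures needed to dissect their roles:

* **Subcomplex deconvolution.** Each BRG1 peak is assigned the Boolean
  triple (DPF2, PBRM1, BRD9 overlap), which maps onto one of eight
  combination classes (BAF_only, PBAF_only, …, BAF+PBAF+ncBAF,
  BRG1_unassigned).  Per class, CRTF co-occupancy fractions and
  chromatin-state enrichments
  `log2[(peak fraction in state) / (genomic fraction of state)]`
  are computed.
* **Spike-in quantification.** Per-peak counts are normalized as RRPM
  (`raw × 10⁶ / Drosophila-mapped reads` — comparable across conditions
  because a fixed amount of exogenous chromatin enters every reaction) or
  RPMPR (`raw × 10⁶ / reads in the union peak set`).  "Enhancer invasion"
  after BRG1 loss is quantified per co-occupied site as
  `Δ = log2(RRPM_treated + c) − log2(RRPM_control + c)` with a paired
  signed-rank summary.
* **Screen scoring.** sgRNA counts → reads per million → per-guide
  `log2((late + c)/(early + c))` → per-domain aggregates → specificity =
  mean over RMS lines − mean over non-RMS lines, ranked ascending.
* **Molecular quantification.** ChIP-qPCR
  `%recovery = 2^(Ct_input − log2 X − Ct_sample) × 100`, exogenous-locus
  Ct correction, `2^(−ΔΔCt)` fold changes, RT-qPCR relative expression
  with the SD > 0.5 technical-replicate outlier rule, and day-2-baseline
  competition trajectories.
* **Proximity proteomics.** Peptide/missingness filtering, modified
  robust z-score normalization, moderated (empirical-Bayes shrunken)
  two-sample statistics, pseudo fold changes for all-missing conditions,
  and volcano hit calling at log2FC > 2.5, p < 0.05.
* **Synthetic data.** Seeded generators plant known classes, co-binding
  rates, condition effects, depletion effects, abundances and enrichment
  so that every stage is exercised — and its truth recovery measured —
  without any downloads.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
data (any single root seed):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_subcomplex_occupancy.py --seed 1
python analysis/03_enhancer_invasion.py --seed 1
```

`02_subcomplex_occupancy.py` prints, among other tables:

```
CRTF co-occupancy fraction per class:
                   P3F  MYOD1   MYCN  any_CRTF
BAF_only         0.622  0.479  0.438     0.890
PBAF_only        0.054  0.047  0.047     0.138
...
BAF-only sites carry a CRTF 89% of the time vs 14% at PBAF-only sites
```

i.e. the classifier recovers the planted biology: the core circuitry
concentrates at canonical-BAF-only (enhancer-like) sites and avoids
PBAF-containing (promoter-like) sites.  `03_enhancer_invasion.py` prints:

```
MYCN occupancy at 394 co-occupied sites: median log2 change 1.027,
100% of sites increased (signed-rank p = 2.61e-66)
BRG1 track median log2 change: -3.34 (depletion control)
```

matching the planted +1.0 log2 MYCN gain (and ~90% BRG1 loss) at
co-occupied sites.  The same stages are available as a CLI
(`bafmap run-all --seed 1 -o results/run`) or as library calls
(`bafmap.subcomplexes.classify_subcomplexes`, `bafmap.chiprx.invasion_analysis`, …).

## Layout

```
analysis/          numbered narrative drivers (simulate → ... → bioid)
src/bafmap/        library: intervals, subcomplexes, chiprx, screen,
                   qpcr, proteomics, simulate, pipeline, cli, validation
tests/             pytest suite (unit + property + end-to-end checks)
scripts/           acceptance.py
docs/methods.md    models, parameters, numerical choices, limitations
```
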