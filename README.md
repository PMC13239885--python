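# nichesig

Tumour immunology increasingly ties patient outcome to *which* immune
cell states infiltrate a tumour and *where* they sit.  `nichesig`
implements, as a tested and reusable Python pipeline, the analysis
chain behind such studies — the motivating case being CD4+CD8+
double-positive T (DPT) cells in hepatocellular carcinoma:

1. **Signature derivation** — cell QC (UMI < 10 000, 500–6000 detected
   genes, mito < 5%), depth-normalisation, and dual-criterion marker
   signatures: a gene enters a subcluster's signature only if it is
   up-regulated (BH-adjusted p < .05, log2FC > .5) both against the
   other subclusters of its major cell type *and* against all remaining
   cells.
2. **Single-sample enrichment** — ssGSEA: per sample, rank genes by
   descending expression and sum the running difference between the
   rank-weighted in-set ECDF and the uniform out-of-set ECDF
   (weights rank^α, α = 0.25).
3. **Survival association** — Kaplan–Meier and log-rank, maximally
   selected cutpoints (the threshold maximising the standardised
   log-rank statistic over all admissible splits), and Cox
   proportional-hazards fits (Efron ties, Newton iterations) on scaled
   continuous scores, adjusted for sex, age, treatment and HBV status;
   responder vs non-responder score comparison by rank-sum.
4. **Tissue preference** — Ro/e (observed/expected cell counts from the
   chi-square decomposition of the subsets × tissues table) and 2×2
   odds enrichment between short- and long-term survivor groups.
5. **Spatial niches** — on binned spatial transcriptomics: spot-level
   signature sums, top-2.5% high-enrichment seeds, 3×3-window (Chebyshev
   distance 1) dilation into niches, and a rank-sum co-localisation test
   of a target signature inside vs outside a context niche, restricted
   to spots with positive target score.

Because the cohorts such studies use are controlled-access, the package
ships synthetic generators (`nichesig.synthetic`) that plant the exact
structure the analyses assume — NB single-cell counts with marker
blocks and composition shifts, bulk cohorts whose signature score
drives an exponential-baseline proportional hazard, and spatial
lattices with disc-shaped niches of tunable co-localisation — so every
stage is testable end to end without any download.  See
`docs/methods.md` for the statistical details and design choices.

## Worked example

The numbered drivers under `analysis/` run the bundled demo study (a
prognostic DPT-like subcluster planted at hazard ratio 2 per SD):

```sh
cd analysis
python 01_simulate_cohorts.py    # writes results/run/data/
python 02_derive_signatures.py
python 03_bulk_prognosis.py
python 04_tissue_preference.py
python 05_spatial_niche.py
```

`02` recovers the planted markers as the DPT signature:

```
signature DPT: 29 genes (top 5: ['MK0016', 'MK0023', 'MK0022', 'MK0020', 'MK0013'])
DPT signature: 29 of its 29 genes are planted markers (100% planted)
```

`03` scores the 200-sample bulk cohort and finds the planted prognosis
and response signal (HR per 1 SD of ssGSEA score; the cutpoint p is
flagged selection-biased because the threshold maximises that very
statistic):

```
optimal cutpoint 0.457 (|standardized log-rank| = 5.91, high n=31, low n=169,
                        split p = 3.47e-09, selection-biased)
  univariate    DPT        HR 1.69 [1.38, 2.08]  p=5.26e-07
  multivariable DPT        HR 1.69 [1.37, 2.08]  p=7.47e-07
response: median score 0.373 (responders, n=79) vs 0.190 (non-responders, n=121);
          rank-sum p = 6.28e-08 (responder_higher)
```

`04` shows the planted tumour preference of the DPT subset (Ro/e 1.45
in tumour, < 1 elsewhere; odds ratio 3.0 for short- vs long-term
survivors in tumour), and `05` the spatial co-localisation:

```
DPT vs capillaryEC-high niche: 39 seeds -> 157 niche spots (threshold 49.0);
  median 39.0 in-niche vs 14.0 outside; rank-sum p = 1.02e-55 (niche_higher)
```

The same pipeline is scriptable via the `nichesig` CLI
(`simulate`, `signature`, `score`, `survive`, `prefer`, `niche`, `all`,
`validate`), driven by a YAML config with a single seed that fans out
deterministically per stage; every run writes a JSON manifest with
seeds and output checksums.

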