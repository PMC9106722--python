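# pausekit

Analysis toolkit for RNA polymerase II promoter-proximal pausing and its
downstream readouts, built for studies that ask how an oncogenic
transcription factor (e.g. MYC) reshapes another factor's transcriptional
program (e.g. the androgen receptor, AR) without displacing it from
chromatin. It provides, as a tested and reusable library with a CLI:

1. **Traveling-ratio (pausing-index) analysis of Pol II ChIP-seq.** For each
   gene the traveling ratio is

   TR = d_promoter / d_body,

   where d is mean per-base fragment coverage per million mapped fragments
   (per-bp BPM), the promoter window is −30 bp to +300 bp around the TSS in
   transcription direction, and the body is the remaining gene length.
   TR ≫ 1 indicates promoter-proximal pausing. Comparing two conditions,
   genes are ranked by ΔTR = TR₁ − TR₂; after rescaling both axes of the
   ranked curve to the unit square, the points where a line of slope 1 is
   tangent to the curve delimit the **pause-release** genes (upper tail, TR
   drops in condition 2) and **pause** genes (lower tail, TR rises).
   Gene-set TR distributions are compared with two-sample KS or Welch
   *t*-tests.

2. **Single-cell anchor-gene covariance shifts.** For an anchor gene *a*
   (e.g. *Ar*), each gene *g* gets cov(g, a) across cells per condition on
   total-count-normalized expression; genes whose covariance difference
   between conditions exceeds a threshold (default 30) are flagged as
   changing their co-expression with the anchor. Includes scRNA-seq QC
   (≥200 expressed genes, ≤80% mitochondrial UMIs), a per-population
   transgene census, and pseudobulk/bulk concordance.

3. **Signature-score survival stratification.** Per-sample gene-signature
   scores use a non-parametric rank statistic scaled to [0, 1]; each score
   is dichotomized at the cutpoint maximizing the standardized two-group
   log-rank statistic (maximally selected rank statistic); crossing two
   signatures (AR × MYC) yields four quadrant groups (e.g. `AR_low/MYC_high`)
   compared by Kaplan–Meier estimation and log-rank tests.

4. **Synthetic-data generators with planted ground truth** for all three
   tracks, so every stage is testable end to end without external downloads:
   two-condition Pol II coverage with planted pause-fraction shifts,
   two-condition negative-binomial UMI matrices with a planted covariance
   structure, and survival cohorts whose quadrant groups set the hazard.

## Worked example

Simulate a two-condition Pol II experiment with 3000 genes, 30 planted
pause-release genes (pause fraction −0.4 in condition 2) and 60 planted
pause genes (+0.4), then recover the planted classes:

```python
from pausekit import (
    PolIISimConfig, simulate_gene_models, simulate_polii_experiment,
    compute_tr_table, tr_difference_curve, tangent_cutpoints, classify_pause_genes,
)
from pausekit.simulate import gene_id

release = [gene_id(i) for i in range(30)]         # planted pause-release
paused = [gene_id(i) for i in range(1000, 1060)]  # planted pause

cfg = PolIISimConfig(
    n_genes=3000, chrom_length=10_000_000, reads_per_gene_mean=500,
    planted_pause_release=release, planted_pause=paused, seed=1,
)
genes = simulate_gene_models(cfg)
wt, myc, truth = simulate_polii_experiment(genes, cfg)

tr_wt, tr_myc = compute_tr_table(wt, genes), compute_tr_table(myc, genes)
curve = tr_difference_curve(tr_wt, tr_myc)
classes = classify_pause_genes(curve, tangent_cutpoints(curve))

jac = lambda a, b: len(set(a) & set(b)) / len(set(a) | set(b))
print(f"median TR, condition 1: {tr_wt['tr'].median():.2f}")
print(f"pause-release genes called: {classes.n_pause_release} "
      f"(Jaccard vs planted: {jac(classes.pause_release, release):.2f})")
print(f"pause genes called: {classes.n_pause} "
      f"(Jaccard vs planted: {jac(classes.pause, paused):.2f})")
```

Output:

```
median TR, condition 1: 6.05
pause-release genes called: 36 (Jaccard vs planted: 0.83)
pause genes called: 64 (Jaccard vs planted: 0.94)
```

The median TR of ~6 reflects the simulated baseline promoter allocation; the
tangent cutpoints recover the planted tails almost exactly, with the handful
of extra calls coming from null genes adjacent to the curve's knees.

The same analyses run from the shell: `pausekit simulate {polii|sc|cohort}`,
`pausekit tr`, `pausekit sc`, `pausekit stratify`, and `pausekit demo --out
DIR --seed N` for an end-to-end run on synthetic inputs (every output file is
hashed into `manifest.json`; identical config + seed gives identical
manifests).

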