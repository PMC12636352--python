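# Methods

## The problem

Cis-regulatory elements (CREs) — short transcription-factor binding words in
promoters — are hard to map within a species when promoter alleles differ by
structural variants (SVs): reference-based variant calling cannot even place
the sequence that carries the binding site. `kprob` sidesteps alignment
entirely. Promoter alleles of a *pangene* (the set of gene models sharing one
pan-genome locus across accessions) are decomposed into k-mers; similar
k-mers are clustered; and the cluster counts of every promoter are regressed
jointly against expression with a spike-and-slab Bayesian variable selection
model. A cluster whose occurrence count moves expression consistently across
thousands of promoters is a candidate CRE, wherever it sits — including
inside an insertion private to a few accessions.

## Pipeline and model

1. **Variation metrics.** Promoter similarity of a pangene is the mean count
   of distinct 31-mers shared between its promoter pairs (0..1970 for 2 kb
   windows; log2 up to 10.94). Expression variability is log10(CV²) of
   log2(TPM+1) across gene copies; because CV² falls with mean expression,
   the expected log10(CV²) given mean expression (a centered running median,
   full window max(101, 1% of pangenes)) is subtracted. Highly variable (hv)
   pangenes sit in the extreme `top_fraction` quantiles of both metrics after
   removing pangenes with <6 gene copies or mean log2(TPM+1) < 1.
2. **K-mer space.** Stride-1 forward-strand enumeration (windows with N
   dropped), ordering by descending pan-genome count with lexicographic
   tie-break, then greedy clustering: scanning in that order, a k-mer joins
   the earliest cluster whose *representative* is within Hamming distance 1,
   else founds a cluster. For equal-length words at an identity threshold of
   1−1/k only a single substitution (no gaps) is admissible, so this
   deterministic scheme realises the one-mismatch clustering rule; gap
   penalties are moot. Clusters present in >1% of promoters (strict) enter
   the count matrix X.
3. **Spike-and-slab regression.** y = Cα + Xβ + ε with
   β_j ~ (1−γ_j)N(0,δ0²) + γ_j N(0,δ1²), γ_j ~ Bern(π), π ~ Beta(a_π,b_π),
   δ1⁻² ~ Γ(a1,b1), δe⁻² ~ Γ(ae,be), and δ0² fixed at q·Var(y)/Σ_j Var(X_j)
   with q = 0.05 (the variance share attributed to background effects). The
   Gibbs sampler updates (γ_j, β_j) jointly — γ_j is drawn with β_j
   integrated out under the two-component prior, which mixes far better than
   a conditional-γ update when the spike is narrow — then α (flat prior,
   normal conditional), π, δ1⁻², δe⁻². PIP_j is the retained-sample mean of
   γ_j; selection at a target FDR uses the Bayesian local-FDR rule
   FDR(t) = Σ_{PIP≥t}(1−PIP)/#{PIP≥t}. X columns are never standardized so
   β stays in log2-expression units per occurrence.
4. **Functional-site filtering.** Selected clusters are re-tested per
   pangene by OLS of expression on counts (≥3 genes, non-constant counts);
   Benjamini–Hochberg across all tested pairs (one global family); pairs
   with q < 0.05 and slope sign agreeing with the cluster's global posterior
   mean are retained.
5. **k selection.** 10-fold CV over k: clusters and prevalence filtering are
   re-derived inside each training fold (no leakage), held-out promoters are
   projected onto training clusters (absent clusters count 0), and fold R²
   is the squared Pearson correlation of prediction and observation. Splits
   are by gene, by pangene, or by accession.
6. **Motif and peak enrichment.** Cluster PWMs are built from member k-mers
   weighted by pan-genome frequency (+0.01 pseudocount). The scanner
   computes the exact null distribution of the integer-discretized log-odds
   score (bin width = score range/10000) by convolving per-position
   histograms, then thresholds at tail ≤ 1e-4; both strands and all
   alignments are scanned, with per-sub-window thresholds when the k-mer is
   shorter than the motif. Library enrichment of the selected clusters uses
   an equal-size resampling null; because per-cluster matching is a fixed
   property, the null count is exactly hypergeometric and is sampled
   directly. The empirical p carries the +1 correction. Occurrence-in-peak
   fractions use half-open any-overlap semantics; clusters are binned at
   >20% and the high-bin enrichment fold gets a percentile bootstrap CI that
   resamples clusters.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| promoter window | 2000 bp | upstream of the TSS, minus strand reverse-complemented |
| similarity k | 31 | shared distinct 31-mers per promoter pair |
| model k | 11 | selected by CV in the 7–12 range on the data at hand |
| prevalence | > 0.01 | strict fraction of promoters containing the cluster |
| q | 0.05 | background share of Var(y) fixing the spike δ0² |
| a_π, b_π | 1, 1 | uniform prior on the inclusion rate |
| a1, b1, ae, be | 0.01 | weakly informative variance priors |
| iters / burn-in / thin | 10000 / 5000 / 5 | 3000 iterations inside CV |
| FDR target | 0.1 | PIP-based local-FDR selection |
| site-filter α | 0.05 | BH-corrected per-pangene significance |

Geweke z-scores (first 10% vs last 50%, batch-means variances, 10 batches)
are monitored on log δe², π and the model size; |z| ≤ 1.96 on all three sets
the converged flag.

## Synthetic fixtures: what they emulate and what they do not

`simulate_pangenome` draws a random ancestral promoter per pangene and
mutates it independently per accession: iid substitutions (default 2%),
short geometric indels, and uniform 50–900 bp SV insertions. Planted motifs
carry additive effects (±1 log2 unit per occurrence by default) and are
embedded either inside carrier-specific SV insertions or written into the
allelic context at random offsets; `motif_mismatch_prob` lets carrier
pangenes receive one-substitution binding-word variants, emulating TF motif
degeneracy. Noise is calibrated so the planted signal explains ~60% of
non-baseline variance unless σ is given. Expression is generated exactly
from the additive model, so recovery tests probe the inference, not the
biology: there is no phylogeny, linkage, selection, chromatin context,
cooperative TF logic, or measurement model, and passing them says nothing
about those features of real pan-genomes.

A subtlety the fixtures expose: any (k+1)-window spanning a planted k-mer
has one variable flank position, and its four variants form a single
one-mismatch cluster exactly collinear with the motif's own cluster.
Posterior inclusion mass can land on either column, so planted-motif
recovery is scored by attributing a selected cluster to a motif when its
count column correlates with the motif's true carrier counts at |r| ≥ 0.8;
selections attributed to no motif count as false.

## Reference study conditions

`kprob.studies` freezes the bundled experiments at desk-scale problem sizes
(the package's own choice of study conditions):

- **Recovery**: 300 pangenes × 26 accessions, 500 bp windows, 5 planted
  11-mers (alternating SV/substitution context), k = 11, pangene covariates,
  1200 Gibbs iterations.
- **Null calibration**: 60 pangenes × 10 accessions, 250 bp windows, no
  planted motifs; the site filter is probed on 15 arbitrary clusters forced
  through as if selected, since the FDR selection itself is typically empty
  on noise.
- **k selection**: 60 pangenes × 12 accessions, 200 bp windows, three
  planted 8-mers with 0.5 mismatch degeneracy, pangene baseline SD 0.5,
  k ∈ {6..10}, 10 folds, 600 iterations per fit.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; GFF3 is converted on read.
- log2 similarity of a zero mean score is floored at 0; log10(CV²) of an
  invariant pangene is floored at −6; quantiles use linear interpolation
  with inclusive comparisons.
- Counting is forward-strand (an option merges reverse complements);
  PWM scanning is double-stranded because TF binding is strand-agnostic.
- The Gibbs chain runs over a sparse CSC X with residual maintenance;
  columns are visited in ascending index order each sweep (a random-scan
  flag exists). Tiny-shape Gamma draws are floored at 1e-300 and the slab
  variance is kept ≥ the spike variance; a diverging residual variance
  aborts with a diagnostic.
- With no covariates the response is centered (the intercept is absorbed);
  with covariates the α conditional uses a pre-factorized CᵀC.
- Per-pangene OLS pairs with <3 genes or constant counts are excluded from
  the BH family rather than counted as tests. BH scope is global by default
  (`per_cluster` available).
- CV R² is squared Pearson correlation (robust to per-fold calibration
  offsets); a 1−SSE/SST variant is available.
- The effect reported per cluster is the unconditional posterior mean
  (direction/selection) alongside the slab-conditional mean (magnitude).

## Known limitations

- The greedy first-fit clustering is order-dependent by design
  (deterministic, but a different abundance ordering gives a different
  partition); cluster identities are not stable across datasets.
- Collinear shifted-window clusters can share posterior mass with the
  causal cluster; interpretation should consider the member sequences of
  all selected clusters, as the attribution rule above does.
- FDR estimates inherit the model's calibration; with strong model
  misspecification (non-additive effects, heteroscedastic noise) PIPs are
  not guaranteed to be calibrated.
- The exact-p scanner matches the intent, not the implementation details,
  of FIMO; thresholds can differ by one score bin from other tools.
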