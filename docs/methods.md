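# Methods

## Model

For each ChIP-seq track, gene-level signal is the maximal narrowPeak
`signalValue` of any peak overlapping the gene's domain, 0 when no peak
overlaps. The enrichment statistic compares the empirical CDF of these
signals over the query list, `Q(c)`, with the ECDF over the background
list, `B(c)`, through the one-sided supremum `D_sup = sup_c (B(c) − Q(c))`.
The query is by construction a subset of the background, so `B − Q` is
evaluated on the grid of distinct background values, with the point just
below the minimum (where both cumulatives are 0) included; `D_sup` is
therefore never negative. `arg_Dsup` — the Critical ChIP — is the smallest
grid value attaining the supremum, which is the tie-break that maximises
the resulting target set and makes outputs deterministic. Target genes
are the query genes with signal *strictly* above the Critical ChIP; a
track with fewer than five targets is triaged before any inferential
statistics, as is a track whose background tail mean is zero (its
tail-enrichment ratio is undefined; we set r = 0).

### p-values

The default p-value applies the two-sided asymptotic Kolmogorov survival
function `2·Σ_k (−1)^{k−1} exp(−2k²λ²)` at `λ = sqrt(N_e)·D_sup`, with
effective size `N_e = N·X/(N+X)`; a one-sided mode (`exp(−2·N_e·D²)`) and
a permutation mode are selectable. Two caveats are intrinsic to the
design and worth stating plainly:

1. The query is *nested* in the background, violating the independence
   assumption of the two-sample KS test. `D_sup` measures subset vs
   pool; relative to a subset-vs-complement comparison, the difference
   is shrunk by a factor `(1 − X/N)` that `N_e` does not compensate.
2. The two-sided survival function doubles the tail of a one-sided
   statistic.

Both effects push in the same direction: the analytic p-values are
**conservative** with respect to the exact nested null. The permutation
mode (resample X genes from the background without replacement,
recompute `D_sup`, add-one empirical tail) is the calibrated reference;
the test suite demonstrates the conservatism quantitatively, and the
null-simulation tests confirm the analytic mode never rejects in excess
of its nominal level. Ranking by Score is unaffected by a monotone
deflation of p-values within a query, which is why the planted-factor
recovery is strong despite the conservatism.

Multiple testing uses Benjamini–Hochberg step-up across the non-triaged
tracks of one query (each query corrected independently; triaged tracks
are excluded before correction, since they are "not considered further").
The Score is `S = −log10(P_corr) · r`, with `P_corr` floored at the
smallest positive normal double before the log; log base 10 only rescales
Scores uniformly, and the 10% FDR highlight threshold reads naturally in
that base. Sorting is by Score descending, then corrected p ascending,
then track id.

### Tail ratio

`n = ⌈0.05·X⌉` with a floor of 1, so small queries keep a non-empty
tail; `μ_q` and `μ_b` are the means of the `n` largest query and
background signals and `r = μ_q/μ_b`. "Top n of the population" means
the top n of all N background genes for that track.

## Matrix building

Coordinates are 0-based half-open throughout (the BED convention).
A peak is in a domain if the intervals intersect by at least 1 bp (the
peak summit is not used). Domains: gene body ± 1 kb or ± 5 kb flank
(strand-symmetric), or a promoter window 1000 bp upstream to 300 bp
downstream of the TSS, strand-aware (TSS = `tx_start` on `+`,
`tx_end` on `−`; upstream is 5'-ward along the gene's strand), clipped
at coordinate 0. Duplicate annotation symbols on one chromosome merge to
the union of isoform extremes so the matrix has one row per symbol.
Engineered-factor status is manifest metadata, never inferred. Overlap
queries use per-chromosome interval trees; the test oracle is an
exhaustive all-pairs scan.

## Evaluation protocol

The positive class for a perturbation dataset is the manipulated factor
plus its potential interactors — partners in a STRING-style links table
with combined score strictly greater than 300 (the table is treated as
undirected; matching to ranked lists is case-insensitive exact symbol
match). Ranked lists become calls vectors with scaled ranks `i/m`;
prediction score is `1 − scaled rank`. PR and ROC curves come from
scikit-learn's `precision_recall_curve` / `roc_curve`; AUCs are
trapezoidal areas over the emitted points, integrated in threshold order
so tied-recall segments contribute zero width (an average-precision mode
is available; the two differ in the second decimal on typical inputs).
No class balancing is applied, so PR is the headline metric. For the
rank-cumulative analysis, contiguous runs of positive calls collapse to
the scaled rank of the first call in the block; `D(r)` is the ECDF of
the collapsed positive ranks and the area under `D(r) − r` has the
closed form `1/2 − mean(collapsed ranks)`, which the tests verify
against fine-grid trapezoid integration. Weighted variants multiply a
curve or AUC by the fractional rank `F_R = 1/(integer rank of the
manipulated factor)`. Distribution comparisons use the two-sample
two-sided KS test on the collapsed positive-rank samples.

## Synthetic data

Signals are zero-inflated log-normal per track: zero with probability
0.6, otherwise `LogNormal(μ=1, σ=1)` — mimicking the field observation
that many genes show low-but-detectable signal under a heavy right tail,
without claiming ENCODE realism. One planted track shifts the query
genes' signals: multiplicatively on nonzero values by the factor
`effect` (so `effect=3` is "3× signal"; 0 or 1 is the null), or
additively on all values. The co-regulated-background variant draws the
true background as a subset of the matrix universe and scales its genes'
signals on *every* track by a bias factor (default 2.0), emulating the
correlation between expression and ChIP signal that makes a bespoke
background list matter; the query is drawn from that background.

What the generator does **not** model: correlated tracks, genomic
position effects, cell-type structure, or realistic peak shapes. Passing
recovery tests therefore show the statistic behaves correctly under its
own assumptions, not that it is robust to every property of real ENCODE
tracks. Peak fixtures place one 200 bp peak wholly inside each gene's
domain (strand-aware, so the same fixture round-trips under all three
domain kinds) with `signalValue` equal to the intended matrix cell,
giving an exact round-trip through the matrix builder.

## Validation experiment sizes

Chosen as the smallest sizes at which the expected effects are decisive:

- Planted recovery and null calibration: 2000 genes × 50 tracks,
  100-gene query, effect 3×, 20 replicates each. Recovery = planted
  track ranked #1; observed ≥ 95% of replicates, with ≤ 10% null
  false-calls at 10% FDR.
- Background sensitivity: 1000-gene universe, 400-gene co-regulated
  background (bias 2.0), 80-gene query, 15 tracks, 50 replicates
  (30 in the acceptance script). Omitting the background list shifts the
  per-replicate median corrected p down; asserted by a one-sided paired
  Wilcoxon test. Counting 10%-FDR threshold crossings instead is
  underpowered at these sizes because of the p-value conservatism
  described above.
- Permutation oracles: 10⁵ resamples via a vectorised sorted-quantile
  formulation of `D_sup` (one `searchsorted` against the pooled
  background per batch).

## Known limitations

- Analytic p-values are conservative under the nested design (above);
  use the permutation mode when calibrated p-values matter.
- Distal enhancers are outside every domain definition; signal assigned
  to a gene is promoter/body-proximal only.
- The evaluation consumes symbol-level ranked lists and links tables; no
  identifier aliasing or Ensembl-protein mapping is attempted.
- Matrix files are read fully into memory; fine at desk scale and for
  ENCODE-scale matrices (~28k × ~2.3k doubles ≈ 0.5 GB) on a workstation,
  but no out-of-core path exists.
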