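# Methods

This note defines the models and algorithms implemented in `airscreen`, the
default parameters and why they were chosen, and the limitations of the
synthetic data the package validates itself against.

## 1. TF-interactome screen

### Inputs

- a cell × gene matrix of expression values with one class label per cell and
  a designated *basal* class (`LabeledExpressionMatrix`);
- a gene → gene-set annotation (`GeneSetAnnotation`, GO-style);
- a weighted undirected interaction network (`InteractionNetwork`) with edge
  confidences in [0, 1]. STRING-style 0–1000 integer scores are divided by
  1000 on ingest; duplicate edges keep the maximum confidence and self-loops
  are dropped.

### Procedure

1. **TF universe.** Genes annotated with the DNA-binding term
   (`GO:0043565` by default) that are present in the matrix.
2. **Expression filter.** Each universe gene is ranked by the *maximum over
   classes* of its per-class mean expression; the top `k = 100` are tested.
   Using the class-wise maximum keeps TFs expressed in any single
   compartment, not just broadly expressed ones.
3. **Interactome.** A TF's gene set is its network neighbors, restricted to
   genes in the matrix, filtered at `min_confidence` (default 0), and capped
   at the `cap = 250` highest-confidence neighbors (ties broken by gene id).
4. **Scores.** With basal mean x̄_g,b, non-basal mean x̄_g,n and pseudocount
   ε = 0.01, the per-gene fold change is (x̄_g,n + ε)/(x̄_g,b + ε). The
   **combined score** is the mean fold change over the interactome. The
   **aggregated score** replaces means with positive-cell fractions
   (fraction of cells with value > 0 in each group); `aggregation="sum"`
   returns the sum instead of the mean. The pseudocount bounds the ratio for
   silent genes and maps all-zero genes to exactly 1.
5. **Permutation null.** For each TF, `n_perm = 999` gene sets of matched
   size are drawn uniformly without replacement from all matrix genes. The
   add-one estimator is
   p_greater = (1 + #{S_null ≥ S_obs}) / (1 + n_perm);
   the two-sided p is min(1, 2·min(p_greater, p_less)). The add-one form is
   conservative and never returns 0; its one-sided floor at n_perm = 999 is
   1/1000. Drawn sets are scored in canonical (sorted) gene order so the
   result is a deterministic function of the set, and the universe is sorted
   internally so results are invariant to input gene order.
6. **Multiple testing.** Benjamini–Hochberg adjustment
   (`scipy.stats.false_discovery_control`) across the TFs that received a
   p-value. Output is sorted by p, ties broken by TF id; TFs with empty
   interactomes are carried through with missing scores.

## 2. Synthetic data with planted ground truth

### Expression matrix (`ScreenSimConfig`)

Counts are gamma-Poisson (negative binomial) with dispersion θ = 2 around
per-gene baselines drawn log-normally (σ = 0.6) about `mean_expression = 1`.
Bernoulli dropout zeroes each entry with probability 0.3. Planted
interactors have their mean multiplied by 2^`planted_log2fc` (default 4×) in
every non-basal cell. Defaults: 3 classes (BSC basal, SC, MCC), 200 cells
per class, 1,000 genes, 100 TF-annotated genes, 50 planted interactors.

The network contains the planted TF's edges to exactly its interactors
(confidence U(0.7, 1)) plus `background_edges = 20,000` edges between
uniformly random gene pairs (confidence U(0.4, 1)); colliding duplicates are
dropped and reported. The default density (mean degree 40) is deliberately
interactome-like: the screen averages fold changes over neighbor sets and is
only meaningful when those sets are sizable, as they are in
confidence-filtered interaction databases. In a near-empty network a TF's
"interactome" can degenerate to a single random gene, whose fold change is
an average of nothing but that gene's noise — a regime the method does not
target.

### Genome, peaks and annotation (`GenomeSimConfig`)

Chromosome sequences are i.i.d. with configurable GC fraction (default
uniform A/C/G/T), 2 chromosomes × 1 Mb, 100 non-overlapping genes of 10 kb
with random strands. 500 peaks of width 200 bp are placed at signed offsets
drawn from a Laplace(0, 5 kb) distribution around random gene TSSs;
`planted_site_fraction = 0.3` of peaks receive the exact motif consensus
(default `TGATGCAA`) at their summit on the forward strand. Ground truth
records each peak's site status and true signed TSS offset.

### Bead traces (`TraceSimConfig`)

displacement(t) = A·sin(2πft) + drift·t + N(0, σ²), sampled at
`fs = 240` frames/s for 10 s. Defaults: f = 10 Hz, A = 3, σ = 0.5.
Frequencies at or above Nyquist are rejected at validation.

## 3. Exact motif threshold and scanning

Scores are log₂-odds of the PWM against a 0-order background. The null score
distribution under the background is computed **exactly** by position-wise
convolution of the per-position score distributions discretized on a lattice
(default step 0.01 bits) — no sampling. `motif_score_threshold(m, p)`
returns the smallest *achievable* lattice score whose exact tail probability
is ≤ p, minus a half-lattice guard of L·precision/2 so that rounding can
never exclude a word whose exact score ties the threshold. If no achievable
score has tail ≤ p (e.g. a uniform PWM, or p below 1/4^L under a uniform
background), a validation error names the smallest attainable tail.
Scanning evaluates both strands (reverse complement of the extended
log-odds), prefers the forward strand on ties, and scores ambiguous bases
(N) as 0 log-odds, i.e. as background.

## 4. Peak geometry and candidate genes

Peaks are BED-style 0-based half-open; genes are GTF-style 1-based inclusive.
A gene's TSS is its start on + and its end on −. The signed offset of a
position to a TSS is measured along the direction of transcription
(negative = upstream). A peak's anchor is its summit when known, otherwise
its midpoint.

- **TSS density profile:** peak-anchor offsets to the *nearest* TSS (ties to
  the smaller gene id), histogrammed in 200 bp bins over ±20 kb and smoothed
  with a 5-bin moving average (edge-normalized).
- **Region classification:** promoter = within (−2000, +500) of the TSS;
  gene body = within the gene span; distal otherwise.
- **Candidate genes:** a gene is a candidate when ≥ 1 motif-bearing peak has
  a signed offset within −20 kb … +0.5 kb of its TSS. All genes on the
  peak's chromosome are examined, not only the nearest, so one peak can
  support several genes. Reported per gene: supporting peak count, the
  offset smallest in magnitude, and the best motif score.
- **Depth comparison:** per-peak mean coverage in control and treated
  conditions, normalized per million (library totals from the provided
  tracks unless given explicitly), log₂ ratio with pseudocount 0.5; peaks
  with zero signal in both conditions are excluded and counted.

## 5. Ciliary beat frequency

Traces (≥ 64 samples) are linearly detrended, Hann-windowed and Fourier
transformed (real FFT). The dominant frequency is the argmax of spectral
power within the physiological band 2–40 Hz, refined by parabolic
interpolation of the log-power peak (clamped to ±½ bin and to the band).
Reported per trace: frequency (Hz), the peak bin's fraction of in-band
power, the spectral resolution fs/N, and a harmonic flag set when the bin at
twice the dominant frequency exceeds half the dominant power. Traces whose
in-band spectrum is numerically zero (constant or pure drift) raise a
no-signal error; `batch_cbf` collects such failures and summarizes the rest
(mean and SD across beads; SD is undefined for a single bead).

## 6. Default parameters at a glance

| Parameter | Default | Rationale |
| --- | --- | --- |
| pseudocount ε | 0.01 | small relative to mean expression 1; bounds ratios for silent genes |
| n_perm | 999 | one-sided p floor 1/1000; runtime linear in n_perm |
| k (TFs tested) | 100 | screen breadth at tractable cost |
| interactome cap | 250 | bounds set size so scores compare across hub and non-hub TFs |
| motif lattice step | 0.01 bits | threshold error ≤ L·0.005 bits, negligible vs typical score gaps |
| candidate window | −20 kb … +0.5 kb | regulatory neighborhood upstream-weighted around the TSS |
| promoter window | −2 kb … +0.5 kb | conventional promoter-proximal span |
| CBF band | 2–40 Hz | physiological ciliary beat range; excludes DC/drift leakage |
| fs, duration | 240 Hz, 10 s | 0.1 Hz resolution; Nyquist 120 Hz well above the band |

Problem sizes (1,000 genes, 600 cells, 500 peaks, 2 Mb genome) are chosen so
the full validation suite runs in minutes on one CPU while leaving every
statistical property measurable; they are package defaults, not biological
claims.

## 7. Limitations

- Synthetic expression treats genes as independent given the class label: no
  co-expression structure, cell-size/library-depth variation, batch effects
  or ambient contamination. Fold changes are computed on raw counts; no
  normalization layer is modeled or applied.
- The interaction network is Erdős–Rényi background plus one planted star;
  real interactomes have heavy-tailed degrees and community structure.
- The genome background is 0-order i.i.d.; no repeats, CpG islands or
  higher-order composition. Only a single motif with exact-consensus
  planting is simulated, so scanner sensitivity to degenerate sites is
  exercised only through the PWM, not the data.
- The beat model is a single stationary sinusoid with linear drift; real
  recordings show amplitude modulation, frequency drift and multi-bead
  interference. The harmonic flag detects, but does not correct, waveform
  asymmetry.
- Permutation p-values are conditional on the realized expression matrix;
  they calibrate set-level enrichment, not differential expression of
  individual genes.
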