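# Methods

## Full-length transcript selection

### Model

A per-gene cluster of Nanopore cDNA reads is summarised by its read-length
histogram (1 bp bins spanning the observed length range). Full-length reads
of an isoform of length `L` concentrate near `L`: substitutions do not move
read length, and with roughly balanced insertion/deletion rates the mode
stays at `L` with a spread of a few tens of bases at most (indel length
jitter has s.d. ≈ sqrt(L·(p_ins+p_del)); ≈ 8 bp for a 3 kb transcript at 2%
total indels). 5'-truncated reads — the dominant artifact of oligo-dT-primed
cDNA — scatter broadly below the full length. Peaks of the histogram are
therefore isoform lengths, and reads near a peak are putatively full-length.

The method is blind to isoform *identity*: two alternative transcripts of
equal length produce one peak and both are retained. It assumes isoform
lengths are separated by more than the wavelet widths in use; modes closer
than ~50 bp merge.

### CWT peak calling

Peaks are found by continuous wavelet transform with the Ricker kernel

    psi(t; a) = 2 / (sqrt(3 a) pi^(1/4)) · (1 − t²/a²) · exp(−t² / 2a²)

over a width grid of 50–200 bp in steps of 10 (the range in bp matches
1 bp histogram bins; the step is our choice — results are insensitive to it
because ridge filtering only needs ≥ n_widths/4 consecutive detections).
Each width row is the same-length convolution of the signal with a kernel
truncated at min(10a, n) points (psi < 1e−10 beyond |t| > 5a). Per-width
relative maxima (plateaus resolve to their leftmost index) are linked into
ridge lines from the largest width downward: a maximum joins the nearest
active ridge within a_row/4 columns of the ridge's position entering that
row, otherwise it seeds a new ridge; a ridge with no connection for more
than gap_thresh consecutive rows is closed. A ridge is called a peak when

* it spans at least ⌊n_widths/4⌋ rows, and
* its coefficient at the smallest-width endpoint is at least `min_snr`
  times the noise floor in magnitude, where the noise floor is the 10th
  percentile of the smallest-width row within a window of `ceil(n/20)`
  points around the peak.

Defaults (min_snr = 1.0, noise percentile 10, gap_thresh = smallest width)
are the documented defaults of the routine this stage reimplements,
`scipy.signal.find_peaks_cwt`; the test suite uses that routine as an
independent cross-check and requires ≥ 95% agreement (count and ±5 bp
locations) on 200 seeded multi-bump signals. FFT convolution is not used;
the direct `np.convolve` path is verified against a shift-and-accumulate
direct-summation oracle at 1e−8 relative tolerance.

### Peak support and retention

CWT ridge filtering alone cannot reject an *isolated* histogram spike: a
single stray read length matches the wavelet at every width and the noise
floor around it is ≈ 0, so its SNR is effectively infinite. On sparse
truncation backgrounds this produces one-read "peaks". Since the method's
purpose is to find the *common* read lengths, a called peak is kept only
when at least max(2, ⌈0.1 · n_reads⌉) reads lie within peak_tol/2 of it.
The support window is half the retention tolerance deliberately: genuine
full-length modes are concentrated (±3σ ≲ 25 bp, above), while chance
clumps of truncations are diffuse.

Reads within peak_tol (default 50 bp, the smallest wavelet width) of any
surviving peak are retained. If no peak survives or no read matches, the
single longest read is kept (truncations are shorter than full length) and
the result is flagged `fallback_used`; every cluster keeps ≥ 1 read.
Clusters with fewer than 5 reads skip peak calling entirely and keep all
reads — a histogram with < 5 counts cannot support 50–200 bp-wide peaks.

## Minimizer-sketch clustering

A stand-in for the Minimap + Carnac-LR front end so the pipeline runs
end-to-end without an aligner. Reads are sketched with canonical
(strand-min) k-mer minimizers (k = 15, window w = 10, fixed splitmix64
hash), and an edge joins two reads when the containment Jaccard
|A∩B| / min(|A|,|B|) reaches 0.1; clusters are connected components. The
min-denominator keeps truncated reads attached to their gene. The 0.1
threshold is calibrated to the error regime this tool targets: at ~5%
error only (0.95)^15 ≈ 46% of 15-mers are error-free, putting same-gene
containment near 0.15–0.3, while unrelated reads score < 0.02. No
equivalence with Carnac-LR's community detection is claimed; real
Carnac-LR cluster files are the preferred input path.

## Genome size

`G = n_kmer / c_kmer`, where `n_kmer` counts k-mer observations (canonical,
N-skipping, K = 21 by default) and `c_kmer` is the coverage depth at the
homozygous peak of the multiplicity histogram. Equivalently
`G = n_base / c_base` with `c_base = c_kmer · L/(L−K+1)` for mean read
length `L`. Sequencing errors create mostly-unique k-mers that pile up at
multiplicity 1–3; the first local minimum of the histogram (scanning
upward, plateau ties resolving to the smallest multiplicity) separates this
error spike from the coverage peak, and with `exclude_error_peak` the
observations below the trough are dropped from `n_kmer`. Histograms are
capped at multiplicity 10,000 (the repeat tail is pooled; it cannot affect
peak finding).

Numerical choice: the reported `c_kmer` refines the integer histogram mode
to the count-weighted mean multiplicity within ±max(2, 0.15·mode) of it.
When the true k-mer coverage is near an integer `c`, the multiplicity
distribution (≈ Poisson) has nearly equal mass at `c−1` and `c`, so the raw
argmax is a coin flip between adjacent integers — a 2.5% error at c = 40 —
while the windowed centroid is stable to < 0.5%.

Counting is vectorised: reads are concatenated with `N` separators, 2-bit
base codes are accumulated into 64-bit k-mer codes by a Horner scheme
(forward and reverse-complement in-place passes), windows containing
non-ACGT bases are masked via a cumulative-sum trick, and multiplicities
come from `np.unique`. ~4×10⁷ 21-mers count in well under a minute.

## Window density, contamination flags, contiguity

Windows are constant-width (default 1 Mb, step 100 kb), starts at multiples
of the step with start+width ≤ chromosome length; trailing partial windows
are omitted so densities stay comparable, except that a chromosome shorter
than the width becomes one whole-chromosome window. A feature counts in
every window it overlaps by ≥ 1 bp. Gene/repeat correlation is the Pearson
r across windows (undefined → error if a track is constant).

A window is a contamination candidate when gene_count > 3× the genome-wide
median and repeat_count < 0.5× the median repeat count (vacuous when the
repeat median is 0). The factors are this package's defaults, motivated by
reported bacterial-contig densities of roughly 4× gene enrichment and 0.33×
repeat depletion; both are parameters. Flag scanning should be run with the
window width matched to the expected contaminant scale (e.g. 100 kb tiling
for ~100 kb bacterial inserts): a 100 kb gene-dense block diluted into a
1 Mb window shifts neither density past its threshold.

N50/N90 are the length at which the descending cumulative sum first reaches
50%/90% of the total; L50/L90 are the corresponding 1-based ranks. Checked
against a brute-force sort-and-scan oracle on 1000 random inputs.

## Simulator: what it does and does not emulate

`simulate_transcriptome` draws, per gene, 1–3 isoform lengths in 800–3000 bp
with pairwise separation ≥ 300 bp (sampling in a separation-shrunk range and
re-adding offsets, so the guarantee is exact); isoforms are 3'-terminal
suffixes of one gene sequence, reflecting shared 3' ends under oligo-dT
priming and giving same-gene reads sequence overlap for the clusterer.

`simulate_cluster_reads` emits `round(0.7 · n)` full-length reads dealt
round-robin across isoforms — making "≥ 30 full-length reads per isoform" a
deterministic property of the battery sizes used — and truncated reads that
keep the 3' end with a cut point uniform over 10–90% of the isoform length.
Errors are independent per base: substitution 3%, insertion 1%, deletion 1%
(5% total; balanced indels keep the full-length mode centred on the isoform
length). `simulate_genome_and_reads` samples fixed-length reads uniformly
from both strands of a uniform-random genome.

Not modelled: homopolymer-biased errors, quality-score realism, expression
level variation, chimeras, strand mixtures within cDNA clusters, genomic
repeat structure, heterozygosity and ploidy. Passing tests therefore show
the algorithms behave correctly under idealised noise of realistic
magnitude, not that selection thresholds are optimal for any particular
flow-cell chemistry; on real data the clustering front end should be
Minimap + Carnac-LR, and genome-size estimates inherit the usual biases of
k-mer methods on repeat-rich or heterozygous genomes.

## Problem sizes in the standard batteries

The shipped test suite and `scripts/acceptance.py` use: 50 random signals
(≤ 2048 points) for the convolution oracle; 200 multi-bump signals for
reference agreement; 200 clusters of 45 reads per isoform (1–3 isoforms)
for recovery/purity; a 1 Mb genome at 50× / 100 bp reads for genome size
(error-free and 0.5% substitutions); 1000 random length lists for
contiguity; 10 Mb chromosomes at 100 kb tiling for flagging. These sizes
give stable percentages while keeping a full run in the minutes range on
one CPU.

## Known limitations

* Isoforms closer than ~50 bp in length merge into one peak (inherent to
  the width grid); same-length isoforms are indistinguishable by design.
* The sketch clusterer is O(n²) in reads and intended for desk-scale data.
* The contamination rule flags *candidates* only; taxonomic confirmation
  (BLAST/kraken-style) is out of scope.
* `find_coverage_peak` requires a visible trough: error-dominated
  histograms (coverage ≲ 4×) raise rather than guess.
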