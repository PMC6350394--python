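# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that were genuinely open.

## Genome ingestion and grouping

GenBank flat files are parsed with Biopython; coordinates are kept 1-based
inclusive (the GenBank convention) and every exported table says so in its
header comment. Ambiguous bases (N, R, Y, …) are retained in the sequence
but excluded from the denominators of genome size, GC content and skew.
For organisms with several replicons the representative is the largest
replicon not annotated as a plasmid; if every replicon is a plasmid, the
largest overall is used so selection is total. Length ties are broken by
lexicographically smallest accession, making the choice order-independent
(how multi-chromosome ties should be resolved is not standardized; this is
our convention). Genus is the first whitespace-delimited token of the
organism name unless a `genus_override` is supplied (for "Candidatus"
names and similar). The grouping threshold defaults to 6 publications out
of the 54-survey corpus, the conventional ≥10% cut for calling a genus
"Common BE"; it is a parameter everywhere it is used.

## GC skew index

Per-window skew is (C−G)/(C+G) counting only C and G inside the window;
windows without any C or G score 0. The chromosome is truncated (not
padded) to `n_windows · floor(L/n_windows)` bases so all windows are equal
— the bias is at most `n_windows − 1` trailing bases. The window number
defaults to 4096, which keeps spectral resolution comparable across
genomes and damps coding-region composition bias.

A chromosome replicated from a single origin shows one skew oscillation
per genome, so the index takes the Fourier power at frequency 1 (cycles
per genome) relative to the mean power over frequencies 1…n/2; the
zero-frequency (mean skew) term is excluded from the denominator, since it
reflects overall strand composition, not replication asymmetry. The
second component is the peak-to-trough span of the cumulative skew curve.
The two are combined geometrically,

    GCSI = sqrt((SR / 6000) · (dist / 600)),

with both normalization constants config-exposed. With 4096 windows these
defaults place an ideal ±0.3 square-wave skew near 1, a strong natural
skew in the 0.5–0.7 range and i.i.d. sequence below 0.005, matching the
published dynamic range of the index (0 to ≈ 1). `sr` agrees with a
brute-force DFT sum on small vectors (tested), and the index is invariant
under complementation because both components depend only on skew
magnitudes.

## S value (selected codon usage bias)

Highly expressed genes are selected from product annotations:
case-insensitive matches of "ribosomal protein" or "elongation factor
Tu/G/Ts/P", with a negative pattern list (methyltransferase, hydroxylase,
kinase, pseudouridine, acetyltransferase, modification) removing enzymes
that merely mention those products. Pseudogenes are excluded.

Codon counting honors strand and `codon_start`, truncates trailing partial
codons, excludes the terminal stop, and skips genes containing internal
stop codons (mis-annotations). Codons with ambiguous bases match no family
and drop out. The background set is **all** annotated non-pseudo CDSs,
HEG included: this matches the usual definition ("the entire genome"), and
in real genomes HEG contribute only a few percent of family codons so the
inclusion bias is negligible. (In small synthetic genomes it is not —
recovery tests therefore use specs where HEG are ≤ 2% of family codons.)

The estimator maximizes the joint binomial log-likelihood of the HEG
C-ending counts across families under a single shared S (per-family
log-odds are reported for diagnostics), using bounded scalar optimization
on [−10, 10] to 1e−6. A degenerate HEG family (k = 0 or k = n) receives a
0.5 pseudocount on both of its HEG codon counts; background-only zero
families are dropped. With one family and c = 0.5 the MLE reduces to the
closed form S = ln(k/(n−k)), which anchors the unit tests; a dense
grid-search oracle confirms the optimizer on random count tables to 1e−3.

## 16S diversity

Pairwise distances use the K80 closed form
`d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)` with transition/transversion
proportions computed over columns where both sequences have unambiguous
A/C/G/T (pairwise deletion, the default of the classic `dist.dna`-style
implementations; complete deletion was considered and rejected because LTP
alignments are long and gappy, and pairwise deletion retains far more
signal). Saturated pairs (non-positive log argument) become missing values
rather than infinities; Dmean reports how many pairs were dropped. Dmean
is defined only for genera with more than two taxa. Faith's PD sums the
branch lengths of the minimal root-inclusive subtree spanning the genus's
taxa on a user-supplied newick tree (dendropy). Genus membership is taken
from the alignment labels, never re-derived.

## Group statistics

The Wilcoxon rank-sum test uses exact enumeration when `n1·n2 ≤ 400` and
the pooled sample is tie-free, otherwise the tie-corrected normal
approximation with continuity correction — exact where enumeration is
cheap, and the same large-sample behavior as the standard R default
elsewhere; the switch point is config-exposed. Two identical constant
groups return p = 1. BH q-values are computed within each invoked
comparison battery (the features of one run, or the category×feature grid
of the environment battery) — the battery membership is what the output
table shows. Cliff's delta uses the dominance definition (ties contribute
zero), computed by sorting and binary search so the 717×1863-scale
comparisons are cheap, with magnitude labels at |d| = 0.147/0.33/0.474.

## Synthetic-data generator

The generator emulates exactly the statistical structure the analyses
assume, with i.i.d. bases outside the tracked codon families:

* background bases are drawn independently per position with
  strand-dependent probabilities — on the leading-strand arc (origin →
  terminus, defaults 0.0 and 0.5 as genome fractions)
  P(G) = gc/2·(1+k) and P(C) = gc/2·(1−k), reversed on the lagging arc,
  A/T splitting the remainder evenly; k is the skew strength in [0, 1];
* genes are placed non-overlapping on alternating strands (exercising
  strand-aware extraction); each is ATG + a shuffled block of family
  codons + TAA, with C-ending probability `p_f = c·e^S/(1−c+c·e^S)`,
  S = `s_true` for HEG ("50S ribosomal protein L…") and 0 for
  "hypothetical protein" genes, and neutral background c = 0.5;
* `generate_codon_counts` draws the same model at the sufficient-statistic
  level, nesting the HEG counts inside the whole-genome counts exactly as
  chromosome-level counting would;
* alignments evolve each taxon independently from a uniform ancestor under
  K80 at branch length d*/2, so the expected pairwise distance is d*.

Everything is a deterministic function of the spec and its single seed;
regenerated GenBank files are byte-identical and round-trip through the
parser unchanged.

What this does **not** emulate: real gene content and length
distributions, amino-acid composition outside the four families, codon
context, indels, rRNA operons, or correlated base composition. In
particular, because the tracked family codons are AT-rich, gene-dense
small simulations depress GC content and dilute the replication skew —
passing tests demonstrate correctness of the estimators under their
generative model, not the biological realism of simulated chromosomes.

## Problem sizes used in tests and the acceptance script

S-recovery runs 200 replicates per true S ∈ {0, 0.5, 1, 2} at the count
level (2000 HEG codons per family inside a 100k background, the ≤2% HEG
regime of real genomes); chromosome-level recovery is verified end-to-end
at 20 seeds on 1.3-Mb genomes. GCSI null and monotonicity use 2-Mb
genomes (3 null seeds; 5 seeds per skew strength over k ∈ {0, 0.05, 0.1,
0.2, 0.3}). Pipeline tests use 60-kb genomes with 256 windows so the whole
bundle stays fast; window number only rescales the spectral resolution.
These sizes were chosen to make sampling error small relative to each
asserted tolerance.

## Known limitations

* The GCSI normalization constants are calibrated to the published dynamic
  range, not refit per dataset; strongly atypical window numbers change
  the SR scale (SR grows linearly with window count for a fixed-shape
  signal) and would need recalibration.
* The S model assumes a single shared shift across the four families;
  genomes with family-specific tRNA modifications will show heterogeneous
  per-family log-odds (reported for diagnosis, not modeled).
* Dmean inherits 16S limitations (intragenomic heterogeneity, transfer);
  saturated pairs are dropped, which slightly biases Dmean downward for
  deeply diverged genera.
* The environment battery compares flagged vs non-flagged genomes within
  the Common BE group only; flags are taken from the metadata table as
  given.
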