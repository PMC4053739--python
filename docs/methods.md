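# Methods

This note documents the model behind `motifdens`, the numerical and design
choices that were genuinely open, what the synthetic generator does and does
not emulate, and the problem sizes used by the validation protocols.

## Model and procedure

**Motifs.** A motif is an IUPAC consensus string; it denotes the set of
exact words given by the Cartesian product of its per-symbol nucleotide
sets.  A gene *contains* a motif if any substring of its regulatory
sequence belongs to that set — presence is binary, occurrence counts play
no role in scoring.  Masked bases (`N` in an input sequence) match no
symbol, a deliberately conservative treatment of unknown sequence.  In
double-strand mode a motif and its reverse complement are one object:
q-mer enumeration keeps the lexicographically smaller member of each
reverse-complement pair, scanning also runs the reverse-complement motif
over the stored strand, and a self-reverse-complementary motif is scanned
once per window so the same interval is never double counted.

**Neighborhoods.** Distances between expression profiles are Euclidean by
default (1 − Pearson optionally).  The raw kNN digraph has an arc g → g'
when g' is among the k nearest profiles of g; distance ties are broken by
gene input order so the graph is deterministic.  High-dimensional kNN
graphs exhibit hubness — a left-skewed in-degree distribution where a few
genes occupy very many neighborhoods — which biases density estimates
toward those hub genes.  The correction: symmetrize the arc set (every
gene then lies in ≥ k neighborhoods), and resample exactly k neighbors per
gene from its symmetrized neighborhood, sequentially without replacement,
with probability inversely proportional to the neighbor's symmetrized
in-degree d(g').  d(g') stays fixed during sampling (it is a property of
the symmetrized graph, not of the growing balanced graph), and "without
replacement" is per gene — the draws of different genes are independent.
The implementation uses exponential sort keys (draw E ~ Exp(1) per
candidate, keep the k smallest E·d(g')), which is distributionally
identical to the sequential renormalized scheme and vectorizes; a test
checks the implied selection probabilities against the sequential
formula.  Genes are processed in input order under one seeded generator.

**Scoring.** Both criteria exist in a discrete (cluster) and a continuous
(neighborhood) version.  Continuous hypergeometric: the upper tail is
monotone in the count, so the max over genes is evaluated at the largest
neighborhood count; tails are computed in log space and never from an
underflowed linear value.  Continuous mutual information: the per-gene
Bernoulli KL divergence between the local density n_mkg/k and the global
frequency n_m/n, averaged over genes — hence always ≥ 0, and 0 exactly
when every density equals the global frequency.  A motif present in all or
no genes scores 0 by continuity (logged).  Log bases: natural log for
−log-tail scores (only ranking matters there) and base 2 for mutual
information (bits); both are configurable and recorded in run manifests.
These quantities are scores, not P values: significance comes only from
the shuffle FDR.

**Seeding.** All 4^q q-mer presences are collected in one pass over the
sequences (integer window codes; windows containing masked bases are
skipped).  The null rescoring shuffles the mapping between sequences and
expression profiles: one shared random gene permutation per round applied
to the presence rows, ten rounds by default, with the neighbor graph held
fixed — sequences are never rescanned.  FDR(s) = (mean null count ≥ s) /
(observed count ≥ s), capped at 1, with no monotonicity smoothing; each
shuffle round uses one shared permutation for all q-mers rather than one
permutation per q-mer (cheaper, and the estimator only needs the joint
null score distribution).  Seeds are q-mers with FDR below 0.001, ranked
by score with string tie-breaks.

**Refinement.** Generalization candidates replace one non-degenerate
position with any strict superset symbol (7 per base; `N` is allowed — the
elongation stage and length cap bound the triviality it could introduce).
A candidate is admissible only if its density profile correlates with the
*original seed's* profile at ≥ α — anchoring to the seed rather than the
previous iterate prevents drift across iterations.  Acceptance requires a
strict score improvement (guaranteeing termination), ties break by motif
string.  Generalization runs to a fixpoint before elongation begins; no
interleaving, and elongated motifs are not re-generalized afterwards.
Elongation prepends/appends any of the 15 symbols up to max_len (9 by
default, at most 15) with no α gate: extension can only shrink the word
set.  Appending `N` never changes matches away from sequence edges, so
`N`-extensions never strictly improve and are never accepted.  Density
profiles during refinement use the same balanced graph as seeding, for
score comparability.  Each seed is optimized independently of the others.

**Filtering.** Overlap is the maximum ungapped aligned length over all
offsets (and, in double-strand mode, both orientations of the second
motif) such that *every* aligned symbol pair has a non-empty IUPAC
intersection — degenerate intersections such as N-N count, since the rule
is "non-empty intersection".  Motifs are redundant iff overlap ≥ 4 and
density-profile Pearson ≥ γ; a flat profile contributes correlation 0
(logged).  Greedy retention visits motifs by descending score (string
tie-break, so the output is order-independent) and keeps a motif iff it is
not redundant with anything already kept.

**Reporting.** Occurrence distances are measured from the codon-proximal
end of the stored sequence (upstream regions: the 3' end = start codon;
downstream: the 5' end = stop codon); histograms count occurrences by
default, genes-per-bin is an option since either convention is defensible.
The expression heatmap bins each condition's values into 25 equal-width
bins over that condition's range (equal-frequency available as a flag) and
shows the density z-score of each occupied cell; empty or degenerate cells
are NaN.  The strand-bias and method-comparison statistic is the exact
two-sided sign test: double the smaller exact binomial tail, cap at 1.
The ranked gene list applies the density z-score per gene and keeps the
genes that possess the motif.

**Database evaluation.** Predicted motifs become PWMs by mapping each
symbol to the uniform distribution over its set (columns ordered A,C,G,T).
The alignment score sums per-column Pearson correlations over ungapped
offsets with at least 4 aligned columns (mirroring the filter's overlap
gate; zero-variance column pairs contribute 0).  The null shuffles columns
across the whole database pool, preserving target lengths (within-motif
shuffling is available as a flag); P = (1 + #null ≥ observed) /
(1 + n_shuffles) with the +1 pseudo-count avoiding zero P at finite
shuffles.  Matches are counted after Benjamini–Hochberg selection at 15%
FDR over the best-match P values, and queries sharing a best target count
once (lowest P wins).

## Parameters

| name | default | meaning |
|---|---|---|
| q | 7 | seed word length (4^q candidates) |
| k | 200 | neighborhood size in expression space |
| n_shuffles | 10 | null rescoring rounds for the seed FDR |
| seed_fdr | 0.001 | FDR threshold for seed selection |
| alpha | 0.75 | profile correlation gate during generalization |
| gamma | 0.75 | profile correlation gate for redundancy |
| max_len | 9 (≤ 15) | motif length cap during elongation |
| min_overlap | 4 | sequence-overlap gate for redundancy |
| criterion | mutual_information | or hypergeometric |
| metric | euclidean | or pearson |
| strands | both | or forward (e.g. 3'UTR analyses) |
| heatmap_bins | 25 | expression-level bins per condition |

One master seed derives per-stage seeds (graph sampling, shuffles,
k-means) by fixed offsets, so a manifest reproduces a run bit for bit.

## Synthetic data

The generator emulates two features of real discovery inputs: smooth
low-dimensional expression structure (unit-amplitude sinusoids with
gene-specific phases over one full cycle, plus Gaussian noise with sd 0.3
by default — a periodic trajectory whose first two principal components
carry nearly all variance; Gaussian blobs as an alternative), and i.i.d.
background sequence of configurable composition up to strongly A+T-rich
regimes.  A planted motif is expression-localized: genes whose profile
lies within a radius of a focal profile (the radius set as the distance
quantile holding a chosen fraction of genes) receive one occurrence with
probability p_inside, others with p_outside; the planted word is drawn
uniformly from the motif's expansion, the position uniformly among windows
not overlapping a previous plant, so every recorded plant remains findable
by the scanner.  Background may still contain chance occurrences, and the
truth object distinguishes planted from background hits — this matters for
realistic FDR behavior at high A+T.

What the generator does **not** emulate: positional biases of real REs,
dependence between neighboring bases (repeats, low-complexity tracts),
occurrence-count effects, paralogy, and cross-species conservation.
Passing the recovery tests therefore shows the machinery is correct and
sensitive under the stated noise model, not that any particular genome
will yield the same motif counts.

## Validation protocol sizes

The reference protocols in `motifdens.benchmark` (used by both the test
suite and `scripts/acceptance.py`) run at these sizes, chosen to exercise
the default parameters (k = 200 requires ≥ 201 genes) while staying
desk-scale:

* planted recovery: 1,000 genes × 24 periodic conditions, 600 bp at 60%
  A+T, planted pair WAGACAA = {AAGACAA, TAGACAA} with p_inside = 0.7 in a
  focal region holding ~20% of genes, p_outside = 0.05, defaults
  otherwise;
* null FDR behavior: 20 independent unplanted fixtures of the same size,
  reporting the pooled fraction of q-mers passing FDR < 0.001.  With a
  10-round shuffle null the estimator gives FDR = 0 whenever the top
  observed score beats every null score, which happens with probability
  ≈ 1/11 on null data by exchangeability — so individual runs can report a
  stray seed and the meaningful quantity is the pooled q-mer fraction;
* hubness: 500 genes × 100 i.i.d. Gaussian dimensions, k = 50 (k/n
  comparable to using k = 200 on genome-scale datasets), mean in-degree
  skewness over 20 replicates before and after balancing.

## Known limitations

* Refinement evaluates each candidate by a fresh sequence scan; very
  permissive settings (α near 0, max_len 15) on large inputs cost minutes.
* The per-gene maxima of the continuous hypergeometric criterion are not
  corrected P values and must never be interpreted as such; only the
  shuffle FDR carries significance.
* With few shuffle rounds the FDR estimate at the very top of the score
  range is coarse (granularity 1/n_shuffles in the numerator).
* When two planted words split the motif's gene set and background
  presence is high, the union motif can score below a single word (the
  global frequency rises faster than the local densities); discovery then
  reports the best-scoring variant rather than the full consensus.  At the
  protocol sizes above the union wins comfortably.
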