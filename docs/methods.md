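# Methods

This note documents the models, conventions and design choices behind
ntnl-forge, in the order the pipeline runs.

## Synthetic genomes and planted ground truth

The simulator (`synthdata`) is first-class, tested code, not a fixture.
It emulates the inputs of a multi-genome nTNL survey: multi-chromosome
nucleotide FASTA with configurable background G+C, GFF3 gene models
(gene/mRNA/exon/CDS; one mRNA per gene; minus-strand genes stored as the
reverse complement, exons listed in ascending genomic order), protein and
CDS FASTA, a truth table, and a replicate-structured expression matrix.
Identical spec + seed gives byte-identical files.

**Planted motif words.** Real NLR motifs are profile-level objects; here
each is realised as a fixed consensus word recognised by the package's
own detectors: P-loop `GGVGKTT`, Kinase-2 `LLVLDDVD` (or `…W`), GLPL
`GLPLAL`, TIR `FDAFISHA`, RPW8 `WEALVKEV`, BED `CxxC…CxxH` with a
10-residue spacer, LRR as ≥ 4 `LAALAALAA` frames, coiled-coil as 4
`LAALAAA` heptads. The truth table is therefore exact by construction:
whatever the detectors define as a motif is what the generator plants.

**Motif-safe filler.** Residues between and around planted spans are
drawn uniformly from {A, D, E, G, H, K, N, P, Q, R, S, W, Y}. This
alphabet excludes L, I, V, M, C, F and T, chosen so that for every
fixed-pattern detector the number of pattern positions a filler-only
window could possibly match is *strictly below* the acceptance threshold
at the default 2-mismatch tolerance (e.g. the P-loop needs 5 of 7 fixed
positions; filler can supply at most the four G/K positions), and the
LRR/CC structural detectors can never fire (no leucines or hydrophobic
a/d residues). Background false positives are thus structurally
impossible rather than merely improbable — a stronger guarantee than a
local guard band, and what makes "background-only proteins yield zero
hits" an assertable invariant.

**Reverse translation.** `reverse_translate` first draws synonymous
codons with binomial weights b^g (1−b)^(3−g) toward the G+C target b,
then greedily switches codons until the total G+C count is as close to
the target as the amino-acid sequence allows. The amino-acid composition
caps the reachable range (≈ 0.28–0.69 for filler-typical sequences), so
extreme targets saturate at the composition limit; at the 0.7 target
used in tests the realised G+C lands within 0.05.

**Pseudogenes.** A planted premature stop is a `*` residue between the
GLPL and LRR spans, reverse-translated to a stop codon; `translate`
keeps internal stops, so the emitted protein carries the `*` the
pseudogene filter looks for. Synthetic CDS exclude the natural terminal
stop codon, so translate(CDS) equals the emitted protein exactly.

**Expression.** Per-gene log2 baseline ~ N(5, 0.5); planted "high" genes
are shifted +3 log2 units; each replicate adds N(0, noise_sd) noise
(default 0.3) and values are exported as 2^x. The baseline spread of 0.5
log2 units between genes is deliberately modest relative to the +3
shift: "highly expressed" models a clear induction signal, not the upper
tail of baseline variation. What the generator does **not** emulate:
probe-level effects, condition-specific induction profiles,
heteroscedastic counting noise, or missing probes — so recovery results
on synthetic data say nothing about probe matching or normalisation on
real arrays, only about the summarisation and categorisation logic.

**Default study bed.** 60 genes on 4 chromosomes (a fifth, chr5, is
empty by design): 50 keepers covering each of the 12 subgroups at least
four times, plus 4 TIR genes, 3 pseudogenes and 3 NB-ARC-less genes.
Start-to-start gaps cycle 70/70/70/250 kb, planting known clusters under
the 200-kb rule. Chromosomes are desk-scale (≤ 3 Mb) on purpose; the
pipeline's logic is size-independent.

## Profile search

The search model is a gapless position-specific scoring matrix in bits:
column score log2(((count + κ)/(n + 20κ))/bg) with pseudocount κ = 1 and
uniform background 1/20 by default; alignment columns with ≥ 50% gaps
are dropped. It deliberately has no insert/delete states — the contract
of interest is the two-threshold, two-pass retention logic, not
profile-HMM internals — and its significance calibration is empirical: a
hit's e-value is the fraction of within-sequence shuffles whose own best
window scores at least as high, times the number of proteins scanned.
This preserves expectation semantics per database while staying fully
self-contained and testable.

**Two-pass protocol.** Pass 1 retains e < 0.05 against the seed profile.
Retained sequences are then domain-verified — a complete NB-ARC (P-loop,
Kinase-2, GLPL in order) per the detectors — before their best-hit
windows are stacked, ungapped, into a genome-specific profile; pass 2
rescans everything and retains e < 0.001. The verification step matters:
with a few hundred decoys, a background sequence occasionally beats all
of its shuffles by chance (the minimum resolvable empirical p is
1/(n_decoys)); without verification its window would enter the rebuilt
profile and reinforce itself in pass 2. The rebuild is ungapped window
stacking rather than a full realignment of pass-1 hits; with the
equal-length NB-ARC cores the seed alignments provide, the two are
equivalent.

## Classification

Order of decisions per gene: TIR present → rejected (TNL) regardless of
other domains; NB-ARC incomplete → rejected; core motifs out of N→C
order → rejected; stop codon before the LRR start (or any internal stop
when no LRR exists) → rejected as pseudogene; otherwise kept and
labelled. LRR-less genes are **kept** and labelled in the N/CN/RN/BN
families — the reference accounting retains such genes — though a
`require_lrr` switch can reject them. The subgroup label is the product
{∅, C, R, RC, B, BC} × {N, NL} over (RPW8?, BED?, CC?) and LRR, yielding
exactly 12 classes; RPW8 + BED together has no defined class and raises.

**Kinase-2 terminal residue.** The literature's convention is
inconsistent about which of …DDVD/…DDVW marks TNL vs non-TNL. The
default here follows the identification protocol (DDVD confirms nTNL;
DDVW flags TNL-type); the mapping is an explicit argument, and a
TNL-type Kinase-2 in a TIR-less protein is flagged in the call's
reasons, not auto-rejected.

## Clustering

"200-kb sliding window" is interpreted as single-linkage chaining:
adjacent genes (coordinate order) are linked when their start-to-start
gap is ≤ 200 000 bp, boundary inclusive; maximal chains of ≥ 2 genes are
clusters. An end-to-start gap mode is available. The interpretation is
oracle-checked against a brute-force transitive closure in the tests.
Summaries round percentages half-up to integers and averages half-up to
2 decimals, always computed **from the counts**. Two published table
cells contradict their own printed counts (29/52 prints as 58% rather
than 56%; 74/29 prints as 2.64 rather than 2.55) and a few percent cells
appear floor-rounded; the summarizer does not reproduce those cells, and
the tests assert the two contradictory ones disagree.

## Ka/Ks (NG86)

Site counting: for each sense codon, each of the nine single-nucleotide
neighbours is classified synonymous or nonsynonymous by the standard
code; the codon's synonymous-site fraction is syn/3, and the fractions
sum to 3. Neighbours that are stop codons count as nonsynonymous.
Differences: each differing codon pair is decomposed over the minimal
mutational pathways (≤ 3! orderings) with equal weighting; pathways
passing through a stop codon are excluded, and in the rare case every
pathway is blocked, all are used with stop-crossing steps counted
nonsynonymous. S and N are averaged over the two sequences; p = D/Sites;
K = −¾ ln(1 − 4p/3). Ks is reported as NA (never ∞) when ps ≥ ¾ or S =
0; the ratio is NA when either distance is NA or Ks = 0. Subclade
summaries take all C(n,2) pairs, excluding NA pairs from min/max/mean
and counting them. These conventions match common NG86 practice except
the stop-pathway exclusion, where some implementations average over all
pathways — the tests pin the difference explicitly.

Family simulation for selection-direction checks accepts proposed
single-nucleotide mutations with probability 1 (synonymous) vs 0.2
(nonsynonymous) for purifying pressure, and ⅓ vs 1 for diversifying;
stop-creating proposals are always discarded.

## Expression summarisation

Per condition: mean over replicates, then log2(mean + 1) (the +1
pseudocount keeps zeros finite). A gene's category comes from its grand
mean ranked against the quantiles of all genes: strictly above the 0.9
quantile → high, strictly below the 0.1 quantile → basal, else mid; the
strict inequalities make a degenerate all-equal matrix uniformly mid.
The quantile thresholds are explicit parameters because "highly
expressed" and "basal" are verbal, not numeric, in the source protocol.

## Numerical and procedural choices

- Tie-breaks: leftmost best offset in profile scans; leftmost-first
  merging of overlapping fixed-pattern hits; mergesort (stable) for
  report row ordering.
- Seeds: one pipeline seed fans out to per-stage seeds by fixed offsets;
  per-protein decoy seeds are spawned from a `SeedSequence` in sorted-id
  order, so results are independent of dict iteration order.
- Degenerate inputs: empty proteome → empty retention with a warning;
  protein shorter than the profile → no-hit with e-value +∞; empty gene
  group → (0, 0, 0.0) exon stats; zero kept genes is a summarisation
  error (division by zero is refused, not silently zeroed).
- Problem sizes: the default study bed (60 genes, ≤ 3 Mb chromosomes,
  200 decoys per scan) keeps a full pipeline run under ten seconds while
  exercising every subgroup and rejection path; the oracle-equivalence
  suites use 200 CDS pairs and 500 random cluster layouts.

## Known limitations

- The profile model is gapless; indel-rich NB-ARC variants that a true
  profile HMM would align are outside the detectors' reach.
- Fixed-pattern detectors with small mismatch budgets are a synthetic
  stand-in for profile-based domain calls; on real proteomes they would
  miss diverged motifs, and results on synthetic data quantify the
  pipeline's logic, not real-proteome sensitivity.
- Empirical e-values have resolution 1/n_decoys; thresholds far below
  that (e.g. 0.001 with 200 decoys and a small database) effectively
  require a score above every decoy.
- Clade assignment (CNL-A…D) is consumed from an external column, never
  inferred: tree building is out of scope.
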