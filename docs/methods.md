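# Methods

This note documents the models and procedures implemented in `baculoscan`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Coordinate conventions

Baculovirus genome maps are circular and, by convention, numbered from the A
of the polyhedrin (*polh*) start codon (position 1), with the *polh* strand
defining the "clockwise" direction. All coordinates in the package are
1-based and inclusive, so an interval 118,740–118,895 spans 156 bp. On
circular records an interval with `start > end` wraps through the origin.
Conversion to and from 0-based half-open coordinates happens only at I/O
boundaries (Biopython `SeqFeature` locations). Residues outside {A,C,G,T}
are normalized to N at read time, and N's are excluded from GC/AT
denominators so composition reflects called bases only.

## ORF cataloguing

An ORF is a maximal start-to-stop reading frame: the first ATG after the
previous in-frame stop, through the next in-frame stop (inclusive of the
stop codon). Both strands and all six frames are scanned; on circular
genomes a doubled-sequence walk finds ORFs that wrap through the origin,
recording each once with its true maximal start. The default threshold is
50 translated residues (`aa_length = span/3 − 1`, the stop codon counts in
the span but not the protein) with ATG-only starts — the common annotation
convention for baculovirus genomes, where published catalogues are built
from ~50-aa ORF calls plus curation. Only the maximal ORF per (frame, stop)
is kept, matching standard ORF-finder behaviour; nested or alternative
starts are not reported.

Catalogue statistics follow the field's reporting conventions: orientation
counts relative to the *polh* strand with the ratio quoted as
anticlockwise:clockwise rounded to two decimals; overlap statistics count
an ORF as overlapping when it shares ≥ 1 bp with any other ORF on either
strand (circular adjacency included), with amino-acid overlap reported as
`floor(overlap_bp / 3)`; genome density is ORFs per kb.

## hr detection and degenerate consensus

Homologous regions (hrs) are clusters of imperfect ~30-bp palindromes that
serve as replication origins and transcriptional enhancers. Detection is
windowed palindromicity: a window of length L is a hit when at most
`max_mismatch` of its (i, L+1−i) base pairs fail Watson–Crick
complementarity. Mismatches are counted **per pair**, not per base — a
single substitution breaks exactly one pair. Defaults are `word_length=30`,
`max_mismatch=3` (12 of 15 pairs complementary), chosen to recover
AcMNPV-style hr repeats that typically carry one to three imperfect pairs.
Overlapping windows merge to the best-scoring one (fewest mismatched pairs,
ties to the leftmost). The scan is linear on the rotated map; a repeat
straddling the origin of a *polh*-anchored map would be missed, which does
not arise in practice because hrs are interior features.

Hits cluster into hr regions when consecutive hits are ≤ `max_gap=500` bp
apart; `min_repeats=1` keeps single-repeat regions, which occur in real
genomes. The genome fraction attributed to hrs uses summed **repeat** bp
(not whole-region spans), so inter-repeat spacer does not inflate the
figure — 30 repeats × 30 bp on a 125,477-bp genome is 0.717%.

The consensus motif is a per-column IUPAC degenerate code over the
(equal-length, ungapped) repeats: a base enters a column's code when its
frequency reaches `inclusion_threshold=0.125`, and the majority base is
always included. The low threshold admits any base clearly above noise, so
rare variants widen the code instead of vanishing. Conservation is
summarized as the number of unambiguous positions (codes in {A,C,G,T}) —
e.g. a 30-nt consensus with 7 degenerate codes has 23 invariant positions —
and, separately, the number of complement-compatible pairs: pair (i, L+1−i)
is compatible when some base allowed at i can pair with some base allowed
at the mirror position.

## CNE scan

The conserved non-coding element (CNE) of alphabaculoviruses is a ~156-bp
element with seven conserved nucleotide clusters (C1–C7) arranged in three
dyad-symmetry elements (DSl/DSc/DSr), each carrying an inverted repeat. The
scanner locates the best infix alignment of a reference CNE against both
strands (edlib, extended CIGAR; identity = matched columns over alignment
columns) and reports a match at ≥ `min_identity=80%`. Cluster presence is
then checked by exact/1-mismatch submotif search inside the match, and the
DS/IR architecture is reported from the packaged annotation; structure
detection is informative, not required for a match. The packaged reference
CNE is a **synthetic stand-in** constructed with the canonical C1–C7/DS/IR
architecture (see `data/cne_reference_synthetic.fasta`); users comparing
against a real genome should supply that genome's CNE as the reference.

## Ortholog mapping and comparative statistics

Orthologs between two ORF catalogues are reciprocal best hits (RBH) under
global protein alignment (BLOSUM62, gap open −10, extend −0.5, Biopython
`PairwiseAligner`). Identity uses **all alignment columns** including gap
columns as the denominator, so length differences count against identity;
this is a documented choice, since percent-identity denominators vary
between tools. A shared 5-mer prefilter keeps only the top 10 candidate
subjects per query before dynamic programming, which keeps an all-vs-all
comparison of two ~150-ORF proteomes under a minute on one CPU. Best-hit
ties break on higher identity, then lower subject catalogue rank
(deterministic); a runner-up sharing the best score is recorded as a
possible gene fusion. `min_identity=25%` drops incidental low-identity
pairs by default and can be lowered to retain weak homologues.

Comparison reports give the shared-ORF count, unweighted mean identity,
gene-parity points (1-based catalogue ranks of each pair; a diagonal
indicates collinearity) and per-pair amino-acid length differences
(query − subject).

The in silico RFLP digests the genome at a recognition site (default BamHI,
GGATCC); on circular genomes fragments run between successive cut positions
and wrap once, so fragment lengths always sum to the genome length, and an
uncut circle yields one full-length fragment. Palindromic sites are
searched on one strand; non-palindromic sites also as their reverse
complement. IUPAC codes in the site are expanded before matching.

## K2P distances, demarcation, and trees

The Kimura 2-parameter distance separates transition (P) and transversion
(Q) proportions and corrects for multiple hits:

    d = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)]

Columns with gaps or ambiguous bases are excluded pairwise (pairwise
deletion), which maximizes usable sites on ragged alignments. When
(1 − 2P − Q) ≤ 0 or (1 − 2Q) ≤ 0 the correction is undefined and a
saturation error is raised. The standard error comes from the delta-method
variance (c₁ = 1/(1−2P−Q), c₂ = 1/(1−2Q), c₃ = (c₁+c₂)/2):
V(d) = [c₁²P + c₃²Q − (c₁P + c₃Q)²]/n.

Species demarcation follows the paired-distance rule used in baculovirus
taxonomy on *polh*/*lef-8*/*lef-9*: pairwise distance < 0.015
substitutions/site indicates the same species, > 0.050 a distinct species,
and the band between is ambiguous. The overall verdict uses the
concatenated three-gene distance; per-gene verdicts are reported for
transparency. Both thresholds are configurable; 0.050 is the conventional
upper bound from the published demarcation criteria. A saturated distance
classifies as distinct with a flag, since divergence beyond the correctable
range can only mean a distinct species.

Trees are classic neighbor joining — chosen over maximum-likelihood search
as a deterministic, desk-scale method sufficient for topology-level claims;
this is a deliberate method substitution, documented here. Q-criterion ties
break on the smallest index pair; negative branch lengths are clamped to
zero with the deficit moved to the sister branch, preserving the pair's
summed length; the final three lineages join at an unrooted trifurcation
via the three-point formulas. On additive matrices NJ recovers the
generating tree exactly (tested against an independent path-length oracle
and cross-checked against scikit-bio's implementation). Bootstrap support
resamples alignment columns with replacement (amino-acid columns for
core-gene supermatrices), rebuilds the NJ tree per replicate, and reports
the percentage of replicates containing each internal bipartition of the
full-data tree; it is deterministic under a fixed seed and invariant to
taxon order (taxa are sorted internally). Core-gene supermatrices
concatenate per-taxon aligned genes in a canonical list order, recording
per-gene boundaries; a missing gene is an error unless the gap-fill policy
is requested. A simple global aligner is available for convenience but
alignment is normally the caller's responsibility.

## Synthetic genomes and what passing tests show

The generator emulates the structure of an alphabaculovirus genome: a
circular, AT-rich (default 60% AT) sequence at study scale (125,477 bp)
carrying 144 planted ORFs — 70 clockwise / 74 anticlockwise, four
opposite-strand overlapping pairs (largest overlap 158 bp) and one ORF
wrapping the origin — eight hr clusters of 8/7/5/4/3/1/1/1 copies of a
shared 30-bp near-palindrome with 0–2 substitutions per copy (30 repeats
total), and one CNE copy carrying 6 substitutions (~96.2% identity). These
defaults are the package's study conditions; smaller layouts are available
for unit testing.

Ground truth is exact by construction: each planted ORF carries an
in-frame guard stop immediately upstream so its ATG is the true maximal
start, and after assembly the genome is repaired so that *only* the planted
features satisfy the detection criteria — spurious stop-free runs are
broken by single-codon edits and spurious near-palindromic windows by
single-base edits, never touching fixed (planted) bases and never
introducing a stop into a planted reading frame; repair edits are frozen so
later repairs cannot undo them. Overlapping ORF pairs are realized by a
constraint solver that keeps both reading frames stop-free across the
shared span. The repair loop uses the package's own detectors, whose
correctness is established independently against brute-force oracles.

Two mutation models drive the tests: a single-hit per-site
transition/transversion mutator with exactly bookkept realized P and Q
(used for identity and ortholog-recovery tests), and a continuous-time K2P
event simulator (Poisson events per site, multiple hits and
back-substitutions included) whose bookkept events/site is the realized
divergence that the K2P estimator should recover.

What the generator does **not** emulate: real promoter/UTR structure,
direct-repeat flanks around hr palindromes, codon usage bias, gene content
homology (planted ORFs are random-codon bodies, so ortholog tests mutate
the same catalogue rather than compare two independently generated
genomes), sequencing error, and assembly artifacts. Passing recovery tests
therefore certify the detectors' coordinate arithmetic, scanning logic and
statistics on genomes with known answers — not annotation accuracy on real
sequence, where start-codon choice and gene boundaries require homology
evidence and curation.

## Numerical choices and problem sizes

All randomness flows through seeded NumPy generators passed explicitly; no
global state. Identity and fraction figures are percentages in [0, 100];
distances are substitutions/site. The test suite and the acceptance script
run at desk scale: one 125-kb study-scale genome, 100 random additive
matrices (n ≤ 8) for NJ, 100 random 2–6-kb circles for RFLP, 10-kb pairs
over 20 seeds for distance recovery — sizes chosen so the full suite
completes in well under a minute of compute while exercising every code
path, including origin-wrapping features.

## Known limitations

- ORF prediction thresholds are conventions, not inference; reproducing a
  published catalogue exactly requires the same (usually unstated) criteria
  and curation.
- The palindrome scanner does not scan windows across the map origin.
- RBH yields one-to-one mappings; fused genes surface only as a runner-up
  annotation, not as one-to-many pairs.
- NJ is a distance method; very unequal rates across lineages can mislead
  it where likelihood methods would not.
- The packaged CNE reference is synthetic; cluster coordinates are
  meaningful relative to that reference only.
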