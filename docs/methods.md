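# Methods

## Annotation model and interval accounting

Coordinates are 1-based inclusive, matching GenBank and the published
feature tables. A feature is a (name, type, start, end, strand) tuple with
optional codon metadata; the genome is circular, and wrap-around features
are supported via explicit flagging (neither study genome wraps — the
D-loop ends exactly at the last position). The signed spacer between
adjacent features is `start(B) − end(A) − 1`: negative values are
overlaps, zero abutting, positive intergenic nucleotides (IGNs). The
closing pair (last feature → first) is included on circular genomes, with
the nearest signed representative on the circle.

The origin of light-strand replication (OL) and the D-loop participate in
spacer accounting exactly like genes: the published tables assign them
intergenic values, and the printed overlap totals (38 bp/13 pairs for
*B. sangzhiensis*, 44 bp/14 pairs for *B. tuberogranulata*) are reached
only when they are counted. Two inconsistencies in the source tables are
handled by trusting coordinates: the *B. tuberogranulata* IGN column sums
to 33 bp over 10 locations (the text prints 32), and its 16S is 1594 bp
by coordinates (the text prints 1595). The package always reports the
value computed from coordinates.

Strict validation requires the canonical 37-feature vertebrate complement
(13 PCGs, 22 tRNAs, 2 rRNAs, 1 control region), in-range coordinates and
codon metadata on every PCG; lenient validation checks coordinates only.

## Composition and skew

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C). A skew whose denominator is
zero is reported as undefined, never as zero. N bases are excluded from
both numerators and denominators. Report output rounds percentages
half-up to 2 decimals and skews to 3, matching the precision of the
published tables.

Per-region rows are computed on the **heavy strand** even for
light-strand genes. This is the convention that makes ND6 — the one
L-strand PCG — show a strongly positive heavy-strand GC skew while every
other gene is negative; computing on coding strands would erase exactly
the pattern the analysis is about.

Codon-position rows are computed per gene on the coding strand and
pooled: position = frame index 1/2/3, and genes with incomplete stop
codons contribute their trailing 1–2 nt to positions 1 (and 2). For
*B. sangzhiensis* this yields position totals 3795/3793/3790 (sum 11,378).
The corresponding published splits (3795/3795/3788) cannot be derived
from any straightforward per-gene frame assignment; the package reports
its own derivation and the difference is documented rather than chased.

A caveat on recomputing published skews from published percentages: the
printed skews were evidently computed from unrounded base counts, so four
of the 58 skew cells sit across a 3rd-decimal rounding boundary (worst
absolute difference 0.00053). Agreement is therefore asserted to one unit
in the last printed place.

## Codon analysis

The genetic code is NCBI translation table 2 (built from Biopython's
table): AGA/AGG/TAA/TAG are stops, TGA is Trp, ATA is Met. The
allowed-start set is {ATG, ATA, ATT, ATC, GTG, TTG} — all non-ATG starts
observed in the study tables are in this set; anything else is a warning,
not an error. Stop classification: a CDS whose length is divisible by 3
must end in a stop codon; otherwise the trailing 1–2 nt must be T/TA, the
incomplete stops completed to TAA by polyadenylation, rendered as
T(AA)/TA(A) in reports.

RSCU(c) = k·n_c / Σ counts over the k synonymous codons of c's amino
acid. Terminal complete stop codons and trailing incomplete codons are
excluded from counting (standard practice; whether the original analysis
included terminal stops is not stated, so the choice is flagged here).
Amino acids with zero total yield RSCU 0 for all their codons and are
flagged. DNA is the internal representation; U-for-T substitution happens
only at the report layer.

## Ka/Ks (Nei–Gojobori 1986 + Jukes–Cantor)

Per sense codon, each position contributes `(# synonymous single-base
changes)/3` synonymous and `(# nonsynonymous, non-stop changes)/3`
nonsynonymous sites; mutations to stop codons are dropped from both
numerators, so site totals sum to 3 minus the stop-adjusted mass.
Pairwise, codons containing gaps, N or stops are removed (complete
deletion per codon); site counts average the two sequences. Codons
differing at 2–3 positions are resolved by averaging over all orderings
of single steps with equal weights, skipping orderings that pass through
a stop (if every ordering does, all are used). pS = Sd/S and pN = Nd/N
are corrected with d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as
saturated rather than corrected.

Gene-level aggregation defaults to the **ratio of mean Ka to mean Ks**
across all taxon pairs, which stays defined when individual pairs
saturate; mean-of-ratios is available behind a flag since classic tool
outputs do not state which summary they print. The estimator choice
itself (NG86 + JC) is the classic counting method of the tool family the
field uses for this analysis; published per-gene values from other
estimators are therefore approximate anchors, and cross-method claims are
rank-based.

## Supermatrix and trees

Per-gene CDS alignments (gap-free by construction on synthetic data;
externally aligned otherwise) are concatenated into a supermatrix with
per-gene charsets; taxa missing a gene are gap-padded. Exports: relaxed
PHYLIP (names up to 256 chars, space-delimited — chosen over strict
10-char PHYLIP) with a RAxML-style partition file, and NEXUS with DATA +
SETS blocks; optional per-codon-position charsets use stride-3
definitions. Partitioned ML/BI inference is export-only: the sidecar
documents the intended downstream settings (ML bootstrap 1000 replicates;
BI 1.0e7 generations, sampling every 1000, 25% burn-in). Re-implementing
partitioned ML/BI would be out of proportion; the in-house, fully
testable tree stage is distance NJ.

Distances: p, JC69 and K2P closed forms with pairwise deletion of gap/N
columns; saturated corrections are flagged and NJ refuses flagged
matrices unless explicitly allowed. NJ is Saitou–Nei with ties in the Q
criterion broken toward the lowest taxon-index pair; negative branch
lengths are clamped to zero with the deficit moved to the sibling edge.
Bootstrap resamples columns with replacement — within partitions when the
matrix is labelled — rebuilds NJ per replicate, and maps bipartition
frequencies onto the full-data tree. NJ bootstrap percentages are not
numerically comparable to ML/BI supports, so only topology-level claims
(monophyly, RF distance) are asserted anywhere.

Clade checks root the tree at a declared outgroup (the family analysis
uses *Microhyla fissipes*) and test leaf-set equality at the MRCA.

## Synthetic data generator

The generator's default architecture is the *B. sangzhiensis* layout:
exact gene order, strands, lengths and signed spacers, hence the same
16,950 bp circle, 38 bp/13 pair overlap structure and 37 bp/11 location
IGNs. Base composition targets the study genome's heavy strand (A 27.45,
C 26.97, G 14.81, T 30.77 %), giving negative AT and GC skews; the
generated genome recovers the targets within ±2 percentage points
(the deviation comes from excluding stop codons during coding-region
sampling).

Root generation pins every initiation codon and terminator (complete or
truncated) first, then fills PCG bodies codon-by-codon, sampling sense
codons weighted by the composition target subject to any bases already
fixed by an overlapping gene — this is what keeps, e.g., the 10 bp
ATP8/ATP6 and 7 bp ND4L/ND4 overlaps mutually consistent with both
reading frames, as in the real molecule. Remaining positions (tRNAs,
rRNAs, spacers, control region) are drawn i.i.d. from the target. An
architecture whose constraints cannot be satisfied by sense codons
raises a template error.

Evolution along a user-supplied branch-length tree: proposals per branch
are Poisson(branch length × genome length); the proposal kernel is
HKY-flavoured with transition:transversion weight κ (default 4).
Acceptance: initiation/termination positions are immutable;
stop-creating changes are rejected; synonymous changes are accepted;
nonsynonymous changes are accepted with probability min(1, ω_gene), with
sites inside two overlapping PCGs requiring acceptance under both.
tRNA/rRNA/control sites evolve neutrally. All randomness flows from the
single spec seed; identical seeds give byte-identical datasets.

The per-gene ω defaults are anchored to the published per-gene pattern
(ATP8 fastest at 0.246, COI slowest at 0.037, ATP6/ND2/ND4 relatively
fast, COI/COIII/Cytb slow; intermediates interpolated). The accept/reject
ω is a simulation convenience, **not** an NG-model quantity: the realized
Ka/Ks sits systematically below ω (the transition-biased kernel proposes
disproportionately many synonymous changes), so recovery checks are
rank-based — Spearman ρ = 1 over a 4-level ω ladder at 500 codons × 8
taxa — rather than absolute.

What the generator does *not* emulate: indels (alignments are gap-free),
gene rearrangement (none is observed in this family), among-site rate
heterogeneity, and real codon bias beyond composition; passing tests on
synthetic data therefore demonstrate correctness of the accounting,
estimators and tree machinery under the study's regimes, not robustness
to alignment error or model misspecification on real sequences.

The 29-taxon reference topology used for recovery tests mirrors the
family's published structure — two subfamily clades, four genus groups in
one, and two *Boulenophrys* species groups holding the two study species
separately — with invented branch lengths (0.008–0.18 subs/site). At the
~11.4 kb concatenated-PCG depth every internal edge carries ample signal,
which is why exact topology recovery (RF = 0) and ≥95% bootstrap on every
true split are appropriate assertions there.

## Problem sizes and determinism

Default analysis sizes: full-architecture genomes (16.9 kb), 29-taxon
family simulations, 28-taxon ingroup Ka/Ks (378 pairs/gene), 100
bootstrap replicates, 500-codon × 8-taxon rate-recovery panels. The whole
suite and the acceptance script each run in well under a minute on one
CPU. Every stochastic stage takes an explicit seed; the CLI exposes
`--seed` throughout.

## Accession-dependent results

Composition rows, RSCU tables and Ka/Ks values for the 28 real GenBank
mitogenomes require the deposited sequences, which this package does not
download (no network code in the library path). The pipeline accepts any
annotated GenBank flat files; the bundled analyses substitute simulated
datasets with the published tables as inputs and treat published
per-gene Ka/Ks values as rank anchors, which is also how the test suite
exercises those claims.
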