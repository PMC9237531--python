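# Methods

This note documents the models, conventions and numerical choices behind
`ripscan`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and domain model

All residue coordinates are 1-based and inclusive at both ends, matching
the `389-440` style of published domain tables.  A protein is annotated
with one TFFD span and an ordered list of TMD spans; where predictors
disagree and several alternative TMDs are listed, downstream operations
take a *TMD selection policy* whose default is "first listed" (the
alternatives carry no ranking, so any other default would be arbitrary);
`all` is available where a protein-level any-TMD semantics is wanted.
Blank cells (topology, hydrophobicity score, NLS) are explicit unknowns
and are never imputed.  TMD spans shorter than 12 or longer than 40
residues trigger a warning, not an error: single-pass helices are
typically 18–25 residues, but annotation sources do list outliers.

The packaged annotation table (`ripscan/data/atmbtf_table1.tsv`, loaded
by `load_table1_fixture`) covers 52 Arabidopsis MB-TFs with TFFD/TMD
coordinates, topology calls, localisations, PTM counts, helix-breaker
annotations, K/R counts and alternative-transcript counts.  Protein
sequences are not part of the table; fixture-level statistics are
computed from annotation columns alone.  One annotated protein (SCP) has
printed TFFD and TMD spans that overlap by two residues; the topology
classifier applies its strict rule and treats it as overlap-class rather
than second-guessing the printed coordinates.

## Motif model

Motifs are compiled from degenerate notation (literals, `x`, `[SET]`,
`[^SET]`) into per-position residue classes.  Semantics chosen for
conservative calling: `x` matches the unknown residue `X`; literal, set
and complement classes never do.  Reverse-orientation scanning reverses
the token order — proteins have no complement strand, and the purpose of
reverse scanning is direction-agnostic detection of helix-destabilising
motifs, so protease-recognition motifs are scanned forward-only by
default while helix motifs are scanned both ways.  `scan_window` reports
every (possibly overlapping) in-window match; presence/absence collapsing
happens only at the protein level, so positional reports and enrichment
counts come from the same scan.  The two redundant rhomboid cleavage
positions of the `LxLSIxGA` site (after the serine-preceding position
and between G and A) are carried as metadata only.

The per-position match probability under i.i.d. uniform residues is the
product over tokens of |class|/20; the default uniform residue model of
the generator makes this analytic value exact, which is what the
background-rate benchmarks check.

## Windows, charges, topology

* `tmd_plus_flank(k)` is the TMD extended `k` residues both ways;
  `flank_tffd_side(k)` is the `k` residues abutting the TMD on the side
  facing the TFFD, excluding the TMD.  Windows are clipped at sequence
  termini and the *clipped* length feeds every enrichment denominator
  (the correct hypergeometric sampling frame).  For overlap-class
  proteins the TFFD-side flank does not exist; the defined-degenerate
  result is an empty window and dependent tests are skipped with a
  recorded reason.
* Motif scans use the symmetric ±20 window ("the TMD region encompassing
  the 20-residue flanks"); charge profiling uses the TFFD-side flank
  only, at k ∈ {5, 10, 15, 20}.
* Topology: position class C (TMD strictly C-terminal of the TFFD), N
  (strictly N-terminal) or overlap; type I = C-terminus cytosolic,
  type II = N-terminus cytosolic.  The TFFD faces the cytosol iff
  (C, II) or (N, I).  Overlap-class proteins are excluded from feature
  scans: a TMD inside the TFFD cannot be removed by proteolysis without
  destroying the domain, so alternative splicing is the only plausible
  activation route there.
* "Between the TFFD and the TMD" is the open interval between the two
  spans; boundary residues belong to their domains.  A proteolytically
  generated N-terminus counts as RIP-consistent when it lies on the TFFD
  side within 41 residues of the TMD.  Unpositioned PTM records that
  carry a between-domains annotation are accepted for the between-domain
  listing, but for the 41-residue proximity flag only when the whole
  TFFD–TMD gap fits inside 41 residues (conservative: the flag is never
  set on evidence the record cannot support).

## Enrichment statistics

`hypergeom_upper_tail(k, n, K, N)` is P(X ≥ k) drawing n without
replacement from N containing K successes (scipy's survival function;
validated in the test suite against exhaustive subset enumeration for
every configuration with N ≤ 12).  Bonferroni multiplies by the family
size and caps at 1.  The family for residue-level K/R tests is (proteins
tested) × (window sizes) per feature — the most conservative reading
when the original correction family is unstated.  When a background is
only known as a proportion, the test degrades to a binomial tail and the
result is flagged `binomial-proportion`; when a synthetic sample is
disjoint from its background the sample is pooled into the population so
the urn model stays well defined (flagged in `mode`).  Fold enrichment
is reported unrounded and displayed to two decimals.  No FDR control is
offered: the procedure being reproduced uses Bonferroni only.

## TMD similarity tree

TMD peptides are aligned with MAFFT (`--globalpair --maxiterate 0`:
global pairwise alignments, one progressive round, BLOSUM62, affine
gaps).  MAFFT was chosen because the cohort mixes near-identical
families with mutually unrelated TMDs, a regime where guide-tree
estimation from pairwise alignment significance breaks down in simpler
progressive aligners.  Distances between aligned rows are mean
per-column normalized BLOSUM62 dissimilarities,
d(a,b) = 1 − (S(a,b) − S_min)/(max(S(a,a), S(b,b)) − S_min), so
identical residues score 0 and a gap against a residue scores 1
(maximal mismatch; gap–gap scores 0).  Trees are neighbor-joining
(scikit-bio, deterministic for a fixed input); per-replicate alignment
columns are resampled with replacement using RNG substreams spawned
deterministically from one integer seed; the majority-rule (> 50%)
consensus carries supports in percent, and all non-trivial bipartition
frequencies are retained so the support of an arbitrary group can be
queried (`ConsensusTree.support_of`, `best_bipartition`).  Degenerate
input (all rows identical) returns a star tree with an explanatory note.
`clusters_above(tree, t)` reports maximal clades with support > t, the
display rule used for substrate-family candidates (t = 70) and
high-confidence clusters (t = 90).

## Candidate tiers

The tier is a pure function of the evidence flags, versioned as
decision-table 1.0 and deliberately simple:

* `RIP-candidate` = cytosolic TFFD ∧ (protease-site flag ∨ (helix
  breaker in TMD ∧ (K/R in TMD ∨ K/R-enriched flank)));
* `splicing-candidate` = TMD-lacking alternative transcript ∧ no
  protease-site flag;
* `RIP-possible` = any single RIP-consistent evidence flag;
* `uninformative` otherwise.

Protease-site flags are the exact and degenerate S1P sites and the
specific rhomboid sites; the pan-rhomboid minimal consensus is reported
but never used for tiering, since it matches the large majority of TMDs
and has no discriminative value.  NLS presence is reported but does not
veto candidacy (an undiscovered NLS is always possible), and topology is
context rather than evidence: a cytosolic TFFD alone never lifts a
protein above `uninformative`.  Unknown topology caps a protein at
`RIP-possible`.  The table is monotone: removing evidence can move a
protein sideways between the two middle tiers but never upward (checked
exhaustively over the flag lattice).  No probabilistic calibration is
claimed — tiers order evidence, they do not estimate cleavage
probability.

## Function prediction

Per TF, GO-BP terms are tested by the same hypergeometric tail on
(annotated targets) vs (annotated universe genes), Bonferroni-corrected
over the terms actually tested for that TF; terms annotating fewer than
3 universe genes are excluded as noise (configurable).  No GO-graph
propagation is performed beyond direct annotations.  TFs with at least
one enriched term form a binary TF × term matrix clustered with average
linkage on Jaccard distance — appropriate for sparse binary profiles;
identical profiles get distance 0 and merge first.

## Synthetic data: what it emulates, and what it does not

The generator emits i.i.d.-residue proteins (uniform over the 20
residues by default, so analytic match probabilities are exact) with one
planted hydrophobicity-biased TMD (length 18–25, 90% of positions drawn
from AILMFVWC), a TFFD placed N-terminal, C-terminal or overlapping the
TMD with class probabilities 60.3/23.8/15.9% and per-class type-II/
type-I/no-call topology fractions (59.5/21.5/19% for C-class,
26.6/26.6/46.8% for N-class) mirroring the Arabidopsis MB-TF inventory;
the default cohort size is 57, the analysis-set size of that study.
Motifs are written in place at a uniformly chosen legal offset inside
the requested window (TMD, ±k flank, TFFD-side flank, the luminal tail
opposite the TFFD, or the whole sequence), resampling the offset on
collision with previously planted features up to a bounded retry count,
then failing loudly (`SpecError`).  Charge planting first strips
background K/R from the whole TFFD-side flank and then writes exactly
`n_kr` K/R residues into the requested window, so the planted count *is*
the charge composition of every nesting flank window and the truth
record is verifiable against the emitted sequence.  Backgrounds come as
a (proteome, membrane-proteome) pair with controlled motif base-rates;
networks as TF blocks wired to gene blocks (wiring rate 0.8 by default)
with one block GO term each plus noise terms.  Identical spec + seed
reproduce byte-identical FASTA/TSV/JSON outputs.

What passing the synthetic benchmarks shows: the scanner finds exactly
what the degenerate notation defines (oracle agreement), the window
algebra and topology classifier are correct, the enrichment machinery
has calibrated type-I error and detects planted effects, and the tree
recovers planted families.  What it does not show: real TMDs are not
i.i.d. (hydrophobicity gradients, compositional bias), real backgrounds
are not uniform, and real protease specificity is not fully captured by
short degenerate motifs — on real data these tests measure the
procedure, not the biology.

## Problem sizes and numerical choices

Benchmark sizes were chosen to make the statistical claims sharp while
keeping runs interactive: exhaustive hypergeometric enumeration up to
N = 12; scanner/oracle agreement on 1,000 random 200-mers for all 14
catalog patterns in both orientations; background match rates on 10^5
positions against 99% binomial intervals; residue-level null calibration
on 1,000 replicate 5-protein cohorts (5,000 protein-level tests);
two-family tree recovery at 1,000 bootstrap replicates; network block
recovery over 20 replicate networks (400 TF tests).  The
hypergeometric-to-binomial limit is checked at N = 10^7, where the
finite-population correction (≈ n/N relative) is safely below the 10^-6
comparison tolerance.  Ties in NJ joins and in linkage follow the
deterministic behaviour of scikit-bio and scipy on the fixed,
alphabetically sorted input order; p-values are capped at 1 after
correction; empty windows and TFs without targets return explicit
skip/empty results rather than NaNs.

## Known limitations

Tier assignment is heuristic and unvalidated against cleavage assays;
the K/R-flank significance flag on the packaged table is carried from
the source annotation rather than recomputed (recomputing needs the real
background proteomes, which are inputs, not package data); the consensus
tree treats alignment columns as exchangeable (standard bootstrap
assumption) and inherits MAFFT's guide-tree heuristics; and GO
enrichment ignores the GO graph structure and annotation bias.
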