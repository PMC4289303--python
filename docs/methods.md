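# Methods

This note documents the models, rules and numerical choices behind
`trlocus`, and what the simulation-based validation does and does not show.

## Functional-competence model

A V gene is scored on five rules; any violation is recorded as a lesion
with kind, detail and position:

* **Splice sites** — the leader/V intron must begin `GT` and end `AG`
  (`splice_donor` / `splice_acceptor` lesions).
* **Open reading frame** — the leader exon and V exon are conceptually
  spliced and translated in frame 0 from the initiator. Frameshifts are
  detected *relative to the subgroup reference V-exon length modulo 3*, not
  by de-novo ORF search: duplicated pseudogene copies typically share one
  small deletion, and re-finding some other ORF would mask it. A detected
  frameshift suppresses the stop-codon scan and residue checks, whose frame
  is no longer meaningful — this also keeps lesion reports minimal (one
  causal lesion, not its downstream artefacts). Stop codons are otherwise
  reported from a through-translation (`*` characters), so a premature stop
  does not cascade into spurious residue lesions.
* **Conserved residues** — Cys-23, Trp-41 and Cys-104 of the standardised
  V-domain numbering. The positions are located on the candidate
  translation by global peptide alignment (match 2, mismatch −1, gap open
  −5, extend −0.5) against a per-subgroup functional reference peptide
  whose anchor indices are known; a position that cannot be aligned counts
  as the corresponding lesion with detail `unalignable`. Reference peptides
  are supplied by the caller (the simulator provides them for simulated
  subgroups); without a reference, frameshift and residue checks are
  skipped and only sequence-intrinsic rules apply.
* **Recombination signal** — heptamer/spacer/nonamer scoring with explicit
  defaults: invariant `CAC` heptamer start, ≥5/7 identity to `CACAGTG`,
  ≥6/9 to `ACAAAAACC`, spacer length within ±1 of 23 (V) or 12 (J). The
  thresholds are deliberately declared constants rather than a position
  weight matrix: they make every call reproducible and testable, at the
  cost of ignoring graded RS quality.
* **Location** — genes mapping neither to the locus chromosome nor to an
  unassigned contig get an `unmapped_location` lesion.

Status aggregation: any missing part sequence (contig break) ⇒
**incomplete**, which outranks pseudogene because such genes cannot be
assessed; otherwise any lesion ⇒ **pseudogene**; otherwise **functional**.
J genes are functional iff the reading frame retains F-G-x-G with no
internal stop, the 12-RS passes, and the 3′ splice donor is `GT`.

Catalog summaries report per-subgroup total/functional/pseudogene/
incomplete counts with percent functional computed over the *full*
subgroup size (incomplete genes included in the denominator), one decimal.

## Identity, subgroups and naming

p-distance is the uncorrected proportion of differing sites after pairwise
deletion (columns with a gap in either sequence are excluded; zero
comparable sites is an error, not 0). All-pairs identity uses per-pair
global alignment (match +1, mismatch −1, gap open −4, extend −1) rather
than one multiple alignment: deterministic, order-independent and
self-contained, at the cost of non-transitive alignment columns —
acceptable because only pairwise identities are consumed downstream.

Subgroup clustering takes connected components of the "identity ≥ 0.75"
graph. The convention is known to be violated in heavily expanded
subgroups, so the clusterer *reports* rather than adjudicates: each cluster
lists within-cluster pairs below threshold (reachable transitively) and
cross-cluster pairs within two percentage points of threshold.

Orthology naming: a cluster takes a reference subgroup's name when its
mean identity to that subgroup's sequences is maximal and ≥0.631 (the
empirical lower bound of cross-species orthologue identity, exposed in
config) and, when a joint rooted tree is supplied, the cluster is
monophyletic with that reference. Otherwise alphabetic designations
(X, Y, …) are issued in genomic order of each cluster's first member.
Conflicting claims on one reference go to the higher mean identity; both
claims are reported.

## Phylogeny

Neighbour joining minimises the standard Q-criterion with the lowest-index
pair as tie-break, yielding identical trees across runs and platforms. The
unrooted result keeps a trifurcating root (n = 2 splits the single edge
equally — NJ is undefined there and a convention is required). Negative
branch estimates are clamped to zero for display with the raw value
retained on the node. On additive matrices NJ recovers topology and branch
lengths exactly; the test suite verifies this against full least-squares
topology enumeration to six leaves and by exact path-matrix recovery to
twelve, plus an independent library implementation.

Bootstrap support resamples alignment columns with replacement, rebuilds
the tree per replicate, and reports the percentage of replicates containing
each original bipartition; all resampling flows from one seed. Outgroup
rooting places the root at the midpoint of the outgroup's pendant edge and
preserves all leaf-to-leaf path lengths. Phylogenetic groups are defined
operationally by user-supplied anchor leaves: each group is the smallest
rooted clade containing all its anchors; overlapping or nested anchor
clades raise a structured conflict; leaves in no anchor clade stay
unassigned. UPGMA and an NNI hill-climb under the OLS total-length
(minimum-evolution) criterion are provided behind the same interface as
robustness checks only.

## Homology units

Unit detection is symbolic, on subgroup-label strings in genomic order
(strand recorded but ignored for matching; unassigned genes become unique
never-matching tokens). Three design choices matter:

1. **Maximal repeats, primitive period.** All maximal exact repeated label
   subsequences are found (occurrences not all extendable by one identical
   label on either side). A tandem array `(w)^k` yields maximal repeats
   that are multi-period concatenations of `w`; these are reduced to the
   primitive period so the array is reported as *k* replicons of the unit
   motif, matching how replicon counts are tabulated for tandem arrays.
2. **Composite replicons.** Exact repeats fragment wherever one replicon
   gained or lost a gene. Instances of different motifs that overlap in
   the gene order are merged into composite candidate replicons; abutting
   fragments merge only when their motifs overlap elsewhere in the locus
   (evidence they are pieces of the same unit). Tandem copies of a single
   motif abut but never merge, so arrays are not collapsed.
3. **Edit-distance clustering.** Composite label strings cluster greedily
   (most frequent string first) with radius `min(merge_edit_distance,
   len(consensus)//2)`; the cap prevents short motifs with disjoint labels
   from merging at the default distance of 2. Clusters need ≥2 replicons
   and ≥`min_motif_genes` labels. Instances align to the consensus by
   label-level Needleman–Wunsch; edge gaps flag `variable_content`
   (variable 5′/3′ replication extent), internal gaps or insertions flag
   `post_replication_indel`.

Occurrences resolve greedily to leftmost non-overlapping instances — the
deterministic analogue of rationalising replicon counts to a minimum.
Coverage counts each gene once even under overlapping units. The k-mer
dotplot (exact seeds chained along diagonals, both strands, configurable
word size ≥8 and minimum run) is confirmatory; it never defines units.

## Expressed-repertoire matching

Percent identity comes from the same global alignment under pairwise
deletion; equal-length inputs shortcut to positionwise comparison (the
gap-open penalty of −4 makes gaps unprofitable at the small divergences
involved). Categories: exactly 100% ⇒ `identical`; ≥97.0% ⇒
`allelic_or_unassembled` (the boundary is inclusive here — a convention
must be fixed, and the published middle class starts at 97.0); <97% ⇒
`novel`, i.e. most likely a gene absent from the assembly. The middle
class is not capped at 99.5%: the published upper value is an observed
maximum, not a rule. Trichotomy summaries first deduplicate by exact
V-segment nucleotide sequence. Ties on best hit go to the gene earliest in
catalog (genomic) order. Usage frequencies are computed over productive
transcripts of a chain, each taking its best hit's subgroup;
representation bias is the expressed/genomic percentage ratio with
configurable over/under thresholds (2× and 0.5×); dual usage is the set
intersection of subgroups with ≥1 productive transcript per chain.

## Simulator: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume,
scaled to desk size. Ancestral subgroups are independent random gene
templates, functional by construction (fixed initiator, splice dinucleotides,
anchor codons and RS consensus; all template and copy mutations avoid
those sites and never create stop codons). The default configuration —
chosen once as the study conditions — has 15 subgroups expanded by four
tandem duplications (2-gene unit ×7 replicons, 4-gene ×6, a TRDV1-anchored
3-gene ×5, 2-gene ×3; 63 V genes), subgroup death rates spanning 0–0.85
per duplication (TRDV1-like 0.2, collateral TRAV23-like 0.8), 20 J genes
at death rate 0.16, and transcript sampling of 198 TRA + 143 TRD chains
with an 11% hidden-gene fraction and TRD usage dominated by TRDV1 — each
value mirroring the published locus accounting. Substitutions are uniform
with a 2:1 transition bias; per-copy rate 0.006 keeps within-subgroup
identity far above the 75% convention. Allelic transcript divergence is
drawn uniformly in (0.003, 0.025) and applied as an exact substitution
count clamped to the 3% band, so the allelic category is recoverable by
construction; hidden ("novel") genes are diverged 5–8% and resampled until
below 96.8% identity to every annotated gene — the sub-97% bound is the
*definition* of a gene missing from the assembly, so the generator enforces
it rather than sampling and hoping. Lesions are planted as concrete
sequence edits (stop codons, 1/2/4 bp deletions, splice/anchor/RS
mutations, part truncation), with the expected classifier call recorded at
plant time; planted sites are frozen against later substitution so copies
inherit their ancestor's lesion — which also reproduces the empirical
signature of shared lesions across replicons.

Consequently, passing the recovery tests shows the pipeline is *internally
consistent and exact under its own assumptions*: every planted lesion
recovered, every replicon found, every transcript categorised correctly.
It does **not** show robustness to features real loci have and the
simulator omits: assembly fragmentation across hundreds of contigs,
inverted duplications (supported as data — minus-strand genes — but not
generated by default), non-uniform substitution processes, indel drift in
intergenic DNA, gene conversion, and alleles segregating in the sequenced
individual. The simulator is a test harness, not an evolutionary
inference tool, and its duplication/mutation rates were chosen for test
coverage, not biological realism.

## Numerical and degenerate-input conventions

* All randomness flows from a single integer seed per run; identical
  configuration ⇒ byte-identical outputs (FASTA, GFF3, TSV reports, which
  carry a config digest + seed header).
* Coordinates: 0-based half-open in memory, 1-based inclusive GFF3 on
  disk, converted only in `trlocus.io`; part sequences always in coding
  orientation.
* p-distance with zero comparable sites, empty transcript pools, empty
  catalogs and empty group subsets raise `ValueError` rather than
  returning sentinel values; a genomic share of zero makes a bias ratio
  `undefined` rather than infinite.
* Percentages are rounded to one decimal in reports; the published totals
  row prints 4.8% where 18/371 = 4.85% — counts, not printed roundings,
  are the tested quantities.
* Test problem sizes (63-gene locus, 341 transcripts, ≤12-leaf oracle
  trees, 520-gene lesion batch) were chosen so the full suite exercises
  every rule and recovery property in well under ten minutes on one CPU.

## Known limitations

* Orthology naming requires references aligned into the same sequence
  space and a joint tree for the monophyly condition; without a tree the
  identity floor alone decides, which over-assigns names for borderline
  cross-species matches.
* Composite-replicon merging cannot reconstruct units whose copies never
  co-occur on one contig (composite units spanning contig breaks are
  reported as separate fragments).
* The competence rules are single-haplotype: allele-level functionality
  (one locus carrying both functional and non-functional alleles) is out
  of scope.
* Frameshift detection needs a subgroup reference; novel subgroups with no
  functional member fall back to sequence-intrinsic rules only.
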