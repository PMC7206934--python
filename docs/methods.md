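# Methods

This note documents the models, conventions and numerical choices behind
`cpedit`, and what the synthetic benchmarks do and do not demonstrate.

## Editing-site detection

Plastid C-to-U editing is observed as a C(genome)/T(cDNA) mismatch between
a coding sequence and its transcript. Detection is alignment-based: each
transcript is aligned globally against its CDS and every substitution
column becomes a candidate site.

**Alignment.** Needleman–Wunsch with affine gaps (Gotoh three-state
recurrences), match +2, mismatch −1, gap open −5, gap extend −1; a gap run
of length *g* scores `open + (g−1)·extend`. Transcript/CDS pairs are
near-identical, so the recovered mismatch set is robust to the scheme; the
parameters are exposed (`AlignParams`) for unusual inputs. The row-wise
implementation vectorizes the match and vertical-gap states over columns
and closes the horizontal-gap state with a running maximum, so cost is
O(nm) with numpy-row constants. Determinism: traceback ties prefer
diagonal over up over left, making output unique for any input. The score
is verified in the test suite against two independent routes — exhaustive
enumeration over all alignments for short pairs, and a separately
implemented affine-gap optimal aligner for pairs up to 12 nt.

**Coordinates and typing.** CDS positions are 1-based; codon index
⌈pos/3⌉, codon position ((pos−1) mod 3)+1, matching codon-indexed site
labels such as `ndhB_50SL`. Transcripts are stored as DNA (T, not U);
reports render C→T as "C-to-U". N bases never call an edit and sites whose
flanking base is N are excluded (and counted) in context tallies.
Mismatches other than C↔T are kept with type `other` and flagged in the
run report as possible sequencing error, rather than silently discarded.
Indel columns never produce sites; a site sharing a codon with an indel is
flagged `frame_disrupted`.

**Site labels.** Canonical form `<gene>_<codonIndex><refAA><altAA>`
(silent edits repeat the amino acid; stop gain uses `*`). The parser also
accepts the amino-acid-first order (`ndhA_S159L`), hyphens, and the
separator-free form (`matK426HY`), all of which occur in published tables.

## Consequence classification

Both codons are translated with the bacterial/plastid genetic code (NCBI
table 11, via biopython). Kinds: silent (same residue, not stop), missense,
stop_gain (new internal stop; residues truncated = protein_length −
stop_codon_index + 1, counting the codon that became the stop), start_gain
(ACG→ATG at codon 1, the canonical editing-created AUG initiator),
start_loss_candidate (codon 1 ATG edited away), plus stop_loss and
stop_retained for completeness. Classification is checked exhaustively
against translation over all 64×63 ordered codon pairs.

**Hydropathy classes.** The three-class scheme is a package decision, not a
published standard: hydrophobic {A,V,L,I,M,F,W}, hydrophilic
{R,K,D,E,N,Q,H,P}, neutral {G,S,T,C,Y}. It pins the three anchors the
headline tallies depend on (serine neutral, proline hydrophilic, leucine
hydrophobic) and groups the rest along usual hydropathy lines; it is
overridable (`PropertyScheme`), and no shipped analysis depends on the
unanchored assignments. The per-gene scan for unedited ACG start codons is
descriptive only.

## Sequence context

Context is read from the genomic strand in coding orientation — the only
convention consistent with naming the edited base a C — at distance
`flank` (default 1) on each side, reported in RNA alphabet with joint
(5′,3′) contexts such as `U_A`. Sites within `flank` of a CDS end are
excluded from tallies and surfaced as `n_excluded_boundary`; marginals of
the joint table equal the per-side tables exactly because all are computed
over the same included sites. Windows (default ±15 nt) are '-'-padded at
CDS boundaries; per-column information content is 2 − H bits over
{A,C,G,U} with gaps excluded per column (an all-gap column scores 0).

## Cross-species comparison

Orthologous-site identity is by canonical label (gene, codon index,
amino-acid change); remapping coordinates between genomes is the caller's
responsibility. For a focal species, a site is *shared with a clade* if ≥1
member of that clade (focal excluded) has it, and *unique* if no other
species has it. Because published clade counts sometimes nest (palms
inside monocots) and sometimes do not, `shared_counts` takes an optional
`clade_groups` mapping that states explicitly which labels each reported
clade covers; `shared_between` implements "shared between clades A and B"
as presence in ≥1 member of each. Prediction comparison intersects
predicted and observed sites by (gene, CDS position); precision and recall
are half-up percentages, left undefined (null) rather than 0 when the
corresponding set is empty.

## Locus selection

A column is parsimony-informative iff ≥2 states each occur in ≥2 taxa,
with gaps and N treated as missing (not a fifth state; configurable by
preprocessing). The test suite validates this rule against an exhaustive
oracle that scores every unrooted topology (≤8 taxa) with Fitch counting
and asks whether the minimum-change count discriminates topologies. Genes
are ranked by PIC/aligned-length; selection uses strict `ratio >
threshold` (default 0.3) with an inclusive flag, since published cutoffs
rarely state which. Concatenation takes the union of taxa in first-seen
order, fills missing gene/taxon blocks with '-', and records partitions;
exports are FASTA, relaxed PHYLIP, NEXUS (with charsets) and RAxML-style
partition files, because tree inference proper (ML/Bayesian, model
selection, supports) is intentionally external. The built-in
neighbor-joining tree (uncorrected p-distances, lowest-index tie-break,
negative branch lengths clamped to 0) is a smoke test of exported data,
not an inference result.

## Transmembrane proxy

Editing in plastids skews strongly toward hydrophobic residues, so the
package gauges structural impact with a transparent hydropathy heuristic:
Kyte–Doolittle residue values, centred moving average with window 19
(truncated at the termini; unknown residues contribute 0 with a warning),
segments = maximal runs above 1.6 of length ≥ 15 — the classic
hydropathy-plot defaults. The before/after diff classifies segments as
gained (no overlap in the other map), extended (overlapping but longer
than any overlapped segment), and symmetrically lost/shrunk. This is a
windowed-mean propensity measure; it is not an HMM topology predictor, has
no signal-peptide model, and its interval coordinates should be read
comparatively, not as structure predictions. Thresholded windowed means
are monotone: raising any residue's hydropathy can only grow TM coverage
(property-tested).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Genes** — `n_genes` = 20 CDSs of 100–500 codons (spanning short
  subunits up to ndhB/rpoC1-sized genes), ATG start, body uniform over the
  61 sense codons, single terminal stop, no internal stops.
- **Edits** — `n_edits` = 46 planted C→T substitutions. Codon position is
  drawn from (0.1521, 0.8043, 0.0436) and the 5′U / 3′A context
  requirements from Bernoulli(0.6521) / Bernoulli(0.7391); a "no" draw
  requires a non-U / non-A neighbour, so the planted marginals equal the
  probabilities exactly. Candidates are indexed by (base, codon position,
  5′U, 3′A) and drawn uniformly without replacement; base 1, the last
  base and the terminal stop codon are never edited. If a drawn
  constraint combination has no remaining candidate the generator raises
  (`InfeasibleError`) instead of silently relaxing the constraint, which
  would corrupt calibration tests — large planted-edit counts therefore
  need proportionally many genes (the 2000-site calibration runs use 300
  genes of 200–400 codons, where the scarcest category, TCA codons, is
  comfortably larger than its expected demand). Reverse (U-to-C) edits are
  supported via `p_reverse_edit` (default 0) to exercise the detector's
  typing logic.
- **Species sites** — presence/absence evolves along a user-supplied tree
  as a two-state Markov chain with gain/loss rates; along a branch of
  length t the switch probability is `(r_away/(g+l))·(1−e^{−(g+l)t})`,
  with Bernoulli root states at the stationary frequency g/(g+l) unless
  given explicitly.

**What passing on synthetic data shows — and does not.** The generator
plants binary, indel-free, fully edited sites in clean sequence, so exact
recovery (precision = recall = 1.0) demonstrates the correctness of the
alignment/coordinate/typing machinery, not robustness to real data
artefacts: partial editing, sequencing error, ambiguous bases, splice
variants and real codon-usage bias are all absent. The 5′ and 3′ context
draws are independent, so the planted joint `U_A` frequency is the product
of the marginals (~48%), slightly below what real site tables show —
joint-context dependence is deliberately not modelled. Chloroplast genome
architecture (inverted repeats, introns, operons) is out of scope.

## Reporting conventions

Percentages are rendered half-up to 2 decimals (`decimal`-based, not
banker's rounding); exact fractions are kept alongside in JSON so rounding
never propagates. Published per-position percentages for counts (7, 37, 2)
of 46 differ from exact half-up rounding by 0.01 at two entries; the
package reports the exact values (15.22, 80.43, 4.35) and comparisons
allow ±0.02. Empty summaries report null percentages rather than zeros.
Pipeline reports are deterministic given inputs and config (byte-identical
JSON apart from the timestamp), carry a config hash over semantic fields
only, and aggregate totals that are checked for mutual consistency in the
tests.

## Problem sizes used in the shipped checks

Recovery: 50 independent datasets at default conditions (20 genes, 46
edits). Context calibration: one 300-gene, 2000-edit dataset, 3-binomial-SD
bands. PIC oracle: 1000 random 4–8-taxon columns. Alignment oracle: 500
random pairs ≤12 nt (plus exhaustive enumeration ≤6 nt). Site evolution:
10,000 two-leaf sites plus 20 replicates of a 4-taxon tree.
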