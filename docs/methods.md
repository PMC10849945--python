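# Methods

This note documents the models, conventions and numerical choices behind
`magfams`, and what the synthetic benchmark does and does not demonstrate.

## Conventions

Gene coordinates are 0-based half-open internally; GFF3 I/O converts
to/from the format's 1-based inclusive convention. `rank_on_contig` is the
0-based order of genes along a contig sorted by start (stable on ties).
Taxonomy lineages are ordered 7-tuples (domain … species) of GTDB-style
prefixed strings; the species identity of a genome is its species-rank
string, and clade membership is lineage-prefix consistent. A gene may
carry several KEGG pathway annotations simultaneously.

Filter boundaries follow the quoted rules they implement: database-hit
significance uses strict inequalities (E < threshold, coverage > 50%);
the dN/dS filter keeps the 0.5 boundary ("higher than" is strict); the
small-peptide rule is strictly <50 aa; the ≥80% member-flag aggregation is
inclusive; synapomorphy member count and coverage are strict (>10, >90%)
while specificity is inclusive (≥100% ⇒ =100%); habitat breadth needs
strictly more than 10 samples but at least 2 habitats.

## Curation filters

All family-level filters are independent predicates, so their order only
affects which reason code a doubly-failing family receives, not the
surviving set. The conserved domain is the longest maximal run of
alignment columns whose per-column non-gap fraction is ≥0.8 (ties broken
leftmost). Per-column occupancy was chosen over block-aggregate occupancy
because it is the standard block-trimming semantics and yields contiguous
conserved regions; the occupancy threshold is a parameter. Candidate
selection evaluates the species rule on the complete members only, which
excludes both orphans and fragment-dominated clusters in one pass.

## dN/dS (NG86)

The purifying-selection screen needs only a pass/fail ratio against 0.5,
so a deterministic pairwise counting estimator is used rather than a
tree-aware ML fit: Nei–Gojobori (1986) site counting (each codon position
contributes one site, split by the fraction of non-stop single-nucleotide
changes that are synonymous), pathway averaging over all minimal
mutational orderings for multi-position codon differences (orderings that
pass through a stop get zero weight; if all are blocked the full set is
used), and Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) with p ≥ 3/4
mapped to +∞. Codons containing gaps, ambiguity or stops in either
sequence of a pair are excluded pairwise. The family ratio is the mean
pairwise dN over the mean pairwise dS, with 0/0 → 0 and x/0 → +∞; pairs
with a saturated (infinite) distance are excluded from the means. An
external per-family estimate column can be supplied instead of the
built-in estimator.

A subtlety worth recording: under pathway averaging, dN = 0 is *not*
implied by "every accepted mutation was synonymous". Chains of synonymous
single steps can connect codons that differ at two positions (e.g. the
leucine network CTT↔CTA↔TTA), and half of the minimal pathways between
the endpoints are then non-synonymous. The simulator therefore offers a
`synonymous_only` mode restricted to synonymous third-position changes,
under which every observed codon difference is a single unambiguous
synonymous step and the estimated dN is exactly zero at any divergence;
free ω = 0 evolution is validated by rank ordering only.

## Orthology

Midpoint rooting is delegated to scikit-bio's `root_at_midpoint` (the tree
is carried as a dendropy object; all-zero-length trees keep their existing
deterministic rooting). Duplication detection uses the species-overlap
rule; at multifurcations a node is a duplication if any pair of child
subtrees shares a species. Events are dated at the deepest rank shared by
all species below the node; species spanning both domains date at "root",
which the basal-orthology test always treats as basal. The default basal
rank set is {domain}, configurable to {domain, phylum}.

## Genomic-context predictor

Scores use pooled (gene-level) denominators for relatedness, strand and
distance, and a member-level numerator for synteny; empty windows score 0.
Distance conservation requires every intergenic gap on the chain from the
focal gene to the P-neighbour to be ≤100 nt (negative gaps — overlapping
genes — pass). Windows truncate at contig ends rather than dropping edge
members.

Calibration: for each pathway with ≥5 known families the level-c threshold
of each score is the empirical (1−c)-quantile with lower interpolation —
the largest observed value that at least a fraction c of known P-families
reach. Confidence is discretized to the two benchmark recovery levels
{0.5, 0.9}; the level list is a parameter so intermediate levels can be
added. Pathways with fewer known families are reported as uncalibratable
rather than silently skipped at prediction time.

## Synapomorphy scan

Coverage counts a genome as containing a family if ≥1 member maps to it
(multi-copy presence is not weighted). The scan enumerates only clades the
family actually touches (others have coverage 0 by construction). The
follow-up purge of families with distant remapping hits is represented as
an optional (family, clade) exclusion list, not an internal search.

## Distribution summaries

The LCA with member support s takes, at each rank, the most frequent
extension of the current prefix (ties by name) and stops when its support
drops below s·n over all members; since the greedy choice does not depend
on s, raising s can only truncate the lineage — the monotonicity property
the tests assert. Novelty density reports mean ± sample sd (ddof = 1; 0
for singleton clades) of distinct families per genome, with every genome
in the clade contributing. Rareness bins for the breadth–mobility summary
default to tertiles of sample counts; the Spearman correlation is computed
over unbinned families and degenerate inputs (constant mobility or
breadth) are reported as rho = 0 with a flag.

## Blocked Wilcoxon

Within each block, midranks are computed and the case rank-sum T_b is
compared with its null mean m_b(n_b+1)/2; the variance uses the
tie-corrected finite-population form m_b·k_b/(n_b(n_b−1))·(Σr² − n_b·r̄²).
Blocks with a single condition (or fewer than 2 samples) contribute
nothing. Block statistics are combined with van Elteren's locally-best
weights 1/(n_b+1) (an unweighted option exists, since the exact weighting
of the reference R implementation is not restated anywhere); the p-value
is two-sided normal without continuity correction, which reduces exactly
to the ordinary normal-approximation rank-sum test for a single block
without ties. BH q-values use the standard step-up with clipping at 1.
The effect reported per family is the case-minus-control mean abundance
per informative block, averaged across blocks; prevalence is the fraction
of samples with non-zero abundance, and all-zero families are excluded
from testing. When a colonoscopy column is present it is collapsed into
the block key (block = study × colonoscopy).

## Synthetic benchmark: what it emulates, and what it does not

The generator emulates, under one seed, every input the pipeline consumes.
Defaults define the benchmark conditions and are chosen once:

* **Taxonomy**: balanced 2 domains × 2 phyla × 2 classes × 2 orders × 4
  species × 3 genomes (192 genomes). Two children at every internal rank
  guarantee that no two scanned clades hold identical genome sets (so a
  planted synapomorphy implies exactly one truth pair) and that every
  clade's species diverge at the next rank (so a planted duplication dates
  at its own rank). This is why the template departs from a
  3-orders-per-phylum layout: with a single class per phylum, class- and
  phylum-level genome sets coincide and the planted truth becomes
  ambiguous.
* **Genomes**: one 20-gene background contig per genome, 303 nt genes,
  background intergenic gaps 120–300 nt; background genes annotated with
  probability 0.3 from a 10-pathway background pool.
* **Planted operons**: 10 calibration pathways × 10 known families, plus
  novel planted families, 8 members each, 90% of members embedded (rounded
  to nearest) in a 4-gene co-strand cassette with 10–60 nt gaps at window
  positions ∓1, ±2. Operon and background pathway pools are disjoint so
  the planted truth is unambiguous; context-shuffled null families instead
  receive sporadic, inconsistent operon-pathway neighbours (≈0.5 per
  window on average, random position/strand/pathway).
* **Synapomorphies**: one gene per chosen genome, planted at order-level
  clades with coverage 1.0 (12 members > 10).
* **Codon families**: HKY-within-codon proposals (κ = 2) with the
  non-synonymous acceptance scaled by ω and stop codons rejected — the
  simplest model that exercises NG86 rank recovery.
* **Abundance**: 500 families × 200 samples in 5 equal blocks, log-normal
  baselines (σ = 0.6), per-(family, block) offsets (σ = 0.5), prevalence
  0.9 zero-inflation, and a 2-fold case shift planted in 20 families.

Passing the planted-truth tests shows the scoring, calibration and testing
machinery is correct, not that the method would perform equally on real
MAG catalogues: real genomes share pathways between operons and
background, annotations are noisy and incomplete, contigs fragment
windows, clusters come from imperfect sequence clustering, and block sizes
and effect shapes are far less regular. Those effects shrink the planted
margins; they do not change the computed quantities.

## Limitations

Sequence clustering, homology searches, structure prediction, read
mapping and coding-potential computation are external: the package
consumes their outputs (cluster tables, hit tables, boolean flags). The
NG86 estimator ignores transition/transversion bias and rate variation by
design and is validated as a rank-preserving pass/fail screen, not as an
unbiased ω estimator. The normal approximation of the blocked test is
inaccurate for very small blocks (a handful of samples per block); its
empirical type-I error is verified at the benchmark's block sizes.
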