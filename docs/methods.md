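# Methods

## The model

`gsred` simulates and analyses a location-driven model of genome-size change
after chromosomal rearrangement. Its premises:

1. The local recombination rate c(p) is determined by chromosomal position —
   near zero across the pericentromere, rising steeply toward each telomere.
2. Deletions occur with intensity proportional to c(p). Most are
   *illegitimate* (homology-free); a minority are *unequal intrastrand
   recombination* events between the two terminal repeats of an intact LTR
   retrotransposon, each of which excises the internal region plus one
   terminus and leaves a solo LTR.
3. TE insertions accumulate with intensity proportional to 1 − c(p)/max c,
   i.e. preferentially in low-recombination regions.
4. Genic sequence is protected: deletions that would remove gene bp are
   rejected, and insertions land only in intergenic/TE sequence.

Unrearranged chromosomes therefore maintain a U-shaped gene-density gradient
(gene-rich, repeat-poor ends; repeat-rich centre) in mutation–deletion
balance. An inversion (or relocation/breakage) that moves repeat-rich
pericentromeric sequence into a distal environment exposes it to rapid
removal, while the formerly distal material now sits proximally and slowly
gains TEs. Removal is much faster than gain, so the rearranged region
shrinks, the fastest loss occurring at its newly distal end — producing the
rising per-block size-ratio gradient ("arc") the analysis stages measure.

## Recombination map

c(p) is a symmetric logistic ramp in d, the fractional distance from the
centromere along an arm:

    c = c_min + (c_max − c_min) · (σ((d − d₀)/w) − σ(−d₀/w)) / (σ((1−d₀)/w) − σ(−d₀/w))

Defaults d₀ = 0.72, w = 0.05, c_min = 0.01, c_max = 1 keep genetic distance
flat across the proximal half of an arm and climbing steeply in the distal
quarter, the shape Marey maps show for plant chromosomes. Cumulative cM is
the normalised integral of c scaled to a configurable genetic length
(default 120 cM). The centromere is modelled as a physical locus: an event
moves it only by adding or removing sequence on its left (an inversion
spanning it reflects it). Each arm's landscape therefore responds to that
arm's own length changes, not the other arm's.

## Ancestral chromosomes

Chromosomes are gap-free tilings of gene / TE / spacer features laid down
left to right. The gene weight rises with d as g_min + (g_max − g_min)·d^1.5
(defaults 0.06 → 0.80) while the TE weight falls symmetrically
(0.82 → 0.05), producing the U-shaped gene track and anti-correlated TE
track. TE copies draw a family from per-class pools (defaults: 14 LTR, 10
DNA, 6 LINE, 3 SINE, 3 simple-repeat, 3 low-complexity families); LTR
families carry explicit 200–350 bp terminal repeats. A 6% tandem-duplication
probability re-uses the previous gene family so local gene duplications
exist. Default chromosomes are 1.2 Mbp — a deliberate desk-scale compression
of >100 Mbp chromosomes chosen so that replicate simulations complete in a
couple of seconds while every measured contrast (region ratios, R², block
gradients, mechanism fractions) remains well resolved.

## Event scheduling

Each generation draws Poisson event counts at the current chromosome length
and thins candidate positions by c(p)/c_max (deletions) or 1 − c(p)/c_max
(insertions); exact in the small-rate limit, and per-generation rates here
are ≤ 10⁻³. Deletion lengths follow a truncated discrete power law
(exponent 1.6 on 30 bp–20 kbp), so short deletions dominate counts while
≥1 kb deletions dominate removed bp. Under gene protection an accepted
deletion overlapping any gene bp is re-drawn up to 10 times, then skipped.
Each intact LTR element converts to a solo LTR with per-generation
probability λ_unequal·c(midpoint); the 5′ terminus (in the element's own
orientation) is retained — an arbitrary, documented choice. Every event is
logged with its span in then-current coordinates, its signed length change,
and the removed ancestral-source slices, so replaying a log on the ancestor
reproduces the final chromosome exactly and final length always equals
ancestral length plus the summed length changes.

Default rates (λ_illegit = 1.8×10⁻⁶ /bp/unit-c/generation,
λ_unequal = 2×10⁻³ /element/unit-c/generation, λ_insert = 4×10⁻⁹
/bp/generation, 2 500 generations) were calibrated once so that a terminal
inversion reproduces the headline outcome of the model — an inverted-region
size ratio near 1.4 beside near-unity non-inverted ratios — at desk scale.
They are study conditions, not biological estimates; the compression of
2×10⁶ generations into 2.5×10³ scales all rates by the same factor and
leaves every ratio-based observable unchanged.

## Annotation realism: fragment degradation

A deletion that truncates a TE leaves a relic. Relics shorter than 200 bp
are re-tiled as unannotated sequence (spacer) while keeping their sequence
provenance: repeat annotation does not recover arbitrarily small fragments,
and treating every sliver as a countable element would let fragmentation
*inflate* TE counts precisely where elements are being destroyed, breaking
the empirical coupling between TE number and sequence loss that the block
statistics measure. Fragments ≥ 200 bp remain annotated, with the template
interval they still represent recorded (`template_start`/`template_end`).

## Sequences and exact alignment truth

Per-family template strings generate all copy sequences deterministically
from the simulation seed. Orthologous gene copies share one ancestral
sequence; TE copies diverge from their family template by 2% substitutions.
LTR terminal repeats are emitted with zero per-copy divergence by default —
the young-element assumption under which the 100%-identity solo-LTR
criterion is meaningful. Alignment blocks are derived from feature
provenance, not from an aligner: every ancestral base surviving in both
lineages maps to a coordinate in each, and maximal runs contiguous in all
three coordinate systems (with consistent orientation) become blocks. The
complement identity — aligned bp + unaligned bp = genome length — holds
exactly by construction.

## Analysis stages

**Synteny.** Homolog pairing is top-hit by family label (a k-mer identity
scorer is available when labels are absent); ties break to the
lexicographically smallest target id. Chaining is a dynamic program for the
maximum-cardinality run of pairs with consistent index direction in both
genomes and index gaps ≤ max_gap (default 5); among equal-length chains the
lexicographically smallest is taken, chains are extracted greedily
(best-first), and blocks need ≥ min_pairs (default 4) members. Because
gene-protected simulations are perfectly collinear, a whole inversion would
chain into one block; `max_pairs_per_block` (pipeline default 8–10) splits
long chains into balanced consecutive sub-blocks, restoring the per-block
resolution that annotation noise gives real chaining runs. Inversions are
maximal runs of reverse-orientation blocks; overall region ratios are
length-weighted (Σ span_I / Σ span_D) over member blocks.

**Density.** Chromosomes are cut into 500 equal partitions (remainder folded
into the last; densities use true partition lengths, so no bias), genes
assigned by midpoint, density expressed per 100 kb. Partition pairs between
genomes match by index. The U-shape diagnostic is 1 − Spearman ρ against a
distance-from-centre template (constant tracks score 1 by convention). The
Marey profile interpolates cumulative cM over fixed windows and reports
cM/Mb; decreasing cM is flagged, duplicate positions are an error.

**TE metrics.** Elements count inside a span if their midpoint does. Count
ratios with zero denominators are NaN and excluded (never coerced to 0);
R² is the squared Pearson correlation of an OLS fit, with constant
predictors defined as R² = 0. Local gene duplications slide a 10-gene
window, step 1, and count each gene once however many windows rediscover it.

**Deletion forensics.** Unaligned segments are the per-genome complement of
the aligned spans. Flanking classification looks for repeats ≥ 50 bp within
100 bp of each endpoint: *identical* requires the same repeat template in
the same direction **and**, when template intervals are annotated, at least
50 bp of shared template — two hits to disjoint parts of one element
consensus are not homologous direct repeats and cannot mediate
recombination; *similar* requires only the same TE class. The solo-LTR
inventory extracts annotated terminal-repeat sequences of intact elements
and searches both strands for full-length exact matches (identity < 100% is
available via banded edit distance); hits overlapping any annotated LTR
element footprint — intact or truncated — are excluded, the rest are solo
loci. At zero terminus divergence this equals the count of ledger events
whose solo survived, provided each family retains an intact copy to supply
the query; default family sizes make that hold, and the few-family
configurations used for exactness checks make it certain.

**Rate estimation.** For region lengths a (unrearranged) and b (rearranged)
after n generations, the compound estimator x = (1 − (b/a)^(1/n))·100 treats
shrinkage as a constant per-generation fractional loss, so a(1 − x/100)ⁿ = b
exactly and the initial-generation loss is (x/100)·a bp. With a = 129 Mbp,
b = 84 Mbp, n = 2.16×10⁶ it gives 2.0×10⁻⁵ per 100 bp per generation
(≈ 26 bp/generation); halving n doubles it to 4.0×10⁻⁵. A linear variant
((1 − b/a)/n·100) ships behind a flag but is not consistent with those
quoted per-100-bp figures; reports always name the variant. b > a returns a
negative rate with a growth flag — the measured rate is a net rate and does
not distinguish loss from gain processes.

## What the synthetic data does and does not emulate

Emulated: shared ancestry with planted rearrangements; U-shaped density
gradients; pericentromere-enriched, family-structured TEs with real LTR
termini; recombination-scaled deletion of both mechanisms; slow proximal
insertion; marker maps drawn from the c(p) integral; exact alignment truth.
Not emulated: nucleotide substitution between orthologs (orthologs are
written identical), population processes and fixation, selection, nested or
polymorphic TE structure, assembly and annotation error, and the
3 000-fold larger scale of real chromosomes. Passing tests therefore
demonstrate that the estimators recover planted truth under the model's own
assumptions — not that real genomes satisfy those assumptions.

## Numerical and degenerate-input conventions

0-based half-open coordinates internally; GFF3 is 1-based closed. Inversion
and relocation breakpoints snap to feature boundaries and never split genes
(TE/spacer splits are allowed and keep family identity). All randomness
flows from a single seed; lineages and chromosomes use independent child
streams, so one lineage's draw count cannot perturb the other. Fixture
problem sizes: 30 replicate pairs at 1.2 Mbp/2 500 generations for the
distributional checks, 400 kbp fixtures for serialization tests, 200
randomized instances ≤ 50 pairs for the chaining oracle, and 30 replicates
of a 400 kbp fully-deletable flat-recombination chromosome for parameter
recovery (configured loss rate recovered within 10%).

## Known limitations

* Thinned-Poisson scheduling is exact only in the small-rate limit; at the
  default rates the bias is far below Monte-Carlo noise.
* Block-span summation slightly underestimates whole-region ratios because
  inter-block gaps (biased toward heavily deleted sequence) belong to
  neither span; the truth-based region ratios run ~0.05–0.1 higher.
* The family-level repeat template model makes "identical repeat" a
  family-level statement, as it is for repeat-library annotation; planted
  unequal events are recovered exactly, but in dense repeat neighbourhoods
  genuinely ambiguous identical-flank configurations exist (adjacent
  same-family elements), which is a property of the underlying inference
  problem, not of the implementation.
* Replay of relocation events requires genome-level context and is not part
  of per-chromosome truth replay; relocation is verified by direct paired
  simulation instead.
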