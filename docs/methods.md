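# Methods

## Coordinate system and substrate model

All coordinates are 0-based, half-open, in the **recipient homology frame**
(the recipient hosts the induced break, so its frame is the single global
coordinate system for markers, breaks, tracts and lengths). "Upstream"
means the smaller coordinate (5' of the reading frame). The donor differs
from the recipient by isolated substitutions (the genotyping markers) and
one 6-bp insertion that inactivates its I-SceI site; the insertion is a
product-identity feature and never enters tract logic.

The pair is aligned globally with edlib (unit edit costs). Because the
engineered substitutions are isolated (≈50 bp apart), the optimal alignment
is forced at every marker column and any aligner satisfying that property
gives the same marker map; affine gap scoring is unnecessary. Optimal
tracebacks may split the single biological insertion into adjacent gap
fragments separated by a matched base; fragments within 3 bp are
re-expressed as one equivalent insertion when a shift-equivalent single
placement exists.

The 18-bp I-SceI recognition site is cleaved with 4-nt 3' overhangs: the
two nick coordinates bound the overhang region and `cut_center` is its
midpoint. A marker's `dist_to_break` is measured to the **nearer 3' end**
of the cut, the convention under which the two break-flanking SNPs of the
published design report 8 bp. Whether distances for non-flanking markers
should instead be measured from the cut center is unknowable from the
design alone; the nick convention is fixed here and the two differ by at
most 2 bp.

## Genotype calling

Reads carry a 16-nt barcode at both ends anchored to product-specific
universal primers. Demultiplexing accepts the unique barcode within
Hamming distance 2 of the leading 16 nt (both orientations tried; barcodes
are validated to be pairwise ≥ 5 apart so assignment is unambiguous);
product identity comes from the universal forward primer that follows the
barcode. Unassignable reads are routed to an unassigned bin with a reason,
never dropped silently.

Each read is aligned (infix, both references) and the higher-identity
alignment frames the marker columns; a column matching the recipient base
is called R, the donor base D, anything else (including a deletion) N.
Alignment identity < 80% yields an all-N profile with a QC flag. CCS reads
are treated as flat-quality; FASTQ qualities are parsed but unused.

Species clustering groups profiles by exact equality on non-N calls, with N
compatible with anything; a profile joins the compatible cluster with the
largest support (ties toward the earlier-created cluster), which suppresses
error-driven species inflation deterministically. A species is **major**
if it has ≥ 2 supporting reads and ≥ 10% of the product's reads — the
published analysis does not quantify "major", and these defaults suppress
singleton error species while retaining both hetDNA-derived species at
typical depths (both thresholds configurable). A recombinant with more
than two major species in either product fails QC as spurious. The product
genotype merges the one or two major species per marker: agreement passes
through, R-vs-D disagreement is the hetDNA diagnosis H, and N defers to the
non-N call.

## Tract segmentation and lengths

Genotype vectors are segmented into maximal runs of {R, D, H}; an N marker
is absorbed when its nearest non-N neighbours agree and excluded otherwise.
Each product of a crossover has two parental flanks (doubly-truncated
product: recipient upstream / donor downstream; full-length product: the
reverse), and every segment inherits the **context** (recipient- or
donor-derived) of its side of the anchor; non-H runs spanning the anchor
are split there, since a donor run continuing across the break mixes
parental flank with break-adjacent conversion. H runs become hetDNA
tracts (relabelled symmetric when both products are heteroduplex at the
identical markers), non-parental homoduplex runs become conversion tracts,
and a parental run flanked by hetDNA on both sides is a restoration patch.

Tract length on a side is the distance from the anchor to the most
break-distal transition out of heteroduplex/converted sequence. The true
transition lies between markers, so it is placed at the midpoint of the
flanking inter-marker interval — the unbiased, reproducible point estimate;
when the outermost informative marker is terminal the length extends to the
homology border. Total length per event is the sum of the two sides (or
the single side's length for one-sided events). Conversion counts toward
length, since a transition between donor and recipient sequence is as
informative about strand-exchange extent as a het-homoduplex transition.
Measured lengths are therefore accurate to at most one inter-marker
interval (~50 bp at the design's density), which the tests assert against
simulator truth.

## Event classification

Induced events are classified in a fixed precedence order that keeps the
classes disjoint: (1) no hetDNA anywhere with conversion → conversion-only;
(2) hetDNA only in donor-derived context → donor-only; (3) recipient-context
hetDNA on both sides of the break → two-sided (donor alterations are
recorded as features, not a class change); (4) hetDNA in both products
wholly on one side with a clean inter-product transition → displaced
transition, with the displacement recorded; (5) hetDNA on exactly one
side → one-sided left/right; (6) anything else → uninterpretable. The
published "patchy/uninterpretable" criterion is verbal; this precedence
order is one consistent formalisation.

"Break-adjacent" conversion means the run includes the break-flanking
marker; one converted marker is single-SNP loss (polymerase proofreading of
the terminal mismatch), two or more contiguous are gap expansion. A
symmetric run is **terminal** when it continues the break-distal end of an
asymmetric tract with no hetDNA beyond (junction migration away from the
break) and **interstitial** otherwise (template switching).

For spontaneous events the initiating lesion is inferred from the pattern:
disjoint asymmetric tracts in the two products → DSB, placed at the
transition midpoint or at the centre of an interstitial conversion tract
separating the tracts (the full tract interval is stored alongside the
point estimate, as the break likely sat at one of its ends); the broken
allele is the one whose sequence the hetDNA replaced (the minor
contribution). A single asymmetric tract in donor-derived context within
one inter-marker interval of the other product's clean junction → nick; a
symmetric tract at the crossover point with an asymmetric extension in
exactly one product → gap. These labels are descriptive, not causal: the
same patterns arise among break-induced events. The 3'-half flag compares
the inferred position with the homology midpoint.

## Simulator

Mechanisms are simulated at **strand-of-markers resolution** with bp-valued
interval endpoints; markers are projected onto sampled intervals and full
nucleotide sequences are realised only at read emission. Each product is a
duplex of two allele strands; hetDNA is where they disagree. This keeps
mechanism logic exact and fast.

Canonical DSB repair samples a resection extent per side (default geometric,
mean 1000 bp — chosen once so that simulated total hetDNA is on the
kilobase scale of the assay; all distributions configurable), forms a
hetDNA tract per side, and resolves as a crossover. Optional complexity,
applied in a fixed order (end loss → back-migration → junction migration →
template switch → patch repair → resolution; the mechanisms themselves fix
no order): 3'-end loss converts break-adjacent markers (gap expansion);
single-SNP loss removes just the flanking marker with side-specific
defaults 0.49 upstream / 0.94 downstream (the measured mismatch-dependent
efficiencies); back-migration erases the invasion-side tract; positive
junction migration creates terminal symmetric hetDNA, negative migration
displaces the inter-product transition past the break; a template switch
places a one-excursion footprint in donor-derived sequence; patch repair
removes individual mismatches with restoration bias 26/37. Nick-directed
resolution fixes the orientation (upstream tract in the doubly-truncated
product); random resolution of ligated junctions flips it with probability
0.5.

The nick model yields a single donor-context tract adjacent to the
crossover point; the gap model a symmetric tract across the gap plus an
asymmetric extension in one product (a zero-length gap degenerates to the
nick pattern); D-loop cleavage yields an invasion-side tract plus an
SDSA-completed partner whose randomly chosen extended end makes the event
one-sided or indistinguishable from canonical two-sided repair.
Spontaneous initiation in the donor allele is modelled as the mirrored
product pattern of recipient initiation, which is what donor breakage looks
like at marker level.

Colony observation replicates each duplex into its two strand-faithful
lineages (two species when they differ); with probability `p_daughter_loss`
one lineage is dropped, rendering hetDNA invisible and producing
conversion-only appearances. Read emission reconstructs sequences on the
recipient backbone (donor insertion included when the locus is
donor-derived), attaches barcode and universal primers at both ends,
applies uniform substitution errors and randomizes orientation.

Allele accounting: outside hetDNA every marker carries two recipient and
two donor alleles across the four product strands; inside an asymmetric
tract one recipient allele remains, because the broken molecule's resected
strand is destroyed and resynthesized from the donor template. The tests
assert this corrected bookkeeping.

Fluctuation counts use the standard branching approximation: mutations per
culture ~ Poisson(rate × N), each clone sized ⌊1/U⌋ (capped at N), which
reproduces the heavy jackpot tail.

## Statistics

Medians use the mean-of-central-pair convention for even counts; events
without hetDNA are excluded and all summaries report n. Fisher's exact
test, the Pearson goodness-of-fit test (no Yates correction by default —
the published variant is unstated; a flag enables it) and the
Mann–Whitney U test (exact for the smaller sample ≤ 8 without ties,
otherwise normal approximation with tie and continuity corrections) are
delegated to scipy behind this module's surface and cross-checked against
enumeration/closed-form oracles in the tests. No multiple-testing
correction is applied.

The Lea–Coulson point estimate solves `r̃/m − ln m = 1.24` by bracketed
root-finding (relative tolerance 1e-9). The 95% CI uses the Stewart-type
standard error on ln m, `σ = 1.225·m^−0.315/√C`, chosen because the
original CI procedure is not reproducible from its description; the formula
is documented and swappable. All-zero counts yield a flagged
upper-bound-only estimate, `m ≤ −ln(0.05)/C`, from the zero-culture
likelihood.

## What the simulator does and does not establish

The generator emulates the observable consequences of the mechanism models
— strand partitioning, colony segregation of unrepaired hetDNA, barcoded
amplicon structure, uniform sequencing error — under stated parameter
defaults. It does not model thermodynamics of strand exchange, BIR or
multi-invasion rearrangements, meiotic recombination, chimeric PCR
artifacts, or context-dependent error profiles of real long-read data.
Passing round-trip tests therefore demonstrates that the pipeline correctly
inverts the simulator's generative process at realistic noise levels, not
that every complication of real colony sequencing is handled. Problem
sizes in the tests (a 16-marker, ~0.9 kb substrate for read-level checks;
the full 82-marker, 4.1 kb design for marker-map and length-scale checks;
500–10,000 events for distributional properties) were chosen as the
smallest giving stable statistics.

## Known limitations

* Breakpoints are only resolvable to inter-marker intervals; midpoint
  placement is a convention, and published length medians could equally
  have been computed marker-to-marker.
* The displaced-transition model commits to one specific strand outcome of
  junction migration past the break; real events may differ in which
  product retains the swept tract.
* Initiating-lesion labels for spontaneous events are pattern matches, not
  causal assignments.
* The reference per-event length data of the original assay are not
  bundled, so printed medians are not re-derivable here; simulated cohorts
  stand in for scale checks.
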