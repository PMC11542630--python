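# Methods

This note documents the models, defaults, and numerical choices behind the
package, and what the synthetic validation does and does not establish.

## Gene families

Family circumscription consumes a 12-column tabular similarity report
(query, subject, %identity, alignment length, mismatches, gap opens,
coordinates, E-value, bit score) plus per-sequence lengths.  Hits are kept
when E ≤ 10⁻³, coverage ≥ 50% and identity ≥ 50%.  Coverage is alignment
length over *query* length; the denominator is configurable because
different search orientations make either convention defensible.  A
transcript joins the family of an anchor (reference) gene only when hits
exist in both directions; transcripts qualifying for several anchors go to
the best bit score, ties broken lexicographically for determinism.

Redundancy removal keeps, within a species, only the longest of any set of
transcripts that are 100% identical over their aligned span.  Without an
aligner in scope, "identical over the aligned span" is implemented as exact
containment of the shorter sequence in the longer, which covers the
intended case (UTR-trimmed or truncated isoforms of one gene).  Where a
species still has two transcripts, pairwise Ks separates ohnolog candidates
from old paralogs: Ks > 1 marks an old duplicate (only the best match to
the anchor is kept as the ortholog), Ks ≤ 1 — boundary inclusive — keeps
both as candidate ohnologs.  Species with more than two surviving copies
are flagged and excluded from quartet classification, which presumes
tetraploidy.  Families flagged by an external gene-conversion screen (e.g.
GENECONV output) are masked, not deleted, and the masked count is reported.

## Topology classes and the IP/SP decision

For two tetraploids there are (2·4−3)!! = 15 rooted binary labelled
topologies on the four ohnologs; collapsing copy identity leaves six
species-labelled classes.  The package orders them T1 = ((A,A),(B,B)),
T2/T3 = the caterpillars with a within-species cherry, T4 = ((A,B),(A,B)),
T5/T6 = the caterpillars with only cross-species cherries.  T1–T3 are
compatible with each species' copies coalescing before any between-species
coalescence and count as evidence for independent polyploidization (IP);
T4–T6 count for shared polyploidization (SP).  Only the IP/SP partition is
biologically fixed; the T-numbering is a presentation convention.

Triplet trees (three tetraploids, six leaves) are called IP when all three
within-species copy pairs are cherries and SP when the root splits the
leaves into two clades each holding exactly one copy of every species;
anything else is AMBIGUOUS.  These are the strict logical extensions of the
two-scenario picture; the AMBIGUOUS bucket makes the triplet tallies
conservative rather than forcing borderline trees into a class.

A pair (or triplet) is decided *independent* when the IP fraction exceeds
the SP fraction by at least the decision margin (default 0.10), *shared*
for the reverse, else *ambiguous*.  The margin guards against coin-flip
tallies; observed majorities in practice are far larger, so the default
never flips a clear case.  Multifurcating gene trees — either rejected
input that was explicitly admitted, or trees whose weakly supported edges
were collapsed (support threshold default 0, i.e. no collapsing) — are
routed to AMBIGUOUS rather than resolved, since resolving would manufacture
topology signal.

## Ks estimation and dating

Pairwise synonymous divergence uses Nei–Gojobori (1986): fractional
synonymous site counts per codon (changes creating stop codons count as
nonsynonymous), differences averaged over all orderings of the differing
positions with stop-codon intermediates excluded (if every ordering is
blocked, all orderings are used and steps touching a stop count as
nonsynonymous), and the Jukes–Cantor correction ds = −¾·ln(1 − 4ps/3).
Records with ps ≥ ¾ are flagged invalid rather than extrapolated.  Codons
containing gaps, ambiguity codes or stops in either sequence are skipped
and counted.  The NG86 engine is checked against a brute-force per-codon
oracle over all 61×61 sense-codon pairs, and against Biopython's
independent implementation.

The per-species Ks distribution is smoothed with a Gaussian kernel on a
2048-point grid over [0, 1.1·max]; the peak is the grid argmax, and local
peaks with prominence ≥ 5% of the maximum are also reported.  Bandwidth is
Silverman's rule by default.  One numerical subtlety matters at recent
WGDs: with S synonymous sites and few synonymous differences per family,
Ks = Sd/S lives on a lattice with spacing 1/S, and a kernel narrower than
that spacing degenerates the argmax to the most populated count.  The
dating step therefore floors the bandwidth at 1.5/median(S) (the
`lattice_bandwidth` helper; multiplier configurable).

Dates follow the molecular clock T = Ks/(2r) with
r = 3.51 × 10⁻⁹ synonymous substitutions per site per year (a Cyprinidae
rate) as the default; times are reported to two decimals in Mya.  T is
linear in Ks and inversely proportional to r, so any other clock simply
rescales the axis.

## Ordering WGD against speciation

T_Ks enters as a point estimate (the density peak); matrilineal divergence
T_mt carries a 95% interval.  A pair is *independent* when both species'
T_Ks fall below the interval's lower bound, *shared* when both exceed the
upper bound, otherwise *ambiguous*; `rel_tol` (default 0) widens the
exclusion band for sensitivity analysis.  The asymmetry — point versus
interval — mirrors how the two quantities are usually obtained (a density
peak has no straightforward confidence interval without bootstrapping,
which is out of scope).  Note that for allopolyploids T_Ks measures the
divergence of the two parental lineages, which predates the hybridization
itself; the ordering and topology evidence still agree on sharing as long
as the donor lineages are sampled (see Limitations).

## MUL-tree reconciliation

Hypotheses for one polyploid clade are: the singly-labelled species tree
(baseline), the autopolyploid MUL tree (second copy of the clade's subtree
attached to the clade's own edge), and one allopolyploid MUL tree per other
edge, including the root edge (which admits an extinct or unsampled parent
above the sampled taxa).  Each gene tree is scored by duplication + loss
parsimony under LCA mapping, with unit costs by default (costs
configurable); every gene-tree leaf of a doubled species may map to either
of that species' two MUL leaves, and the score is minimised exactly over
all assignments up to 12 polyploid leaves (exhaustive 2^k search; beyond
that a greedy per-leaf pass is used and flagged non-optimal).  Hypotheses
are ranked by total score over gene trees; ties prefer the hypothesis
assuming fewer WGDs and are reported, never silently broken.  Absolute
scores depend on the cost convention, so only the ranking is interpreted:
winner's second-copy placement on the clade's own edge ⇒ autopolyploidy,
elsewhere ⇒ allopolyploidy naming the donor.  Exactness of the minimisation
is verified against an independent brute-force on random instances.

## Synthesis into events

Pair-level sharing is the topology-tally decision when it agrees with the
T_Ks/T_mt ordering; disagreement yields *ambiguous* with both decisions
recorded and the agreement flag cleared — the package surfaces conflicts
instead of arbitrating them.  Species connected by shared calls merge
transitively into one event (the event count is the number of connected
components of the sharing graph); an independent call inside a merged group
is a contradiction and raises an error listing the offending pairs.  Event
mode comes from the joint reconciliation of the merged clade when it forms
a clade of the species tree, else from the consensus of the members'
per-species reconciliations.

## The simulator

The generator produces the statistical structure the analysis assumes, so
each stage can be validated without external data.

* **History.** A time-calibrated species tree (nested (left, right, age)
  description, ages in Mya) with WGD events placed on edges.  An event must
  lie on the stem edge of the MRCA of its species set — crown age < event
  time < stem-parent age — so shared events necessarily predate the splits
  they span.  Allo events name a sampled donor species and must be younger
  than the recipient–donor lineage divergence.
* **Gene trees.** Each family's tree follows the history deterministically:
  at an auto event the lineage's subtree duplicates in place; at an allo
  event the second copy of the recipient subtree grafts onto the donor
  lineage at the event time — so allo ohnologs coalesce at the *parental
  divergence*, reproducing the biological fact that Ks dates parental
  divergence, not hybridization.  Noise: with probability q (default 0.05)
  one random nearest-neighbour interchange, and each ohnolog copy is lost
  independently with probability 0.05 by default.  NNI + loss is used
  instead of a multispecies coalescent because the classifier consumes
  topology frequencies and these two dials control the minority-class and
  missing-copy rates directly; a coalescent generator is a natural
  extension point.
* **Sequences.** Branch lengths are expected synonymous substitutions per
  synonymous site (r × years).  Along each branch, synonymous events arrive
  per codon as Poisson counts with mean = branch length × that codon's NG86
  synonymous site count, nonsynonymous events at 0.2× the equivalent
  nonsynonymous rate, each event substituting a random single-nucleotide
  neighbour of the matching class; no indels.  Calibrating the mutation
  process with the estimator's own site accounting makes E[Ks] = 2rT hold
  by construction, which is the property the validation needs — a named
  codon model would test the estimator against a different model's
  opinion of a synonymous site and conflate two error sources.
* **Defaults as study conditions.** The four canonical scenarios use
  Pleistocene-scale parameters: independent WGDs at 0.93/1.45 Mya under a
  9.02-Mya split, a shared WGD at 2.0 Mya over a 0.16-Mya split, allo
  variants with sampled donors diverging 3–5 Mya; 500 families of 2,000
  codons; mito intervals of ±2.0 Mya (deep splits) or ±0.05 Mya (shallow).
  The 2,000-codon default is deliberately long — the information content of
  a long or concatenated family alignment rather than one typical CDS — so
  that the expected synonymous-difference count at Ks ≈ 0.0065 is ≈ 10,
  the regime where the density-peak estimator is informative.  At
  single-gene lengths (a few hundred codons) the count lattice dominates
  and the peak is biased low by tens of percent; that bias is a property of
  peak-based dating at very recent WGDs, not of this implementation.

## What the validation shows

On the four canonical scenarios the pipeline recovers sharing and mode
exactly and the dated ohnolog divergence within 15% (typically within
5–7%).  This demonstrates internal consistency: the estimator inverts the
generator under the stated noise.  It does not establish robustness to
features real transcriptome data adds — assembly artifacts, alignment
error, rate variation among sites and lineages, gene-tree estimation error
beyond one NNI, rediploidization (which can distort ohnolog genealogies in
ancient WGD lineages), or unsampled allopolyploid parents.  The last two
are the known failure modes: with both parental lineages extinct or
unsampled, an allopolyploid is indistinguishable from an autopolyploid by
reconciliation, and independent allopolyploidizations from a shared donor
mimic a shared event; the ortholog-Ks asymmetry test is the partial guard.

## Numerical conventions

* Degenerate Ks densities (all values equal) fall back to a narrow kernel
  and peak at the common value.
* Density evaluation reflects mass at 0 so peaks near zero are not
  attenuated; the curve integrates to 1 ± 0.01 over its grid.
* Wilcoxon signed-rank (via scipy): zeros dropped; exact null for n ≤ 25
  without ties, normal approximation with continuity and tie correction
  otherwise; the all-zero case returns (W = 0, p = 1) with a warning.
* All randomness derives from one seed via numpy `SeedSequence` fan-out;
  identical (scenario, seed) reproduce byte-identical trees and sequences.
* Reported times round to 2 decimals; internal values are unrounded.
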