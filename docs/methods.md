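# Methods

This note records the models and procedures behind `nlrevo`, the parameter
choices that matter, and what the synthetic-data validation does and does
not demonstrate.

## Classification of NLR architectures

A protein enters the NLR universe iff it carries an NB-ARC domain; among
NLRs the N-terminal domain fixes the class — TIR → TNL, RPW8 → RNL,
Rx_N → CNL, none of the three → NL. LRR presence is recorded but never
changes the class (NL deliberately includes both NBS-only and NBS-LRR
architectures). Proteins carrying more than one of the three N-terminal
domains are classified with the fixed precedence **TIR > RPW8 > Rx_N** so
that the labelling stays a total, deterministic partition; such proteins are
additionally flagged (`is_multi_nterminal`) so a user can review them.
Domain names are canonicalized (Pfam accessions PF00931/PF01582/PF05659/
PF18052 and common aliases; any name starting `LRR` counts as LRR).

The phylogenetic screen keeps a candidate iff the smallest clade containing
it and at least one reference leaf contains only plant-R references (strict
mode). A permissive mode instead keeps a candidate if *any* enclosing clade
consists solely of candidates plus plant-R leaves. Strict is the default:
it is the more conservative reading of "forms a monophyletic group with
plant R proteins", and the two modes differ only when references from both
classes interleave near the candidate. Outgroup-labelled leaves are inert:
they neither anchor nor poison a clade.

Isoform redundancy is resolved per locus by keeping the longest protein,
ties broken by lexicographically smallest identifier — the standard
longest-isoform convention, made deterministic.

## Duplication and transfer calling

Both callers operate on maximal single-species clades (clades whose leaves
are all one species and whose parent clade is not). A duplication event set
is emitted per such clade of size ≥ 2; `node_count` mode scores a clade of
*n* genes as *n* − 1 events (each coalescence a duplication, polytomies
counted as resolved), `per_clade` scores 1. Both tallies are reported
because published event counts rarely state which granularity they used.

HGT calling reads "the diversity of one species falls within that of
another" as two-sided nesting: from a recipient clade, each of the next
`context_depth` enclosing clades must add leaves of one and the same other
species. The default `context_depth = 2` requires the recipient to be
bracketed by donor material on both sides; depth 1 would fire on any
heterospecific sister pair and is far too permissive. Raising the depth can
only remove calls (monotone specificity; property-tested). Donor = the
enclosing species, recipient = the nested clade's species. Singleton
recipient clades are allowed by default (`min_clade_size` raises the bar).
Node-support thresholds are off by default (`min_support = 0`) since event
calling on published trees rarely states one; when supports are present the
context nodes are checked. Trees explicitly flagged unrooted (`[&U]`) are
midpoint-rooted with a warning; otherwise trees are used rooted as written.

Known limitation: a single transfer between sister species can license a
reciprocal call in the opposite direction (the true recipient's relatives
look nested from the other side). This direction ambiguity is inherent to
species-tree-free clade heuristics and accounts for most residual false
calls in the recovery experiment below. Incomplete lineage sorting is not
modelled and would be confounded with transfer on real trees of closely
related cultivars.

## MaxChi recombination scan

The detector is the classical maximum chi-square idea applied pairwise: the
site list is the alignment's polymorphic columns (≥ 2 states among non-gap,
non-N characters over all rows), minus sites where either sequence of the
tested pair has a gap or N (pairwise, not alignment-wide, exclusion). Along
this list a boundary slides; at each position the 2×2 table of
(match, mismatch) counts in the left vs right `half_window` sites is scored
by the uncorrected chi-square, and the maximum over boundaries is the
statistic. Restricting to polymorphic columns is essential: it is what
concentrates the signal (a recombinant is *identical* to one parent at
polymorphic sites on one side of the junction and different on the other);
over all columns the same breakpoint is statistically invisible at
realistic window widths.

Significance comes from permuting site order: `p = (1 + #{permuted max ≥
observed}) / (n_permutations + 1)`, exact under the null and reproducible
under a fixed seed, so the smallest attainable p is `1/(n_perm+1)`.
Defaults `half_window = 25`, `n_permutations = 500`. Degenerate inputs —
fewer than `2·half_window` usable sites, or a constant match/mismatch
vector — return p = 1 with no breakpoint. The breakpoint is reported both
as an index into the polymorphic-site list and as the alignment column of
the last left-half site.

The consensus rule over external method batteries is deliberately strict:
a candidate event is significant iff at least `min_methods = 4` of the
seven named methods (RDP, GENECONV, Chimaera, MaxChi, BootScan, SiScan,
3Seq) report p strictly below `alpha = 1e-6`; absent p-values never
support. The rule is monotone in every p-value (property-tested against a
brute-force count over all 2⁷ patterns).

## Selection summaries

The M7-vs-M8 comparison is tested with `stat = max(0, 2(lnL₈ − lnL₇))`
against χ² with 2 degrees of freedom, whose upper tail has the closed form
`exp(−stat/2)`; negative differences (optimizer noise) clamp to 0 rather
than erroring. A group is called positive iff the LRT p-value is below
`alpha = 0.05` **and** at least one BEB site reaches posterior
`min_posterior = 0.95` — the conventional thresholds, both exposed as
parameters since published analyses often leave them implicit. The closed
form is verified against numerical integration of the χ² density to 1e-10.

## The simulator and what validation shows

`simulate_gene_family` runs an exact Gillespie simulation of a
birth–death–transfer process along a dated species tree: per gene lineage,
duplication at rate λ (optionally per species-tree branch), loss at μ,
transfer at τ, all per unit branch length; transfers copy the gene into a
uniformly chosen contemporaneous other branch (no distance bias — no
mechanism is assumed); speciations copy every lineage into all daughters.
The default species tree is a 10-leaf ultrametric ladder of unit depth with
evenly spaced splits, echoing a ten-genome study design; any dated newick
tree can be supplied. The returned gene tree is pruned to extant lineages
with unary nodes suppressed; the event log keeps every duplication, loss
and transfer with its branch, time, and (for transfers) surviving
descendant genes. Defaults λ = 0.3, μ = 0.1, τ = 0.1 give families of a
few to a few dozen genes — large enough to exercise every rule, small
enough that thousands of replicates run in seconds.

Domain states evolve on the pruned gene tree as four independent two-state
Markov chains from the NL root state (NB-ARC + LRR), with transition
probability `(g/(g+l))(1 − e^{−(g+l)t})` for gain (symmetrically for loss).
The defaults (gain 0.3/0.1/0.3/0.1, loss 0.5/0.5/0.5/0.1 for
TIR/RPW8/Rx_N/LRR) encode the view that N-terminal domains are gained and
lost frequently relative to LRR; NB-ARC is never lost because the family
is defined by it.

The recombinant generator draws parent A uniformly, derives parent B (and
optional backgrounds) with i.i.d. per-site difference probability equal to
the divergence, and splices C = A[1..k] + B[k+1..L]. It models exactly one
clean breakpoint with no rate heterogeneity, indels or homoplasy gradient —
sufficient for calibration and power checks of the scan, not a sequence
evolution model.

Validation scales (chosen as comfortable desk-scale experiment sizes):
100 seeded families for event-caller soundness (no loss/transfer → zero HGT
calls and exact terminal-duplication recall), 200 families at τ = 0.1 for
transfer recovery (called events matched to the truth log one-to-one by
recipient species plus Jaccard clade overlap ≥ 0.5; precision ≥ 0.8),
1000 three-sequence null alignments × 500 permutations for MaxChi type-I
calibration, and 500 replicates for the branching expectation
E[copies] = e^{λ·depth}. Passing these shows the rules are implemented
correctly and calibrated under the generative model's assumptions
(clock-like species tree, uniform transfers, no ILS, no alignment error);
it does not certify behaviour on real genomes, where tree estimation error
and ILS add false-positive pressure the simulator does not emulate.

## Numerical conventions

E-value thresholds are inclusive (≤); consensus and LRT significance are
strict (<), matching the usual reading of "p < α". CSV output is UTF-8
with `\n` endings and `.` decimals; newick round-trips preserve leaf
labels, topology, supports and branch lengths to well below 1e-9. All
stochastic components take integer seeds and are byte-reproducible;
internal streams are derived through `numpy` seed sequences so different
components never share a stream.
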