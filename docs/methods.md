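# Methods

## Scope and data model

The package works at the resolution classical cytogenetics provides for
taxa without sequenced genomes: a karyotype is an ordered list of
chromosome pairs, each with a centromere-position morphology class, an
optional relative length (% of TCL, the pair's share of the total
chromosome length of the diploid set), and annotations (NOR loci,
heteromorphism, sex-pair status). There are no ordered markers, so all
rearrangement reasoning is over *compositions* — counts of pairs per
morphology class, optionally with a relative-size multiset — never over
gene orders. Genome-order distances (DCJ, reversal distance) are therefore
out of scope by construction, as are likelihood models of chromosome-number
evolution; the comparative claims the pipeline reproduces are parsimony
claims.

## Morphology classification

Arm measurements are oriented long ≥ short and classified by the arm ratio
r = long/short using Levan-style bins: metacentric 1.0–1.7, submetacentric
1.7–3.0, subtelocentric 3.0–7.0, acrocentric above 7.0 (a missing short
arm is acrocentric by definition). The bin table is a parameter, since
published studies vary slightly in their cut-offs.

Transitional (composite) classes such as SM/ST are assigned when the
measurement lies close to an interior bin edge. Proximity is judged on the
centromeric-index scale ci = short/(short + long) rather than on r itself:
measurement error acts roughly additively on arm lengths, hence on ci,
whereas the same absolute error maps to wildly different Δr across the
range (r is unbounded as the short arm shrinks). The default relative
tolerance is 5% of the edge's index; for example arms (2.6, 7.4) give
r = 2.85, ci = 0.260 against the SM|ST edge index 0.250, inside the 5%
band, hence SM/ST. Tolerance 0 disables composites.

Predominance of biarmed (M, SM, M/SM) over monoarmed (ST, A, ST/A) pairs
is "approximately the same" when the two counts differ by at most two
pairs; SM/ST pairs — the only composite that straddles the biarmed/
monoarmed divide — are excluded from the comparison but stay in the pair
total and in the denominator of the biarmed percentage. The sex pair,
when listed, counts like any other pair; this is required to reproduce
the published 20% figure for the 35-pair charontid karyotype (7/35).
Printed percentages round half away from zero.

## Chiasma statistics

The mean chiasma frequency pools all plates: f = Σ chiasmata / Σ bivalents,
not a mean of per-plate frequencies — with unequal bivalent counts the two
differ, and the pooled form is the one the frequency definition states.
The banding low/moderate/relatively-high is implemented as the half-open
intervals [1.0, 1.2), [1.2, 1.6), [1.6, 2.5); the conventional printed
upper edges (1.19, 1.59, 2.49) are two-decimal truncations of these, and
the half-open reading preserves every printed worked example (1.24
moderate, 1.08 low, 1.72 relatively high). Values below 1.0 or at 2.5 and
above are reported out of range rather than silently clamped, because a
bivalent by definition carries at least one chiasma.

Positional classification uses cuts at 10% of the whole chromosome length
(not of the arm). Precedence: (1) a chiasma on an arm that is itself at
most 10% of the chromosome is pericentric, whatever its exact position;
(2) otherwise a chiasma–centromere distance under the cut is pericentric;
(3) a distance under the cut from the telomeric end of its arm is distal;
(4) the rest is interstitial, with the 20% of the arm's interstitial span
nearest the telomere refinable as "subdistal" (a refinement, never a
separate count in totals). With an unknown centromere only distal
(within the cut of either bivalent end) versus intercalar can be
distinguished. The "distal 20% of the interstitial region" is measured per
arm; measuring it per chromosome would let a long arm's subdistal zone
swallow part of the short arm's.

## Character coding

Each order has its own scheme: an ordered character list with one-symbol
state codes (0–9 then A–G) whose meanings are numeric values, ranges,
small value sets, or categorical labels; `?` is missing data, not a state.
Schemes ship as YAML fixtures so the state tables, not prose, are the
single source of truth. Encoding is kind-driven: diploid number by
value/range lookup (a record whose 2n spans a range must be fully covered
by the state's range); predominance through the composition summary, with
qualitative printed calls ("monoarmed predominant") used when no pair list
exists; NOR count by value lookup with a qualitative fallback state
("most pairs carry one or two loci") that triggers when the locus count
reaches the pair count; NOR location as the single most-derived category
present, with precedence pericentric > interstitial > subterminal >
terminal (whole-arm loci count as terminal — required by the printed
solifuge rows); heterochromatin pattern, sex-chromosome differentiation,
X-linked NORs and first-pair prominence from record annotations. A value
that fits no state raises an error naming the character; missing fields
encode as `?`.

The karyotype table fixture carries a few annotation columns (CH pattern,
X-linkage of NORs, first-pair prominence) that the printed per-species
accounts state only narratively; the full-matrix regression test checks
that encoding the 57 records reproduces all five transcribed matrices
character-for-character, `?` positions included.

## Ancestral reconstruction

Characters are unordered multistate with unit change cost. The
implementation is the Sankoff dynamic programme (upward pass of per-state
subtree costs, downward pass of whole-tree costs), which handles
polytomies natively and yields, per node, the exact MPR set — the states
attainable in some most-parsimonious reconstruction — rather than the
downpass sets of the classic two-state shortcut. Missing tips carry the
universal state set. A cost-matrix hook would admit ordered variants; the
published legends give no ordering, so unit costs are the default and only
tested mode.

Root reconstructions are reported as full optimal sets, decoded through
the scheme (ambiguity is surfaced, never resolved silently). For
synapomorphy maps one most-parsimonious labeling is fixed: ties between a
child's optimal states are broken toward the parent's state under DELTRAN
(changes delayed tipward) or away from it under ACCTRAN (default); either
way the number of changes on the labeling equals the parsimony length. A
derived state with exactly one origin branch is a unique synapomorphy;
multiple origins mark homoplasy. The tree fixtures transcribe the
order-level topologies used in the comparative analysis; the alternative
placement of *Stenochrus* ships as a second schizomid topology and is run
separately — no consensus machinery, per-topology results only. The
thelyphonid matrix has no usable published topology; the encoder supports
the order, mapping requires a user-supplied tree.

## Rearrangement model

Events act on composition count vectors (biarmed, subtelocentric,
acrocentric): centric fusion consumes two monoarmed pairs (any mix of ST
and A) and produces one biarmed pair (2n − 2); tandem fusion consumes two
acrocentric pairs and produces one acrocentric pair of summed size
(2n − 2; the acrocentric product follows the morphology of the fused
solifuge karyotypes, the only taxa the model's tandem fusions are invoked
for); fission splits a biarmed pair into two monoarmed pairs (2n + 2);
pericentric inversion toggles one pair between classes with 2n unchanged —
coarse mode (default, matching how the verbal scenarios are phrased)
toggles monoarmed ↔ biarmed, fine mode adds A ↔ ST shifts; polyploidization
doubles every count. Operands are consumed before products are added, so
an event can never act on a pair it creates. Nested fusions are not a
separate event kind: on compositions they are exactly a fusion followed by
an inversion, and the model represents them as such.

Size tracking is optional: relative sizes are normalized to fractions of
the total and multisets compare with 1% relative tolerance, since
published size statements are qualitative. Fusions conserve total
chromosome material; polyploidization doubles it.

`min_scenario` is breadth-first search over composition space with unit
edge costs, so the witness length is globally minimal; per-kind counts are
those of one optimal witness. Targets may be full compositions or
predicates (e.g. "any eight-pair set"). The size-aware variant searches
over (counts, rounded normalized size multiset) states and enumerates
which pairs fuse. The search space is bounded (default 60 pairs); an
unreachable target returns an explicit null result. The test suite checks
the search against an independently written BFS oracle with its own inline
transition rules on 200 random instances of up to 12 pairs, plus symmetry
and triangle-inequality properties.

## Synthetic data

Each generator is a pure function of its config (single integer seed,
one dedicated pseudo-random stream per generator, so adding one generator
never shifts another's draws).

* Spreads: arm ratios uniform inside the target class's bin shrunk by a
  relative margin of 0.15 at each edge, then both arms perturbed by
  independent relative Gaussian noise. The margin keeps noiseless draws
  out of the composite-class tolerance band (so zero-noise classification
  recovers the truth exactly) and keeps recovery at 5% measurement noise
  above 95%, the generator's contract. Acrocentric ratios are capped at
  12 for sampling; pair sizes decrease geometrically unless given.
* Meiotic plates: per-bivalent chiasma counts from a categorical
  distribution over {1, 2, 3} (at least one chiasma — bivalents are
  chiasmate by definition); positions from a pericentric/distal/
  interstitial mixture drawn uniformly within the exact regions the
  classifier assigns to those categories, so category recovery is
  well-posed and the estimate's error is pure sampling noise (within 0.02
  of the mixture at 10^4 chiasmata).
* Character evolution: a branch count–scaled Poisson number of changes per
  branch, each change a uniform draw from the other states; all true node
  states are recorded. At one expected change per character on a ten-tip
  tree, Fitch recovers the true root state in well over 95% of replicates.

What the generators do not emulate: correlated measurement error within a
spread, interference between chiasmata, heterogeneous change rates across
branches or characters, and any FISH/CGH signal model. Passing recovery
tests therefore demonstrate estimator correctness under the stated
sampling assumptions, not robustness to those real-data complications.

## Numerical and interface choices

Distances and lengths are dimensionless within an observation (µm or
pixels — only ratios matter). %TCL values sum to 100 within 1e-9 by
construction. All tabular I/O is TSV; trees are Newick with tip labels
matching matrix taxa byte-for-byte (no silent normalization); scenarios
are line-oriented text (`start:`, `sizes:`, `event:`, `expect:`);
pipeline reports are JSON-serializable dicts with a schema version.
Diploid numbers recorded as ranges (conflicting sources) are kept as
ranges and matched only by states that cover them. The karyotype-table
validator enforces 2 × pairs = 2n whenever a full pair list accompanies an
unambiguous 2n, and flags %TCL vectors that do not sum to 100.

## Problem sizes

The packaged analyses are desk-scale: 57 karyotype records, matrices up to
25 taxa × 5 characters, trees up to 25 tips, BFS spaces of at most a few
thousand composition states. The full test suite (including the 500-
replicate recovery study and the 200-case BFS oracle comparison) runs in
well under a minute on one CPU.
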