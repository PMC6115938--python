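# Methods

This note documents the models and procedures implemented in `ensipipe`,
the parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish about real data.

## Assembly QC

Scaffolds are removed when coverage < 10× or length < 200 nt; both
thresholds are configurable and the boundary values are kept (the removal
rule is a strict "less than"). GC% excludes N from both numerator and
denominator — the standard convention; the assembly the thresholds were
designed around is silent on the point, so the behaviour is documented
here rather than assumed elsewhere. N50 is the length of the scaffold at
which the descending-order cumulative length first reaches half the total;
L50 is its rank; ties between equal-length scaffolds are ordered by id so
both are deterministic. "Over 40 kbp" uses a strict `>`. Mean coverage is
length-weighted; a per-scaffold (unweighted) mean is a different statistic
and the ambiguity is flagged in the API docs. Coverage is carried either in
a two-column sidecar TSV or in SPAdes-style `_cov_<x>` header suffixes.

## Fragment ANI

The published analyses used a minimizer-based ANI tool whose internals are
out of scope here. `ensipipe` instead defines a transparent estimator:
non-overlapping 1000-nt query fragments (terminal remainder discarded),
each aligned to its best location in the reference by infix edit-distance
alignment (edlib), identity = 1 − dist/1000, fragments kept at ≥70%
identity, ANI = mean identity of kept fragments. Absolute values can
deviate slightly from minimizer-based tools — edit distance can be
marginally below the Hamming distance when a gap happens to be cheaper —
but on substitution-only divergence the bias is well under the ±0.5-point
acceptance band, and self-ANI is exactly 100. One-way values in the two
directions are averaged for genome pairs; whether a published one-way or
averaged value is being compared against must be decided by the caller.

## BBH, AAI, species clustering

A best hit is the maximal-bitscore hit per query, with a fully
deterministic tie-break: lower e-value, then longer alignment, then
lexicographically smaller subject id. A pair is a BBH when each protein is
the other's best hit and both direction hits pass identity ≥70% and
coverage ≥70% (coverage = alignment length / querying protein length; a
stricter both-lengths mode is a flag). AAI filters the raw tables to
e-value ≤ 1e−12 first, calls BBH at 40%/70%, and averages the per-pair
mean identities; zero qualifying pairs is an error, never an AAI of 0.
CompareM-style tools differ in whether they average per-direction
identities or pair means; pair means were chosen and with symmetric tables
the two agree.

Species are connected components of the graph with an edge where ANI and
AAI both reach the threshold (96% default). Requiring both measures is the
default because the published grouping used both; OR-semantics is a flag.
Missing AAI entries pass with a log message rather than silently breaking
an edge, since AAI matrices are often sparse. Single linkage means the
partition can chain; lowering the threshold can only merge clusters
(monotonicity is property-tested).

## Pangenome analytics

The presence/absence matrix is the pangenome CSV dialect (`Gene`,
`Non-unique Gene name`, `Annotation`, then one gene-id column per strain;
presence = non-empty cell). Core = present in 100% of strains. The Venn
partition over 2–4 focal strains counts families per non-empty presence
pattern restricted to those strains. Unique families are present in the
focal strain and no other strain *in the matrix* — the scope of the strain
set is the caller's statement, not the function's.

Genomic islands: the source analyses visualize islands without stating a
rule, so the rule here is an explicit invention: per scaffold, genes are
ranked by position; maximal runs of unique genes with ≤ `max_gap_genes`
(default 3) intervening non-unique genes form candidates; candidates with
≥ `min_island_genes` (default 4) unique genes are reported. Both
parameters are config-exposed precisely because they are conventions, not
measurements.

COG profiles count one increment per category letter, so a protein
annotated "PC" counts in both P and C (percentages are against annotated
proteins, which can make categories sum past 100%); single-assignment mode
is a flag, as is excluding category S from the annotated total. Pairwise
profile comparison runs one 2×2 Fisher exact test per category with no
multiple-testing correction by default — deliberately matching the
published procedure — with a Bonferroni flag available.

### Fisher exact test

Implemented directly as exact enumeration: with margins fixed, every table
is weighted `w(x) = C(r1, x)·C(r2, c1−x)` as an exact integer; the
two-sided p is the sum of weights ≤ the observed weight divided by
`C(N, c1)`. Integer comparison eliminates the floating-point boundary
problem of deciding whether two tables are "equally probable"; the float
conversion happens once, at the end. The suite cross-checks against
`scipy.stats.fisher_exact` and an independent float hypergeometric
enumeration (relative agreement ≤1e−9 over all tables with N ≤ 60). The
odds ratio is ad/bc with ∞ for a zero denominator with a positive
numerator and NaN for 0/0.

## Model expansion

Models are stoichiometric structures with signed coefficients (negative =
consumed), bounds, boolean GPR strings (`and`/`or`/parentheses; the empty
rule is "not gene-constrained", i.e. true), and one objective reaction.

**Orthology pruning.** Donor genes absent from the donor→recipient
ortholog map (built from BBH at 70%/70%) are deleted. A reaction is
removed iff its GPR becomes unsatisfiable with the deleted genes false;
surviving GPRs are simplified (false literals dropped from `or`,
short-circuit `and`). Orphan metabolites are removed.

**Equation comparison.** Reactions are compared by canonical signature:
metabolites sorted per side, coefficients reduced by exact rational GCD
normalization (floats rationalized with denominator ≤1e6, tolerance
regime ≈1e−9), backwards-only reactions flipped, reversible reactions
oriented so the lexicographically smaller side is left. Classes:
*identical* (signatures equal), *proton_variant* (equal after dropping
protons), *stoich_variant* (equal metabolite sets ignoring protons,
different coefficients), else *distinct*. A proton is a metabolite whose
compartment-stripped id is in a configurable set (default `h`, `h+`,
`proton`); the comparison ignores the proton's compartment only through
that stripping. Only *distinct* donor reactions are transferred, with
bounds, new metabolites, and GPRs rewritten gene-by-gene through the
ortholog map — an unmapped literal in a transferred GPR is a hard error,
because silently dropping it would fabricate gene support. Classification
runs against the *running* model, so a reaction shared by two donors is
transferred once and counted identical the second time.

**Dead-end pruning.** A metabolite is a dead end iff, under the declared
directionalities (forward open when ub > 0, reverse when lb < 0; exchanges
treated identically through their bounds), it cannot be both produced and
consumed. The pass removes every reaction a dead-end metabolite
participates in, then orphan metabolites, and iterates to a fixpoint.
The participant interpretation (rather than producers-only) is the default
because it is idempotent and matches reconstruction practice — removing
only producers leaves consume-only reactions that can never carry flux;
`mode="producer"` preserves the narrower reading. Genes of removed
reactions stay in the gene list (standard behaviour; genes are evidence,
reactions are claims). Removing the objective reaction is a hard error
naming the dead-end metabolites responsible. Dead-end pruning runs once
after all donors by default (`dead_ends_per_donor=True` switches to
per-donor), since the expansion narrative reads most naturally as pruning
"following the expansions" and a second pass after the second donor would
be a no-op on the planted fixtures either way.

## FBA and the carbon screen

FBA maximizes the objective flux subject to S·v = 0 and bounds, with
medium bounds overriding model bounds for listed exchanges; the LP is
solved with HiGHS (deterministic; objective reproducible to 1e−9). Every
optimal solution is checked to steady-state residual ≤1e−6. Objective
value is the only contract: fluxes of a degenerate optimum are not unique
and are never asserted. The screen closes uptake on every declared carbon
exchange, opens one panel source at a time at −`uptake_rate` (default 10
mmol·gDW⁻¹·h⁻¹ — a conventional uptake bound, not a measured one) and
calls growth above `growth_epsilon` = 1e−6. The published 163-source panel
is a platform media set not enumerated in print, so the panel is data (a
YAML list); the shipped fixture panel has two sources with one planted
positive. The objective is whatever the input model declares.

## Symbiosis rules

Stage one collects every query hit by the seed profiles regardless of
e-value (deliberately — the published procedure collects all hits and lets
the second stage discriminate). Stage two takes the top-scoring hit per
query from the full-database scan; ties break by lower e-value then
lexicographic accession — the published rules state no tie-break, so this
is a documented decision. The label is a pure function of the top hit via
the rule table (TIGRFAM accessions, Pfam profile names); versioned
accessions are tolerated by stripping the suffix. Operon presence
(nodABC, nifHDK) is the conjunction of member labels.

## Synthetic fixtures: what they show

The generators plant exact ground truth: substitution-only divergence (so
planted ANI is analytic; no indels, by design — indel support is a
non-goal), decoy hits strictly dominated in bitscore (so BBH truth is
unambiguous; ties are never planted), presence/absence rows constructed
per class, and donor reactions constructed per match class with
transferable pathways built as make+consume pairs over fresh metabolites
(a single-reaction transferable over existing metabolites would fall into
the stoichiometry-variant class by that class's own definition). Scattered
non-island unique genes are placed at a wide, even stride so planted
islands are the only qualifying clusters; when no islands are declared the
stride can be small and island ground truth is not claimed.

Passing tests therefore establish correctness of the *computations* under
these statistical structures. They do not establish robustness to real
data's complications: indels and rearrangements (ANI), paralog ties and
chimeric hits (BBH), fragmented annotation and split families
(pangenome), or compartment and biomass conventions of real
reconstructions (merge/FBA).

The offline assembly-statistics check runs on a synthetic surrogate whose
length/GC/coverage structure is planted to the published draft's summary
values; it verifies the statistics code, not the deposited sequence, which
users can download and pass through `ensipipe stats` themselves.

## Problem sizes

Default test and acceptance runs use 10⁵-nt genomes for ANI recovery,
hit tables up to ~10³ rows, a 6-strain × ~3400-family matrix for the
pangenome counts, 100 seeded model fixtures for merge recovery, and the
exhaustive Fisher sweep over all 2×2 tables with N ≤ 60 (635,375 tables).
These sizes make every planted recovery exact while keeping the whole
suite in the order of a minute.
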