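# Methods

## Model representation and SBML dialects

A model is stoichiometry (dense S, metabolites × reactions), per-reaction
flux bounds in mmol gDW⁻¹ h⁻¹, a boolean GPR per reaction, an optional
subsystem label and a linear objective (the biomass pseudo-reaction, whose
flux is the predicted specific growth rate).  A reaction is irreversible
iff its lower bound is ≥ 0.

Two GPR encodings are read: `fbc:geneProductAssociation` (preferred when
both are present) and the legacy notes-field `GENE_ASSOCIATION:` string —
the yeast consensus-model lineage has used both historically.  Bounds come
from fbc bound parameters or COBRA-style kinetic-law parameters; infinite
bounds are capped at ±1000 (configurable), since flux variability needs
finite ranges.  Subsystems are carried in reaction notes (`SUBSYSTEM:`).
Metabolite ids are taken verbatim; no de-compartmentalization.  Writing
always emits SBML L3 + fbc v2.  An unparseable GPR is logged and the
reaction kept with an empty GPR; an empty GPR evaluates true (the reaction
is not gene-associated, so no deletion can disable it — the COBRA
convention).  In GPR strings, AND binds tighter than OR; parse errors carry
the character position.

## Differential expression

Inputs are log2-normalized gene-level values with WT/MUT sample labels (≥2
samples per group).  Per gene a two-sided Student's pooled-variance t-test
compares the groups (the classic microarray-era default; Welch is available
behind a flag), and the fold change is mean(MUT) − mean(WT) on the log2
scale, so down-in-mutant is negative.  A gene is significantly
down-regulated iff p < α (strict; default α = 0.01, raw p-values — no
multiple-testing correction by default, Benjamini–Hochberg optional).
Zero-pooled-variance genes get p = 0 if the means differ and p = 1
otherwise, flagged as degenerate.  No normalization, probe collapsing or
count modeling is performed; inputs are assumed pre-processed.

## Valve integration

The wild-type reference flux vector is the minimal-total-|flux| point of
the optimal face: FBA, then total absolute flux over all reactions is
minimized with the objective pinned exactly at its optimum.  FBA optima are
generically degenerate; the parsimonious representative makes the reference
— and everything built on it — reproducible run-to-run.

Each reaction touched by ≥1 significant down gene (via GPR leaves; OR/AND
structure is deliberately ignored at this step, matching the leaf-based
mapping the valve rule defines) receives the most negative fold change
among its down genes — the conservative choice when several genes share a
reaction.  With factor φ = 2^FC and reference flux v:

- **cap mode (default):** bounds become [0, φ·v] if v > 0, [φ·v, 0] if
  v < 0; if v = 0 both *original* bounds are multiplied by φ (the valve
  stays meaningful for reactions the WT optimum does not use).
- **fixed mode:** both bounds are set to φ·v.  Fixing many fluxes at once
  is generically infeasible — a model with throttles on several reactions
  usually cannot hold every one of them at an exact value while balancing
  mass — so this literal reading is kept only for fidelity experiments.

Up-regulated genes are excluded: widening bounds cannot change a
maximization optimum.  Positive fold changes are rejected rather than
silently clamped.  Cap-mode constraints are subsets of the original
intervals intersected with the reference-flux sign, so mutant growth never
exceeds the WT optimum; FC → −∞ recovers the switch-based limit.

## LP analyses

One deterministic backend (scipy `linprog`, HiGHS) solves every LP.  FBA
returns the objective f, fluxes x, shadow prices y (equality duals) and
reduced costs w (bound duals), reported on the maximization sign
convention and exposed without interpretation; a strong-duality residual is
attached and checked in tests (< 1e−6).  Infeasible/unbounded statuses are
reported, never silently swallowed.

Carrying-flux counts use a 1e−9 tolerance on |flux|, split by sign.

FVA constrains the objective to ≥ fraction·f* (default fraction 1.0, no
extra slack — HiGHS's own feasibility tolerance is the only slack) and
minimizes/maximizes each reaction flux; `fraction=None` drops the
objective requirement, which is how blocked reactions are detected.
Capacity = max − min; the mutant-vs-WT comparison lists a subsystem as
increased (decreased) when ≥1 member reaction gains (loses) capacity
beyond tolerance, so a subsystem can appear in both lists.

Single-gene deletion evaluates every GPR with the gene absent, zeroes the
bounds of reactions that turn false, and re-solves FBA.  Essential means
growth ratio < 1% of WT (exposed as a flag): "any reduction" would make
nearly every constrained gene essential, so both a strict-reduction
percentage and the cutoff-based essential percentage are reported in the
study tables.

pFBA fixes growth within 1e−6 relative and minimizes Σ|v| over
gene-associated reactions via positive/negative flux splitting.  The
six-way classification assigns, in priority order: essential (deletion
ratio < cutoff) > blocked (no reaction of the gene can carry flux even
with the objective requirement removed) > pFBA optima (some reaction
carries |flux| > tol in the parsimonious solution) > ELE (usable at optimal
growth but unused by the parsimonious optimum) > MLE (usable only below
optimal growth) > pFBA no-flux.  With blocked defined objective-free, any
gene reaching the MLE test necessarily passes it, so pFBA no-flux is empty
under these definitions; the class is kept for completeness of the
standard six-way vocabulary.  The flux tolerance for "carries flux" is
1e−7.

Targeted objectives (acetyl-CoA synthetase / carboxylase style): on a copy
of the model, all objective coefficients are zeroed, the target gets
coefficient 1 and lower bound 0 (the turnover reactions are irreversible),
and FBA maximizes it.

## Enzyme-centric network and centralities

Nodes are genes (the "enzyme" granularity; complexes and isozymes are not
resolved — every GPR leaf is a node).  Two genes are adjacent iff they
annotate the same reaction or their reactions share a non-excluded
metabolite.  Currency metabolites (ATP/ADP/AMP, NAD(P)(H), CoA, CO2, H2O,
H⁺, Pi, PPi) are excluded by name/id match by default, else they connect
nearly everything.

The twelve indices follow the standard hub-detection definitions, computed
within connected components; degenerate conventions: singletons score 0 on
eccentricity/radiality, isolated nodes 0 on MCC/MNC/DMNC.

- MCC: Σ over maximal cliques containing v of (|C|−1)!; a node whose
  neighborhood has no internal edges only joins 2-cliques, so the sum is
  its degree.
- MNC: order of the largest connected component M of the open-neighborhood
  subgraph; ties on order break toward more edges, then lexicographically.
- DMNC: |E(M)| / |V(M)|^ε, ε = 1.7.
- EPC: Monte-Carlo mean (default 1000 realizations, seeded; the seed is
  part of the report) of the size of v's component when each edge is kept
  with probability 0.5; retention 1.0 reproduces the exact component size.
- BottleNeck: one deterministic shortest-path tree per root (each node's
  parent is its smallest-id neighbor one BFS level closer); v scores a
  point for each tree in which it lies on more than a quarter of the
  root-to-node paths.
- Eccentricity (the one index where smaller is more central — ranked
  ascending), Closeness as the sum of reciprocal distances (unreachable
  pairs contribute 0), Radiality as mean (diameter + 1 − distance) within
  the component, Betweenness and Stress over shortest paths, and the local
  clustering coefficient: textbook definitions.

Ranking is per index, ties broken by node id; top-k membership (default
k = 100) is reported for a designated gene set (the down-regulated genes of
each condition).  All twelve indices are verified against exhaustive
brute-force enumeration on seeded graphs of ≤8 nodes, and EPC additionally
against its exact edge-subset expectation on sparse graphs.

## Synthetic data

Expression simulation is Gaussian on the log2 scale: per-gene baselines ~
N(8, 1), measurement noise sd 0.5 in the generic planted benchmark (200
genes, 4 vs 4 samples, 20 genes planted at FC −2 — settings at which the
pooled t-test at α = 0.01 has high but not perfect power, ~0.94 measured),
and sd 0.25 in the multi-condition study so that fold changes of −1.5 to
−2.5 are recovered reliably while −1 remains borderline, which is
realistic for replicate arrays.  Count-level (negative-binomial) simulation
is out of scope: the pipeline consumes log2-normalized values, so the
simulation matches that interface.  Consequently the tests say nothing
about normalization, probe effects or count overdispersion in real data.

Toy models carry analytic optima derived by hand at design time (linear
chain, parallel routes, short-vs-long route, and a classification fixture
with one gene per pFBA category); the seeded random generator guarantees a
feasible growth route via a backbone chain and decorates it with random
branches, reversibility, coefficients and GPRs.  Fixture truths are stored
with the fixture, never computed by the engine under test.

The nine-condition study plants, per condition, a small down-regulated
gene set at a stated fold change in the branched core model (unique-route
steps, a parallel pair, an enzyme complex, an overflow reaction, a
dead-end reaction) plus two non-metabolic filler genes; one condition
plants nothing.  When the throttled step is the only route to a biomass
precursor the growth ratio is 2^FC analytically; redundant or unused steps
leave growth exactly at the WT optimum.  Realized ratios scatter around
2^FC because the valve uses the *estimated* fold change.

## Reproducibility and problem sizes

Every stochastic component (expression simulation, EPC, random models and
graphs) takes an explicit seed; a pipeline re-run with the same config is
byte-identical, and the manifest records versions, seeds and tolerances.
The verification sweeps use 200 random models (≤10 reactions) for the LP
oracle comparison, 50 simulation seeds for the differential-expression
recovery, and 100 random graphs (≤8 nodes) for the centrality oracle —
sizes at which the independent oracles (GLPK via cobrapy; exhaustive
enumeration) are exact and fast.

## Known limitations

- The gene-level enzyme network ignores complex/isozyme structure; an
  AND-complex contributes each subunit as a separate node.
- The valve rule scales bounds by the point estimate 2^FC; no shrinkage or
  uncertainty propagation on the fold change.
- Blocked-gene detection is steady-state only (no thermodynamic loop
  removal), and pFBA no-flux is empty under the chosen definitions (see
  above).
- Shadow prices and reduced costs are exposed but not interpreted.
- No support for kinetic laws, gap-filling, MOMA/ROOM, double deletions or
  dynamic FBA.
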