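# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions taken where the method left
room.

## Differential-expression criterion

Fold changes are signed linear folds (down-regulation as a value ≤ −1, never
a ratio in (0, 1)), which keeps the |FC| > 1.5 phrasing unambiguous.  Both
inequalities of the criterion are strict, so boundary records (FC exactly
−1.5, or p exactly 0.05) are *not* DE.  Genes use the 1.5-fold cut-off,
microRNAs the 2-fold cut-off, both at p < 0.05.  Records with a missing fold
or p are classified not-DE with a logged warning rather than dropped, so
row counts stay stable across a pipeline run.

## Over-representation Z score

The score standardizes the pathway's DE count r by the exact mean and
standard deviation of a Hypergeometric(N, R, n) draw — the classical
MAPPFinder/PathVisio statistic, including the finite-population correction
(N − n)/(N − 1).  It is undefined when the variance vanishes (R = 0, R = N
or n = N); such pathways are skipped with a warning rather than given a
sentinel value.

The reference universe N defaults to the *mapped* measured genes (measured
and attached to at least one pathway of the collection), which is how
pathway tools that work from a collection behave; `universe="all_measured"`
is available because the choice is genuinely ambiguous and changes N.

The permutation p-value shuffles the gene-level DE labels — not the
expression values — and recomputes the score, with add-one smoothing
p = (1 + #{z* ≥ z}) / (1 + n_perm), so p ∈ (0, 1] and p can never be zero
at finite n_perm.  Within one analysis all pathways share the same label
permutations (a data-wide shuffle scored against every pathway), which is
both faster and closer to how a label permutation is defined.  Default
n_perm = 1000.  Because r is integer-valued the permutation p is discrete
and conservative for small pathways; with richly labelled universes (DE
fraction near one half) the null rejection rate at 0.05 sits in the
0.03–0.05 band, which is what the calibration checks assert.

Selection uses Z > 1.96 and permutation p < 0.05 (both strict) and r ≥ 5
(inclusive).  No multiple-testing correction is applied across pathways:
the selection rule is the published three-condition rule on raw permutation
p-values, and the ambiguity is noted here rather than silently "fixed".

## Pathway merging and identifier unification

Gene products and metabolites are rewritten onto unified identifiers through
the mapping table; unmapped nodes keep their original identifier plus an
`unmapped` flag (a state, not an error).  Nodes of one pathway that unify to
the same identifier collapse into one node with the union of their edges;
collapse-induced self-loops are dropped.  Namespaces are kept disjoint by
prefixing: metabolites `met:`, pathway-link nodes `pw:`, group/complex nodes
`grp:<pathway>:<node>`.  Group nodes are deliberately pathway-local — a
"complex" drawn in two diagrams is two distinct nodes — because complexes
drawn in different pathways rarely denote the same molecular species, and
merging them would fabricate linking nodes.

Merging is a union keyed by unified identifier; `pathway_memberships`
accumulates the contributing pathways, and an edge contributed by several
pathways becomes one edge whose provenance lists all of them.  Edges with
identical endpoints but different kinds remain parallel edges distinguished
by kind.  Linking nodes are simply nodes with two or more memberships,
reported sorted by membership count.

## First-neighbour extension

A candidate node joins the network iff (a) it is new, (b) it is DE under the
gene criterion, and (c) it has a PPI edge scoring strictly above 0.4 (the
"medium confidence" convention on a [0, 1] scale) or any TF→target edge to
or from a gene already in the pre-extension network.  PPI candidates are
admitted before TF candidates, so a node reachable both ways counts as a
PPI extension.  All qualifying edges among the final node set are added —
including interactions between pre-existing pathway nodes — so the module
search can traverse them.  Extension never removes anything, and because
every new node is anchored to an existing node the component count cannot
increase.

## Active modules

Gene significance is z_i = Φ⁻¹(1 − p_i) with p clamped to
[1e−10, 1 − 1e−10]; a set A of k genes scores z_A = Σz_i/√k.  Network nodes
without a measured p (metabolites, groups, unmeasured genes) enter at p = 1,
i.e. the lower clamp z ≈ −6.4: they may be traversed as connectors but any
module that includes one pays heavily, which matches the intended semantics
of traversing non-DE hubs.

Because real gene scores are neither independent nor centred, z_A is
calibrated against a Monte-Carlo null: μ_k and σ_k are the mean and sd of
z_A over n_samples (default 500) uniformly random gene sets of each size k,
*without* a connectivity requirement — the null asks how an arbitrary
size-k collection scores, and sampling connected subgraphs instead would
shift μ_k upward on degree-assortative networks (a documented divergence
risk, accepted deliberately).  The corrected score is s = (z_A − μ_k)/σ_k.

Search is greedy seed-and-expand: from each of the `restarts` (default 20)
highest-z genes, repeatedly add the adjacent node that raises s most, stop
when no single addition helps or k reaches `max_k` (default 30).  Ties are
broken by a seeded generator, so runs are reproducible given the seed —
chosen over simulated annealing precisely for that reproducibility and
speed; an annealing refinement (T₀ = 1.0, geometric decay 0.995, 10⁴ steps)
remains available as `strategy="anneal"`.  Candidates are deduplicated,
ranked by s, and reported subject to a pairwise Jaccard cap (default 0.5),
at most `n_modules` (default 10).  Edge direction is ignored during search.

Sign-aware runs (`down_only` / `up_only`) convert the two-sided p into a
one-sided one (p/2 for the matching sign, 1 − p/2 otherwise), so a
down-regulation module is rewarded for coherent sign, not just significance.

On the planted-module benchmark (15 genes at p ~ U(0, 0.001) in a
300-gene interactome with uniform background), greedy recovery sits at
median Jaccard ≈ 0.85–0.95; the residual gap comes from high-z background
neighbours that marginally improve s and are absorbed at the module rim.

## Term enrichment and kappa grouping

Enrichment is the right hypergeometric tail P[X ≥ overlap] over the
annotation universe, BH-adjusted across the tested terms.  The universe
defaults to all genes annotated to at least one term (the behaviour of the
usual GO-clustering tools), not the measured universe; a `universe=`
argument overrides it.

Term similarity is Cohen's kappa over the universe-length membership
indicator vectors, κ = (p_o − p_e)/(1 − p_e), defined as 1 in the degenerate
case p_e = 1.  Terms with κ ≥ 0.4 are connected; each term seeds a group
with its neighbours; two groups merge while they share at least 50 % of the
smaller one's terms; the merged cover is made disjoint by assigning each
term to the group with the highest summed kappa to its members (ties to the
smaller group id).  Each group is named by its member with the smallest raw
enrichment p (ties by term id); isolated terms stay unassigned.  The 0.4
threshold and 50 % merge rule are the conventional defaults of
kappa-clustering enrichment tools and are both exposed as parameters.  The
GO hierarchy is deliberately not modelled: the annotation is a flat
term→genes table, and any level filtering is the caller's concern.

## Regulatory overlay

Each (regulator, gene) pair gets at most one directed edge whose provenance
set lists the supporting linksets, so "present in both databases" is an edge
property rather than a parallel edge, and re-applying the same linksets is a
no-op.  Interactions whose target is absent from the network are skipped and
counted.  DE regulators absent from the overlaid network are reported in two
classes — present in a linkset but with no in-network target, versus absent
from the linksets altogether — because the two failure modes (coverage vs
identifier vintage) have different remedies.  Regulator identifiers are
taken verbatim; no miRNA nomenclature remapping is attempted.

## Synthetic data

The generator emulates the statistical structure of a treatment-response
microarray study: ~5 % DE genes split evenly up/down (DE genes draw
|fold| = 1.5 + Exp(1), p ~ U(0, 0.045); non-DE genes fail the criterion via
a sub-threshold fold *or* a non-significant p, keeping both conditions of
the criterion live), nine up-regulated microRNAs with fold > 2 and no
down-regulated ones, 60 pathways of 20–200 genes with shared-pool overlap,
8 planted pathways with a 30 % DE fraction, a Beta(2, 2)-scored interactome
of mean degree 4, a connected 15-gene planted module wired with
above-threshold scores and anchored to pathway genes, dual-source microRNA
linksets (predicted ≈ 8× validated, ~10 % dual provenance), a flat GO-style
annotation with correlated term families and one term coherent with the
planted module, and a curated regulator list biased toward up-regulated
genes.  Scaled-down sizes (2000 genes, 60 pathways) keep a full bundle under
a second to generate; `paper_scale_config()` (15 000 genes, 276 pathways)
exists for stress runs.

Two deliberate structural choices: planted pathways draw their DE members
from only half of the DE list, so the network of merged pathways captures
part of the DE signal and the interaction-based extension has genuine work
to do (this mirrors the real situation the method was designed for, where
most DE genes sit outside curated pathways); and the planted module's genes
are re-assigned p ~ U(0, 0.001), so the module is a coherent *strong* signal
rather than a random subset of ordinary DE genes.  A fraction (20 %) of
pathway nodes carry synonym xrefs that only the identifier map can resolve,
so unification and node-collapsing are genuinely exercised.

What the generator does **not** emulate: probe-level intensities and
normalization, realistic gene symbols, pathway topology beyond random trees,
degree heterogeneity (hubs) in the interactome, correlated expression
noise, and miRNA seed-match biology.  Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated
statistical structure — not performance on real arrays, where identifier
vintage, annotation bias and correlated noise all degrade recovery.

## Numerical conventions

- Permutation and Monte-Carlo procedures take explicit seeds; all
  tie-breaks (ranking, greedy expansion, group assignment) are resolved by
  seeded draws or lexicographic order, so same-seed runs are byte-identical
  down to the written files.
- Network files are written with nodes and edges sorted by identifier;
  set-valued attributes are serialized as sorted JSON arrays inside GraphML.
- p-value clamps: gene z-scores at 1e−10; permutation p floors at
  1/(n_perm + 1).
- Duplicate PPI rows keep the maximum score (conservative toward inclusion
  at a fixed threshold); duplicate curated-list entries keep the maximum
  report count.
- Degenerate inputs fail loudly: zero-variance Z scores, empty queries,
  all-identical calibration scores and conflicting identifier mappings are
  errors, while unmapped identifiers and missing measurements are flagged
  states.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run at: exhaustive Z-score
enumeration to N = 40 (tests) / N = 25 (script); 500 null pathways × 200
permutations for permutation calibration; 1000 random sets for the module
null; 10 seeded 300-gene scenarios for planted-module recovery; and 5–10
full pipeline runs at generator defaults for end-to-end recovery.  These
sizes were chosen so the whole suite completes in a couple of minutes on one
CPU while keeping the Monte-Carlo bands meaningful.

## Known limitations

- The greedy search optimizes locally; it can absorb high-scoring rim nodes
  and has no backtracking (annealing mode mitigates, at a runtime cost).
- The permutation p is conservative for small pathways (discreteness), so
  very small pathways need a large r to pass the selection rule.
- Group/complex semantics are lost at merge boundaries by design
  (pathway-local groups); analyses that need cross-pathway complex identity
  must unify complexes upstream.
- The kappa grouping depends on the annotation universe; switching between
  the annotated-genes universe and the measured universe changes κ values
  and hence group structure.
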