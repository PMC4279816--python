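# Methods

## Problem and data model

Fluorescent-fusion imaging classifies a subset of bacterial enzymes as
*localized* (discrete punctate cytoplasmic foci) versus diffuse. The
analyses here ask two questions about that label. First, within Elementary
Flux Patterns — ordered routes of L reactions through a metabolic
subsystem, consumed as input, never computed from a stoichiometric model —
do localized enzymes preferentially occupy the first or last position?
Second, in the genome-scale reaction network, do the reactions catalyzed by
localized enzymes occupy topologically distinctive positions (more loops,
higher within-group connectivity, lower clustering)?

Inputs are flat text: 4-column reaction TSVs (id, substrates, products,
genes; one file for irreversible, one for reversible reactions), a
localized-gene list, an EFP table (one ordered comma-joined reaction list
per line), and category membership tables with an explicit gene universe.

## Reaction adjacency

The network is a directed Boolean matrix M over reactions: M_ij = 1 iff
some compound is an output of i and an input of j. For an irreversible
reaction outputs = products and inputs = substrates; a reversible reaction
can run either way, so both roles are unioned on both sides — the minimal
reading of "feeds into" consistent with reversibility. Self-edges are
removed: they would contribute trivial length-1 cycles to every loop
statistic. Reactions are deduplicated by id.

Ubiquitous currency metabolites (water, ATP, pyruvate…) would otherwise
connect most of the network into one spurious clique, so compounds with a
connection count strictly above a threshold (default 60) are excluded
before edges are formed. A compound's connection count is its number of
(reaction, role) incidences — substrate and product roles count once each
per reaction; a per-reaction counting mode is available
(`count_mode="reaction"`), since the literature rarely states which is
meant. Exclusion is applied before edge creation, which makes the edge set
monotone in the threshold (a property test asserts this).

Localization propagates from genes to reactions by an OR rule: a reaction
is localized iff any catalyzing gene is labeled. This is the only rule that
maps more labeled genes onto fewer labeled reactions, matching how gene
lists reduce to reaction lists in practice.

## Positional nulls for EFPs

For each length L, the observed statistics are the fraction of EFPs
(conditioned on k ≥ 1 localized) with a localized first *or* last step, and
the fraction (conditioned on k ≥ 2) with localized first *and* last steps.

*Permutation null.* Each draw independently re-places every eligible EFP's
k flags uniformly over its L positions and recomputes the ratio; the
p-value is one-sided (observed high) with add-one smoothing,
p = (1 + #{draws ≥ observed}) / (1 + n_draws), so p is never 0 and the test
is exact-conservative. Two samplers are provided: a literal per-EFP shuffle
and a stratified sampler that draws, for each (L, k) stratum of m EFPs, a
Binomial(m, p_hit) count with p_hit = 1 − C(L−2, k)/C(L, k) (or
k(k−1)/(L(L−1)) for the both-terminals statistic). Because per-EFP hit
indicators under the shuffle are iid Bernoulli(p_hit), the two samplers
draw from the identical distribution; the stratified one is the default
(orders of magnitude faster) and a test checks their agreement.

*Closed-form null.* With q(k;L) the empirical probability that an EFP of
length L carries exactly k flags (conditioned on k ≥ 1, matching the
conditioning of the observed ratios; an unconditioned variant is a flag):

    P(first | L) = Σ_k (k/L) q(k;L) = P(last | L)
    P(first ∧ last | L) = Σ_{k≥2} [k(k−1)/(L(L−1))] q(k;L)
    P(first ∨ last | L) = 2·P(first | L) − P(first ∧ last | L)

These are exact expectations of the permutation null, verified against
brute-force enumeration of all C(L, k) placements for every L ≤ 8.

EFPs outside lengths 3–12 are dropped at load time with a warning (the
analyzed range); a reaction appearing twice in one EFP keeps per-position
flags, and permutation shuffles positions, not identities.

## Loop statistics

[Mⁿ]_ii counts closed directed walks of length n through node i (n = 2..7).
Walks, not simple cycles: a 2-cycle traversed twice contributes to n = 4 —
that is what the matrix power defines, and it is kept as such. The
feed-forward measures are the diagonals of M Mᵀ M and M Mᵀ M Mᵀ. They are
proxies, not literal triad censuses: on the canonical feed-forward triad
A→B, B→C, A→C the FFL3 diagonal is (0, 1, 0), concentrated on the
intermediate node. The formulas are implemented verbatim and documented as
such rather than "corrected". [M Mᵀ]_ii equals out-degree for Boolean M and
serves as the connection count; loop density is count/connections, with
zero-out-degree nodes *excluded* (0/0 is undefined; imputing 0 would drag
the group containing more sinks toward zero and bias the contrast).

All powers use exact integer arithmetic. Products run in int64 behind an
explicit pre-multiply bound (max entry × max column sum < 2⁶²) and fall
back to arbitrary-precision object arrays if the bound could be exceeded;
float drift would otherwise corrupt the ranks used by the KS tests.

Group contrasts use the two-sample KS test. The default alternative is
"localized stochastically larger" (mapped to scipy's CDF convention); a
two-sided variant is a flag. The random-group null re-samples groups of the
observed size uniformly without replacement (default 10⁵ draws), reporting
the empirical p and a z-score (observed − null mean)/null sd.

## Group structure

Within-group connectivity (wgc) is the probability that an ordered pair of
distinct group members is joined by a directed edge: internal edges /
g(g−1). Unordered-pair and per-node normalizations are selectable because
published wgc values rarely state the denominator; the ordered-pair reading
is the one under which wgc is a directed-edge probability, and the whole
node set's wgc then equals the global edge density. The contrast statistic
is wgc(group) − wgc(complement) against random same-size groups.

Clustering coefficients and triangles deliberately ignore direction (the
loop statistics are the direction-aware counterpart): both are computed on
the symmetrized simple graph. Nodes of undirected degree < 2 get
coefficient 0 and are included (exclusion is a flag). Triangles are
3-cliques counted once each and classified by how many of their three
vertices are localized; the headline ratio is t(1 localized) /
t(2 localized). Expected value under a random mask with localized fraction
f is (1−f)/f — the binomial-composition oracle a property test checks.

Degree-preserving surrogates use directed double-edge swaps: pick edges
(a→b), (c→d), replace with (a→d), (c→b) unless a self-edge or duplicate
would arise. Default 10×|E| successful swaps (a common mixing heuristic),
attempts capped at 100× that with a logged shortfall; a degree sequence
admitting no swap returns the original with a rigidity warning. The
localization mask stays attached to nodes. The surrogate ensemble's
triangle ratio is compared to the observed value by a one-sample t test;
one- and two-sided p-values are both reported since the direction
convention varies across publications.

## Enrichment and scaling

Category enrichment is the one-sided hypergeometric upper tail
P(X ≥ n_loc_in_cat) (identical to Fisher's exact test for
over-representation; cross-checked against an exact enumeration oracle and
scipy's `fisher_exact` in tests), with expected count n_cat·|localized|/
|universe|. The gene universe is a required explicit input — enrichment is
meaningless without one, and the package never assumes it. No
multiple-testing correction by default; Benjamini–Hochberg is a flag.

Pathway scaling reports the Pearson correlation of log(length) vs
log(n_localized) over pathways with n_localized > 0, plus the mean
length/n_localized ratio.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
real biochemistry: random reaction–compound bipartite structure with a few
high-incidence hub compounds (wired into more reactions than the exclusion
threshold), reversibility flags, one gene per reaction, and localization
labels drawn independently per gene.

* `wgc_boost` b: a localized reaction draws each substrate from the pool of
  localized-reaction products with probability 1 − 1/b (else uniformly).
  At b = 1 assignment is independent of labels — an exact null.
* `terminal_enrichment` t: an EFP's k flag positions are sampled without
  replacement with the two terminal positions at odds t against 1
  (Gumbel-top-k, equivalent to sequential weighted sampling). At t = 1
  placement is uniform, exactly the closed-form null's regime; for k = 1,
  L = 7, t = 10 the terminal-hit probability is 20/25 = 0.8 (a test pins
  this).
* `planted_enrichment`: planted categories over-sample localized genes by
  these odds.

Parameterizing effects as odds (not fixed ratios) keeps the analytic nulls
correct at multiplier 1. What the generator does **not** model: true KEGG
stoichiometry, flux feasibility, mass balance, thermodynamics, correlated
pathway membership, or the heavy-tailed compound-degree distribution of
real metabolism. Passing tests therefore demonstrate statistical
correctness and calibration of the machinery, not biological conclusions
about any organism.

Defaults (300 reactions, 150 compounds, 2000 EFPs, 25% localized genes,
30% reversible, 3 hubs at incidence 80) keep a full pipeline run under a
minute while leaving every contrast estimable; all generators are
deterministic in (config, seed).

## Orchestration and determinism

A master seed derives one sub-seed per stage by stable name hashing
((master·1000003 + crc32(stage)) mod 2³¹), so extending one stage's draws
never perturbs another. The consolidated report persists every analysis
switch, the seed, a config hash and per-stage tables; reruns are
byte-identical up to timestamp and output path. `reproduce` recomputes the
published E. coli headline quantities when the original supplementary
tables are supplied as fixtures and reports per-target "skipped" otherwise.

## Test problem sizes

The suite calibrates type-I error over 400 null replicates (150-reaction
networks, 400-EFP sets, 499-draw nulls), checks permutation/closed-form
agreement on 50 sets of 2000 EFPs at 10⁴ permutations, validates loop
counts against a DFS closed-walk enumerator on 200 random digraphs of ≤ 12
nodes, and degree preservation on 10⁴ rewired networks — sizes chosen so
the statistics are well-resolved while the whole suite stays fast.

## Known limitations

* The FFL measures are diagonal proxies; they do not count feed-forward
  triads and should not be read as motif censuses.
* The hub-exclusion connection count and the wgc normalization are
  field-ambiguous; both expose switches, and cross-study comparisons should
  state which convention is used.
* Empirical p-values are bounded below by 1/(1 + n_draws); very small
  published p-values can only be matched by raising the draw count.
* The closed-form null conditions on the realized q(k;L); it is a null of
  *placement*, not of *abundance*, and says nothing about why some EFPs
  carry more localized enzymes than others.
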