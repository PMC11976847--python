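# Methods

## Associated networks and the association coefficients

Pathway networks are simple undirected graphs over uppercase-normalized
gene symbols; self-loops are dropped at parse time and every module uses
the lexicographically sorted pair as the canonical edge form.

The associated network a-b of pathways *a* and *b* has node set
V<sub>a</sub> ∪ V<sub>b</sub> and edge set E<sub>a</sub> ∪ E<sub>b</sub> ∪ D,
where D are the *derived* edges: reference-interactome interactions whose
endpoints both lie in the union but which belong to neither input edge
set. The interactome contributes edges only, never nodes. Each node is
labeled `a_only` / `b_only` / `shared`, each edge `a_only` / `b_only` /
`overlapping` (in both edge sets) / `derived`; the labels are exhaustive
and exclusive, and all counts are read off them.

Two deliberate definitional choices:

- **"Overlapping edge" means present in both edge sets**, not merely
  joining two shared nodes — parallel to the overlapping-node definition.
- **Derived edges are not restricted to cross-pathway pairs** by default:
  any interactome edge between union nodes absent from both pathways
  qualifies, because reconstruction from protein interactions carries no
  side restriction. A stricter variant that keeps only edges bridging
  the two pathways is available as `derived_mode="cross-only"`
  (`--derived cross-only` on the CLI).

The coefficients are C_N = N_r/N_ab, C_E = (E_r+E_d)/E_ab and the
root-mean-square C = sqrt((C_N²+C_E²)/2). When E_ab = 0 the edge
coefficient is undefined and C reduces to C_N; the same reduction is
applied verbatim to the weighted coefficient C_w (the edgeless rule is
only stated for the unweighted case in the method's original
formulation; extending it keeps C_w well-defined on degenerate inputs).

Weighted coefficients divide the weight sum over shared nodes
(overlapping ∪ derived edges) by the weight sum over all nodes (edges).
Uniform weights therefore reduce them exactly to the unweighted
coefficients — a property the test suite checks to 1e-12.

## Topology indicators

Five per-node indicators feed the ranking, all positively oriented and
all on unweighted (hop-count) shortest paths:

| indicator | definition | default range |
|---|---|---|
| degree centrality | deg(v)/(n−1) | [0, 1] |
| betweenness | normalized Brandes betweenness | [0, 1] |
| closeness | Wasserman–Faust component-corrected | [0, 1] |
| clustering | local triangle density; 0 when deg < 2 | [0, 1] |
| topological coefficient | NetworkAnalyzer convention (below) | [0, 1] |

The topological coefficient of v (degree > 1) averages, over all nodes m
sharing at least one neighbor with v, the count of shared neighbors plus
1 if m is adjacent to v, normalized by deg(v); nodes with degree ≤ 1 or
no neighbor-sharing partner score 0. This is the Cytoscape
NetworkAnalyzer convention, the de facto standard in pathway analyses.

Choices on the open points: associated networks are frequently
disconnected, so closeness uses the Wasserman–Faust component-size
correction, which keeps the indicator finite and positively oriented;
whether centralities are normalized is immaterial downstream because
TOPSIS standardization is scale-invariant per column (verified by a
property test). Edge betweenness values are raised by a floor of 1e-9 so
weighted edge sums can never be identically zero.

## Entropy weights and TOPSIS

Column shares p<sub>ij</sub> = x<sub>ij</sub>/Σ<sub>i</sub>x<sub>ij</sub>
are computed on the raw nonnegative indicator values (the topology
module guarantees nonnegativity; negative input is an explicit error,
never a silent shift). Entropy e<sub>j</sub> = −(1/ln n)·Σ p ln p with
0·ln 0 = 0; a constant column — including an all-zero one — is assigned
entropy exactly 1 (zero weight) rather than trusting floating-point
cancellation. Weights are w<sub>j</sub> = (1−e<sub>j</sub>)/Σ(1−e);
if every column is constant the method degenerates and uniform weights
are used with a logged warning. A single-row matrix is an error
(entropy over one object is undefined).

TOPSIS standardizes by column Euclidean norm (zero columns stay zero),
applies the weights multiplicatively (v = w ⊙ z), takes the column-wise
max/min of v as ideal and anti-ideal points, and scores each node
c = D⁻/(D⁺+D⁻); identical rows score 0.5 by convention. Whether the
weights sit inside the distance or in the matrix is a known ambiguity of
entropy-TOPSIS couplings; the weighted-matrix convention used here is
the common one and is fixed throughout. Key nodes are those with
c > 0.6, strict, sorted by descending score with lexicographic
tie-breaks. When TOPSIS scores serve as association node weights they
are floored at 1e-6 so the worst-ranked node never vanishes from
weighted sums.

## Protected k-core decomposition

Given a protected set (key proteins ∪ DEPs present in the network), the
protected k-core repeatedly deletes any *non-protected* node of current
degree < k together with its incident edges. Protection shields the
node itself — a protected node's surviving edges still count toward its
neighbors' degrees, since the decomposition preserves survivors' nodes
*and* incident edges and there is no contrary rule. The result is
independent of removal order (the removable set only grows as degrees
drop; verified against randomized one-at-a-time removal).

The maximum coreness Ks is the largest k at which the protected k-core
retains at least one non-protected node. Defining Ks by non-protected
survival is necessary: a fully protected residue survives every k, which
would otherwise make Ks unbounded. With an empty protected set the
procedure reduces exactly to the textbook core decomposition (checked
against an independent core-number computation).

The final curation step — supplementing the target network with
pathway-biology knowledge — is inherently manual; the pipeline supports
it only as an explicit user-supplied amendment file
(`add_node`/`remove_node`/`add_edge`/`remove_edge` lines), never
automatically.

## DEP filter

A protein is differentially expressed when p < p_max and |log2FC| >
min_abs_lfc, both strict, with defaults p_max = 0.05 and min_abs_lfc = 0;
boundary rows are excluded. The filter uses whatever p-value column is
supplied and applies no multiple-testing adjustment of its own. The
filter is monotone in both thresholds (property-tested).

## Pipeline

Stage order: DEP filter → pathway resolution → pairwise association
matrix → top pair → topology → entropy weights → TOPSIS → key nodes →
protected maximum core → optional amendment → report. The stage order
resolves a genuine circularity: weighted association needs TOPSIS node
weights, which need the topology of the pair's own associated network —
so in weighted mode the full topology→entropy→TOPSIS→weighting chain is
recomputed independently for every pair, never shared across pairs.
Correctness is preferred over speed here; the matrices involved are
small.

Pathway names resolve to edge-list files in a networks directory when
present (with an optional `<name>.nodes.tsv` companion carrying isolated
nodes), else to the reference interactome induced on the pathway's GMT
gene set — a gene-membership list carries no edges of its own, so
interactions are borrowed from the interactome. `+`-joined names denote
pathway combinations (node/edge union).

All outputs use fixed column orders and 6-decimal fixed-point
coefficients; `report.json` rounds to 10 decimals and sorts keys, so
identical configuration and inputs yield byte-identical artifacts.

## Synthetic data

`synth_pathway_pair` generates two Erdős–Rényi graphs over partially
shared node sets: exactly `n_shared` common nodes, independent edge
probability `p_edge`, and an interactome equal to the union of both
pathway edge sets plus exactly `n_derived` extra edges drawn uniformly
from the unused union pairs. `synth_quant_table` gives a chosen fraction
of proteins p-values below 0.05 and the rest above it, with N(0, σ)
log2 fold changes.

The acceptance study (`scripts/acceptance.py`) uses an engineered pair
of 40-node pathways sharing 15 nodes (65-node union, edge density 0.10,
10 derived interactome edges), three disjoint distractor pathways of
25–30 nodes, and a 150-protein quantification table with a 20% DEP
fraction — sizes comparable to a single enriched-pathway pair in a real
proteomics study, and small enough that every quantity is recomputed
from scratch in seconds.

What the generator does *not* emulate: scale-free degree structure of
real interactomes, correlated pathway membership, annotation noise, or
p-value/effect-size correlation. Passing tests therefore demonstrate
algorithmic correctness and determinism, not biological validity of any
particular association.

## Known limitations

- Association coefficients carry no significance measure; the method
  assigns none, and none is invented here.
- The TOPSIS threshold 0.6 and the DEP thresholds are conventions of the
  method, not fitted quantities.
- Real studies build pathway networks with external services (database
  enrichment, physical-interaction extraction); this package starts from
  their exported edge lists and does not query any service.
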