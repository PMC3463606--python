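# Methods

## Typed regulatory network

Nodes carry one of three types — TF, miRNA, gene — and only TFs and miRNAs
may be arc sources. The type of a regulator is fixed by the edge-list file it
regulates in; an id regulating in both files is an error rather than a silent
override, and a regulator that appears as someone's target keeps its
regulator type. Self-loops are dropped at load (counted in the load report)
because the size-3 motif machinery and the clustering-coefficient definition
assume simple digraphs. miRNA→miRNA and miRNA→TF arcs are allowed: the
backtrack treats every upstream regulator uniformly. Node ids are opaque,
case-sensitive strings; no alias resolution is attempted.

## Active sub-networks

The activity rule is either `absolute:x` (log2 expression strictly greater
than x) or `percentile:p` (strictly greater than the per-time-point p-th
percentile). The default is `percentile:50`: the threshold behind the
original analysis is unpublished, and a per-time-point median is
scale-free and produces comparable sub-network sizes across time points.
With this rule, housekeeping status ("active at every time point") uses the
same cut, and a gene active at several but not all time points belongs to
each of those time points' specific sets — the set-algebra reading of the
definitions, applied literally.

Backtrack closure is reverse reachability: since only regulators have
out-arcs, repeatedly adding every regulator with an arc into the current set
terminates at the set of nodes with a directed path into the seed set. The
operation is idempotent and monotone, and the implementation is checked
against a brute-force reverse-BFS oracle.

## Topology

- Clustering coefficient uses the union neighborhood N(v) and counts
  *directed* arcs among it over |N(v)|·(|N(v)|−1) ordered slots; nodes with
  |N(v)| < 2 score 0 and are included in the mean (exclusion available via
  the per-node table).
- Betweenness is the raw sum of geodesic fractions over ordered pairs with
  both endpoints distinct from v (no normalization), computed via Brandes'
  algorithm (networkx) and cross-checked against a geodesic-counting oracle.
- Average path length is taken over *reachable* ordered pairs only; the
  reachable-pair count is reported alongside so the denominator is explicit.
  Empty denominators (arcless networks) yield NaN, never 0.
- Mean out-degree averages over regulators only, mean in-degree over nodes
  with at least one regulator, matching the regulatory reading ("targets per
  regulator", "regulators per target").
- The size-matched null resamples the sub-network's per-type node counts
  uniformly from the static network, re-applies backtrack + induced wiring,
  and aggregates metrics with nanmean/nanstd (sample SD, ddof = 1).
- Hub removal uses total degree (in + out, so a mutual pair counts twice),
  recomputed after every removal, ties broken by lexicographic node id;
  singletons are remaining degree-0 nodes that were connected in the input.

## Motifs

Motif identity is the typed-isomorphism class of the connected 3-node
induced sub-graph: the canonical label is the lexicographic minimum over all
six node permutations of `(type triple):(6 adjacency bits)`. This implies
equality of each node's in/out degrees and incoming/outgoing neighbor-type
compositions, and is the cleaner formalization of that classification rule.
Enumeration is Wernicke's ESU specialized to k = 3, which yields each
connected triple exactly once; counting goes through a precomputed
(27 type-triples × 64 arc patterns) label table. RML is tagged on any motif
containing a 2-cycle between two regulators (full canonical labels are
reported, so finer splits remain available); FFL/SIM/CRM require exactly the
defining arcs and nothing else.

The null permutes arcs by double swaps in which the partner arc must share
the (source type, target type) pair and the swap is rejected if it would
create a self-loop or duplicate. These conserve, exactly: arc count, every
node's in/out degree, and every node's in/out neighbor-type histograms
(asserted over 100 random networks in the tests). The swap budget defaults
to 10·|E| attempts — "random enough" is unquantified in the field, and at
10·|E| the achieved-swap acceptance is logged so the mixing is auditable.
Z = (observed − null mean)/null SD with sample SD; SD = 0 yields NaN (an
explicit undefined marker, never ±∞). Labels seen only in the null or only
in the real network enter with count 0 on the missing side. Family-level Z
aggregates raw counts per family per replicate before computing moments.

`motif_dynamics` runs every network in a series against nulls with a shared
seed (common random numbers), so identical networks produce identical Z
columns; time-point clustering of the Z matrix imputes NaN as 0, uses
Euclidean distance and average linkage, and reports the merge tree (Newick)
plus the 2-group cut.

One structural caveat: because the null preserves every gene's in-degree,
shared-target counts are nearly degree-determined, and destroying the A→B
arc of an FFL turns that triple into a CRM in the null. CRM Z is therefore
*anti*-signed in FFL-rich networks and is weakly informative on its own;
directional claims in the tests rest on RML, FFL and SIM.

## Correlation randomization

Pearson correlations between each measured miRNA and its measured targets
are binned over [−1, 1] (default width 0.05, right-closed, −1 folded into
the first bin). Each randomization replaces every miRNA's target set by an
equal-sized uniform sample (without replacement) of measured genes — true
targets are not excluded from the pool, since at realistic scales the bias
is negligible and the simpler null is exactly reproducible. Pairs with an
unmeasured or constant-profile endpoint are excluded and counted. Z per bin
as above; the observed histogram total is seed-invariant and the null
preserves per-miRNA target-set sizes exactly.

## Enrichment

Upper-tail hypergeometric probability P(X ≥ k) (over-representation only),
via `scipy.stats.hypergeom.sf`, validated against exhaustive draw
enumeration for every (c, k, G, n) with G ≤ 12. The universe defaults to the
measured genes rather than network membership — measurement, not wiring,
defines who could have been drawn — and is overridable. The Bonferroni
denominator is the number of terms with at least one universe gene (the
family of tests actually performed); terms with zero overlap are omitted
from output but counted there. e-value = k/(c·n/G); significance thresholds
are left to the user, raw numbers are always reported.

## Synthetic data

The generators emulate the study conditions: ~6 ordered time points; gene
and miRNA clusters peaking at distinct time points (Gaussian bump of log2
amplitude 4 and width 1 over baseline 6, noise SD 0.5); 30% of miRNA→gene
pairs rewritten to anti-correlated profiles (mirror around the mean, noise
SD 0.2) plus a 5% positively correlated tail; a static network of 10 TFs /
30 miRNAs / 800 genes — a desk-scale rendition of the 44 TF / 284 miRNA /
~17k-gene system — with regulator out-degrees from a capped discrete power
law (exponent 2.5, floor 2, cap 80; the real degree law is unknown, so this
is a config knob) and 50 planted feed-forward loops (TF→miRNA→gene).

Per-time-point regime networks (6 TF / 10 miRNA / 120 genes each; 3 early,
3 late) encode the two developmental phases. Early: every gene redundantly
regulated by 3 regulators, plus 25 planted mutual regulator pairs with an
attached gene; reg–reg arcs exist *only* inside those pairs so that
reciprocity is a genuine signal the degree-preserving null cannot mimic.
Late: hub-and-spoke modules (each regulator owns an exclusive gene block), 6
one-way bridges, 25 planted FFLs and 15 planted CRMs whose shared targets
come from a reserved pool regulated by exactly the two planted regulators.
This yields, by construction: higher clustering and hub-robustness early,
modular fragility late (hub removal isolates module genes), RML enrichment
early, FFL enrichment late.

Every generator is a pure function of (config, seed); per-generator streams
derive from `SeedSequence(seed, spawn_key=(k,))`. Manifests record planted
triples, cluster assignments and realized pair correlations, sufficient to
verify every planted property independently.

What the generator does **not** emulate: microarray noise structure (probe
effects, intensity-dependent variance), the real — much higher — edge
density and hub sizes of genome-scale networks, correlated TF/miRNA
activity, or a mechanistic model of repression (anti-correlation is planted
by profile reflection, since only correlations are consumed downstream).
Passing tests therefore demonstrate that the *machinery* recovers known
structure under the stated statistical assumptions, not that the biological
conclusions transfer to any particular real dataset. One known divergence:
the synthetic early regime encodes reciprocity directly at the pair level,
so 2-node mutual motifs come out enriched there, whereas three-element
mutual loops can be enriched without the bare two-element motif being so in
real data.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale: metric and enumeration
oracles on graphs of ≤ 12–30 nodes; planted-motif recovery on the default
840-node network with 200-replicate motif nulls; regime analyses with
60–100-replicate nulls per network; correlation tests with 200
randomizations; topology nulls of 3–300 replicates depending on context.
Full-scale conventions (1000 motif/correlation randomizations, 300 topology
replicates) remain the library defaults. Throughout: sample SD (ddof = 1)
in all Z denominators; NaN as the undefined marker (never infinities);
right-closed correlation bins; strict inequality at activity thresholds;
lexicographic tie-breaks wherever order matters, so every result is
reproducible bit for bit under a fixed seed.

## Known limitations

- Exact betweenness/APL are O(|V|·|E|); the package targets desk-scale
  networks (thousands of nodes), not genome-scale ones.
- Edge swapping can mix slowly on networks with highly constrained type
  classes (e.g., a single arc per class returns a logged copy).
- Activity is node-level only; condition-specific *edge* activity is out of
  scope, as are soft/probabilistic activity calls.
- GO-style DAG propagation, FDR beyond Bonferroni, and under-representation
  tests are deliberately not implemented.
- The counts of network nodes vs measured entities are treated as
  independent facts; no reconciliation between network membership and
  measurement coverage is attempted.
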