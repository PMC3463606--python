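# retnetdyn

Dynamics of gene-regulatory networks built from transcription factors (TFs),
microRNAs and their target genes, modeled on developing-retina time-course
studies. Static regulatory wiring (TF→target from ChIP-type evidence,
miRNA→target from target prediction) is combined into one typed directed
network; per-time-point **active sub-networks** are carved out of it with
expression data; and the dynamics of those sub-networks are characterized by
topology, network-motif usage, and functional enrichment. The package is
aimed at systems-biology analyses of developmental time courses where the
question is not *which* genes are expressed but *how the regulatory circuitry
reorganizes* over time.

## What it computes

**Active sub-networks.** At time point *t* the initial active set is every
entity expressed above a threshold (absolute log2 value or per-time-point
percentile). A *backtrack closure* then repeatedly adds every TF/miRNA with
an arc into the current set — regulators count as active regardless of their
own expression, since master regulators need not be highly expressed — until
a fixpoint. The sub-network is the static network induced on the closure.

**Topology.** Per network: mean out-degree over regulators, mean in-degree
over regulated targets, clustering coefficient

CC(v) = |{(i,j) ∈ E : i,j ∈ N(v), i ≠ j}| / (|N(v)|·(|N(v)|−1)),

with N(v) the union of in- and out-neighbors; betweenness
BW(v) = Σ_{s≠t≠v} σ_st(v)/σ_st (raw, directed geodesics); average directed
shortest-path length over reachable ordered pairs; and reachability (fraction
of other nodes reachable from v). Significance comes from size-matched random
sub-networks: the same per-type node counts are resampled from the static
network and re-closed/re-wired. A hub-removal curve (remove the current
highest-degree node, count newly isolated singletons) probes robustness.

**Motifs.** All connected 3-node induced sub-graphs are enumerated with
Wernicke's ESU algorithm and classified up to *typed* isomorphism (node types
TF/miRNA/gene enter the motif identity). Families: RML (two regulators in a
mutual 2-cycle plus an attached third node), FFL (A→B, A→C, B→C), SIM (one
regulator, two targets), CRM (two regulators, one shared target). Each motif's
count is compared with degree-preserving random networks generated by double
arc swaps restricted to arcs with matching (source type, target type) — these
conserve every node's in/out degree *and* neighbor-type composition — giving
Z = (observed − null mean)/null SD. Clustering time points on their motif
Z-profiles reveals regime shifts that raw expression clustering misses.

**miRNA–target correlation.** Pearson correlations of miRNA/predicted-target
expression are binned over [−1, 1] and compared against randomizations that
give each miRNA an equal-sized random target set, yielding a Z per bin.

**Enrichment.** Hypergeometric over-representation P(X ≥ k) of annotation
terms (GMT format) in time-point-specific gene sets, Bonferroni-corrected,
with e-value = k/(c·n/G) (observed/expected overlap).

Because the original microarray and ChIP/target-prediction inputs are not
redistributable, a seeded synthetic-data generator (`retnetdyn.syndata`)
produces all inputs with the structure the analysis assumes: clustered
time-course profiles, planted anti-correlated miRNA targets, hub-dominated
networks with planted motifs, and early (interconnected) vs late (modular)
per-time-point regimes.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data.
For instance:

```
$ python analysis/05_motif_dynamics.py --seed 1
family z per time point (vs degree-preserving null):
  E15    [early] {'CRM': '+3.7', 'FFL': '-5.4', 'RML': '+6.4', 'SIM': '-6.9', 'other': '-6.7'}
  E18    [early] {'CRM': '+4.3', 'FFL': '-5.9', 'RML': '+6.6', 'SIM': '-7.1', 'other': '-7.0'}
  P1     [early] {'CRM': '+3.1', 'FFL': '-4.9', 'RML': '+5.6', 'SIM': '-6.0', 'other': '-5.9'}
  P5     [late ] {'CRM': '-3.0', 'FFL': '+5.0', 'RML': '-2.0', 'SIM': '+1.3', 'other': '+1.4'}
  P12    [late ] {'CRM': '-4.8', 'FFL': '+5.4', 'RML': '-1.3', 'SIM': '+0.5', 'other': '+0.6'}
  Adult  [late ] {'CRM': '-3.2', 'FFL': '+4.8', 'RML': '-1.4', 'SIM': '+0.6', 'other': '+0.5'}
2-node mutual pairs at E15: observed=25 z=7.4
motif-Z 2-cut of time points: [['E15', 'E18', 'P1'], ['Adult', 'P12', 'P5']]
expression 2-cut of time points: [['E15', 'E18'], ['Adult', 'P1', 'P12', 'P5']]
```

Mutual-loop motifs (RML, z ≈ +6) dominate the early interconnected networks
and feed-forward loops (z ≈ +5) the late modular ones; clustering time points
on motif Z-profiles recovers the early/late split exactly, while clustering
the same time points on raw expression does not. The other scripts cover data
generation (01), expression clustering and the correlation randomization
(02), active sub-network extraction (03), topology + robustness (04) and
functional enrichment (06); each writes its tables under `results/`.

A `retnetdyn` command-line interface exposes the same stages individually
(`retnetdyn build-irn`, `correlate`, `extract-active`, `topology`, `motifs`,
`motif-dynamics`, `enrich`, `simulate`, `run`); `retnetdyn run --config
run.yaml` executes the whole pipeline with per-stage seeds and provenance.

## Layout

- `src/retnetdyn/` — the library: `network`, `expression`, `active`,
  `topology`, `motif`, `enrichment`, `syndata`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance tests (brute-force oracles in
  `tests/oracles.py`).
- `docs/methods.md` — models, parameters, numerical choices, limitations.
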