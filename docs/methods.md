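# Methods

This note records the models, defaults and numerical choices behind
`netpharm`, and what the synthetic benchmark does and does not show.

## Co-prescription model

Prescriptions are treated as unordered herb sets of size ≥ 2.  The
2-mode structure is a binary incidence matrix *B* with herbs in rows
(sorted union of all herbs used) and prescriptions in columns; herbs
appearing in no prescription are rejected rather than carried as zero
rows.  The 1-mode herb network is the matrix-product projection *BBᵀ*:
off-diagonal entries count co-prescriptions, the diagonal holds herb
frequencies, and an edge is drawn for every pair co-prescribed at least
once (no edge threshold — observed co-use is the relationship of
interest at these sample sizes).

Two similarity views are computed.  The **Jaccard coefficient** is the
standard presence-set form |P₁∩P₂| / |P₁∪P₂|.  This is a deliberate
choice: binary-similarity implementations that count matching zeros
(Sokal–Michener-style) inflate the similarity of rare herbs that are
jointly *absent* from most prescriptions, a known artifact in
co-prescription matrices.  Presence-set Jaccard assigns such pairs 0,
and the test suite pins this behaviour.  The **Pearson matrix** is the
phi coefficient between binary rows.  A herb present in every
prescription has zero row variance and an undefined correlation; we map
its correlations to 0 with a warning rather than NaN so heatmaps of
small corpora never fail.  Heatmap ordering uses average-linkage
hierarchical clustering on the distance 1 − r: average linkage is the
least extreme of the common linkages and needs no additional parameter.

## ADME screen

Compounds are retained when OB ≥ 30 % **and** DL ≥ 0.18, both inclusive
(the thresholds are stated as "≥" wherever this screen is used in the
TCMSP tradition, and boundary compounds exist, e.g. DL = 0.19 passes at
0.18).  Records sharing a PubChem CID across herbs are merged to one
record carrying the union of source herbs before Venn partitioning, so a
compound found in both herbs counts once, in the shared block.  The
filter is monotone in both thresholds, which the suite checks as a
property.

## Target algebra

A herb's target set is the union of targets of its ADME-passing
compounds; compounds sourced from both herbs contribute to both unions.
Gene symbols are opaque uppercase tokens — no live identifier resolution
is attempted; an optional user-supplied synonym map can be applied at
ingest.  Disease genes supplied as two lists (two databases) are
combined by **intersection** by default: "supported by both sources" is
the conservative reading, and a `union` switch is provided because
either convention is defensible.  The analysis universe for PPI work is
the intersection of the combined disease set with the herb target union.

## PPI screening

Edges at combined score ≥ 0.4 (the STRING "medium confidence" default,
inclusive) over the analysis universe define the graph; scores in
0–1000 STRING export convention are auto-detected (any value > 1) and
rescaled to [0, 1].  Duplicate unordered pairs keep the **maximum**
score — conservative toward edge inclusion.  Zero-degree proteins are
removed and reported.

Degree and betweenness centrality are computed on the unweighted graph:
scores gate edge existence but do not act as path lengths, matching the
binary-interaction reading of such networks.  Betweenness uses Brandes'
algorithm normalized by (n−1)(n−2)/2; unreachable pairs contribute
nothing, so values stay in [0, 1] on disconnected graphs.  Graphs with
fewer than 3 nodes report betweenness 0 with a warning.  The test suite
cross-checks the implementation against an independent oracle that
explicitly enumerates every geodesic, exhaustively over all graphs on
≤ 5 nodes and on 500 random 6–7-node graphs.

**Key targets** are genes *strictly* above the arithmetic mean on both
degree and betweenness, with both means taken over the isolate-free
network (isolates cannot carry centrality and would only dilute the
mean).  Strictness matters: on a regular graph every node ties the mean
and nothing is selected.  Metrics are a **two-pass** affair: screening
uses full-network centralities, while the reported key-target table is
recomputed inside the induced subnetwork — that convention is what makes
a printed key-target degree column sum to exactly twice the subnetwork's
edge count (handshake lemma), which the package exposes as
`edge_count_from_degrees` and verifies on the bundled 31-row table
(Σdeg = 616 → 308 edges).

## Clustering

The key-target subnetwork is clustered by spectral k-means: embed nodes
with the eigenvectors of the k smallest eigenvalues of the symmetric
normalized Laplacian, then k-means with k-means++ initialization, 100
restarts and a fixed seed.  The reference workflow used a web service's
k-means button whose feature space is undocumented; spectral embedding
of the subnetwork itself is the nearest documented, deterministic
analogue.  k defaults to 3.  Cluster ids are relabelled 1..k by each
cluster's lexicographically smallest gene so the assignment is stable
across runs.  On a graph with k components the embedding reduces to
component indicators and clusters equal components (tested).

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P[X ≥ k] for X ~ Hypergeom(N, K, n) with background N defaulting to the
union of all annotation genes (configurable).  Query genes absent from
the background are dropped with a warning — the behaviour of mainstream
ORA servers for unmapped identifiers — and every term is intersected
with the background before testing; only terms overlapping the query are
reported.  BH adjustment is applied **per category** (KEGG/BP/CC/MF),
mirroring per-ontology reporting, with a global option.  The plain
hypergeometric tail is used rather than an EASE-style (k − 1)
modification; that divergence is intentional and documented here.
Top-n reporting sorts ascending by p with ties broken by term id.

## Synthetic benchmark

The generators produce every input with planted structure at defaults
chosen to mirror the emulated study's magnitudes: 9 prescriptions over
17 herbs with the planted pair co-occurring with probability 0.8 against
a 0.25 background; 15 + 7 + 2 ADME-passing compounds plus 50 % decoys
straddling the OB/DL thresholds; 223 major-herb targets with the
31-gene minor-herb pool nested inside and 3 dual-herb targets; a
152-gene disease overlap (two disease lists of ~2400 genes whose
intersection is exactly the planted core); a PPI layer with 10 hubs
(attachment 0.6, scores ≥ 0.4), background density 0.05 with scores
U(0.15, 0.99) so a controlled fraction falls below threshold, and 17
edge-free isolates; and 30 noise annotation terms against one term
planted strictly inside the largest target cluster.  Noise terms are
drawn at the planted term's size: with equal term sizes, the fully
query-contained planted term attains the smallest achievable p, so
recovery can only fail through a (vanishingly rare) noise term landing
entirely inside the query.  A single top-level seed
derives per-generator sub-seeds by fixed offsets; regeneration is
byte-identical, and `truth.json` suffices to score every recovery claim.

What passing recovery tests shows: the pipeline's statistics detect the
planted signals (dominant pair, hubs, nested unions, dual targets,
enriched term) at these effect sizes.  What it does not show: behaviour
on real databases — synthetic scores are not STRING's evidence-combined
semantics, annotation terms have no hierarchy or overlap structure, and
gene symbols carry no biology.  Database-snapshot-dependent counts
(e.g. exact target-list sizes or p-values from 2021-era web resources)
are out of reach by construction and are replaced by structural and
property checks.

## Problem sizes and determinism

Recovery properties are evaluated over 20 replicate seeds with the
defaults above (152-node PPI graphs; 100-node graphs for the hub-recall
property), sizes at which every check completes in seconds while leaving
the planted effects comfortably detectable.  All outputs are written
with sorted keys and sorted node/edge order; two runs of the pipeline on
the same config produce byte-identical reports, which both the suite and
the acceptance script verify.

## Known limitations

- Gene identifiers are not resolved against any nomenclature authority;
  inconsistent symbols in user data will silently be treated as distinct.
- The Jaccard/Pearson views are computed on very small prescription
  corpora in the motivating use case; correlation estimates at n = 9
  columns are noisy and the heatmap ordering should be read
  qualitatively.
- Spectral k-means is one defensible stand-in for an undocumented web
  clustering; cluster boundaries (not the key-target set) may differ
  from other tools.
- The hypergeometric test assumes the background is the right sampling
  frame; with the default (annotation-union) background, sparsely
  annotated queries lose genes and power.
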