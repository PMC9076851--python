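# Methods

`netpharm` implements the standard offline workflow of a network-pharmacology
study: intersect the predicted targets of a compound panel with disease-gene
lists, analyze the protein–protein interaction (PPI) network of the common
targets, select *hub targets* by a median-degree rule, test the hubs for
gene-set over-representation, assemble the layered
compound–target–disease–pathway networks, and keep the books on externally
computed docking scores and MM-PBSA binding free energies.  This note
records the models, the conventions chosen where the field leaves them
open, and what the synthetic generators do and do not emulate.

## Target sets and the Venn intersection

Gene names from different databases are normalized by stripping whitespace
and uppercasing; hyphens and digits are preserved because official symbols
contain them (HSP90AA1, IL-6 aliases).  No alias or ortholog resolution is
attempted — that requires an external symbol database — but a user-supplied
two-column alias table can be applied before normalization.  Multi-source
disease lists are merged by plain set union with pooled source labels
(union-then-normalize); the compound/disease comparison is a two-set Venn
partition whose three parts are checked to partition each input exactly.

## PPI topology and hub selection

The PPI network is an undirected simple graph: duplicate edges in either
orientation collapse, self-loops are removed, and degree-0 nodes are
dropped by default (mirroring the "hide disconnected nodes" convention of
STRING exports).  The *edgecount* of a node is its number of distinct
neighbors.  Hubs are the nodes whose edgecount strictly exceeds
`multiplier × median(edgecounts)`, default multiplier 2.  Strict `>` is the
default reading of "more than twice the median"; on the bundled reference
degree table (median 15, minimum hub degree 31 against a threshold of 30)
strict and non-strict agree, so both readings reproduce its 25-hub set.

Topology metrics follow the Cytoscape NetworkAnalyzer conventions:

* local clustering of a node with degree < 2 is 0 and *included* in the
  network mean;
* density is 2|E| / (n(n−1)); average neighbors is the mean degree;
* characteristic path length is the mean shortest-path length over all
  *connected* unordered pairs; diameter/radius are the max/min node
  eccentricity.  On a disconnected graph the path-based statistics are
  computed on the largest component and the report carries an explicit
  `largest_component_only` flag, avoiding infinite distances.

The bundled 93-gene degree table ships as degrees only; its true edge list
is not public.  When a concrete graph is needed it is realized with a
deterministic Havel–Hakimi construction (ties broken by symbol order).
Only degree-derived statistics of that realization are meaningful — the
median and the hub set depend on the degree sequence alone — and its
edge-dependent statistics (clustering, path length, density) are *not*
reference values.  Relatedly, the published topology table this work is
checked against is internally inconsistent for the 25-node hub network (it
reports 456 edges, above the simple-graph maximum of 300, alongside
density 0.987), so only the node count of the hub network is treated as
reproducible.

## Enrichment

Over-representation of a query gene set in an annotation term is tested
with the hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, K, n),
evaluated through `scipy.stats.hypergeom.sf` (log-space, stable in the
extreme tails).  The EASE variant — the tail at max(k−1, 0), the
conservative convention of the DAVID server — is available as an option.
The background universe defaults to the union of all term gene sets, the
only self-consistent choice when no genome-wide annotation is supplied;
query genes outside the background are dropped with a warning and the
effective query size reduced accordingly.  Raw p-values are
Benjamini–Hochberg adjusted (via `statsmodels.multipletests`) across the
tested terms *within each category* (BP/MF/CC/pathway) by default, since
GO categories are conventionally reported separately; a global adjustment
is a switch away.  Whether a given published "adjusted p-value" was BH is
usually unstated; BH is this package's default and the choice is logged at
run time.  Published enrichment p-values from annotation servers are not
reproduction targets at all — they depend on the server's hidden
background and test variant — only overlap counts are.

Category proportions (the BP/MF/CC pie) are percentages rounded half-up to
two decimals; the raw values are returned alongside because the rounded
ones need not sum to 100.

## Layered networks and core compounds

Layered networks are typed multipartite graphs over five layers (herb,
compound, target, disease, pathway) with a fixed relation vocabulary
(herb-compound, compound-target, target-disease, target-pathway);
intra-layer edges are rejected at construction, so PPI edges cannot leak
into these networks.  Node accounting is closed-form and asserted:
compound-target networks have |compounds| + |distinct targets| nodes; the
compound–target–disease network restricts targets to the common set and
adds one herb and one disease node (compounds with no common target are
retained, connected through the herb node — dropping them would break the
arithmetic); the compound–hubtarget–pathway network keeps only hubs
annotated to at least one pathway, so unannotated hubs drop out of the
target layer.

*Core compounds* reuse the median rule on compound-layer degrees.  The
rule is commonly stated without fixing either the comparison strictness or
the population whose median sets the threshold; both are exposed
(`strict`, `median_scope` ∈ {all_nodes, compound_layer}) with defaults
strict/all_nodes, and the ambiguity is documented rather than guessed.

## Binding bookkeeping

Docking and MM-PBSA numbers come from external engines and are consumed as
tables.  Surflex Total Scores grade as none / certain / good / strong at
strict thresholds 4 / 5 / 7.  MM-PBSA components must satisfy

    ΔG_bind = ΔE_vdW + ΔE_elec + ΔG_polar + ΔG_SASA,

and an externally supplied total is validated against the component sum at
a tolerance of 0.005 kJ/mol — enough to absorb the 3-decimal rounding of
each printed component.  One bundled reference row (MAPK1-geniposide) has
a typographically ambiguous polar term in its published source; the value
shipped (162.12 kJ/mol) is the unique one consistent with additivity, the
row is flagged `ambiguous`, and it is excluded from the default fixture
set.  Critical residues of a per-residue decomposition are those with
|energy| strictly above 5 kJ/mol (configurable threshold).

Number parsing accepts the Unicode minus (U+2212) and a space between sign
and digits, because published energy tables contain both.

## Synthetic data: what it emulates

The generators produce inputs with *planted* ground truth at the scale of
the motivating study — 12 compounds, a 161-target union, 4124 disease
genes with a planted overlap of exactly 97 — so every stage has a known
right answer offline.  Each generator draws from its own named stream
derived from `(seed, crc32(name))`; adding a generator never perturbs the
others, and all outputs are byte-identical per seed.

* **Compound-target map**: each target links to 1 + Poisson(2.4) compounds
  (mean ≈ 3.4 links/target, matching the edge density of published
  compound-target networks at this scale); one unique and one shared
  target are forced so both kinds always exist.
* **Disease set**: exact planted intersection, remainder disjoint.
* **PPI with planted hubs**: the background is a random d-regular graph
  (d = 6 by default) — degrees exactly d, emulating the tight degree
  concentration of non-hub proteins while making the selection threshold
  sharp.  Planted hubs form a clique among themselves (dense hub cores are
  characteristic of real PPI networks) and each attaches to 4d + 1
  uniformly chosen background nodes, so hub degrees exceed four times the
  background median — twice the margin the 2×-median rule needs.  With
  the defaults (100 background nodes, 5 hubs) the rule recovers exactly
  the planted set in ≥ 95 of 100 seeds, and selects nothing under the
  0-hub null.
* **Annotations**: decoy terms draw uniformly from a 2000-gene background
  containing the query, so their overlaps sit at chance level; the planted
  term contains ⌈0.8·|query|⌉ query genes and must attain the minimum raw
  p in ≥ 95 of 100 seeds.
* **Energy tables**: components drawn in realistic ranges (vdW in
  [−160, −60], electrostatic [−120, −10], polar [50, 190], SASA
  [−20, −14] kJ/mol), totals set to *exact* sums; critical residues are
  planted with magnitudes in [5.5, 15] against a [−3, 3] background and
  carry distinguishable ids, giving an independent recovery oracle.

What the generators do **not** emulate: real gene nomenclature and aliases
(symbols are synthetic tokens), STRING-like confidence-weighted edges and
scale-free degree tails, GO term ancestry, correlated term memberships,
chemical structure.  Passing the recovery tests therefore shows that the
*rules* behave as specified under their stated assumptions, not that any
particular biological claim holds on real data.

## Problem sizes and numerics

Property tests compare metrics to brute-force oracles (Floyd–Warshall,
triangle enumeration) on ≥ 200 random graphs with n ≤ 20, the regime where
exhaustive checks are exact and fast; the hypergeometric tail is checked
against explicit enumeration of all C(N, n) draws for N ≤ 12; recovery
experiments use 100 seeds.  The full synthetic pipeline at study scale
runs in well under a second.  Floating-point tolerances: 1e−12 where both
sides are exact computations, 0.005 kJ/mol for energy additivity (rounding
of printed components), exact equality for set-valued results.

## Known limitations

* Symbol normalization is lexical only; two databases naming the same gene
  differently will not be unified without a user alias table.
* The hub rule's outcome is sensitive to the median when many degrees tie
  at it; both strictness readings are exposed but only one can be default.
* Enrichment treats terms independently (no GO-graph propagation,
  no term–term overlap modeling).
* The Havel–Hakimi realization of a degree sequence is one graph among
  many; edge-dependent statistics computed on it are constructions, not
  inferences.
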