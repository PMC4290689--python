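# Methods

## Model

The method predicts a single active gene sub-network from three time-ordered
groups of scored differentially expressed genes and a reliability-weighted
interactome. It is a minimum-cost flow formulation solved as a continuous
linear program.

**Graph construction.** Every gene of the interaction network is duplicated
into layers A and B. For each ordered interaction (u → v) with reliability
w ∈ (0, 1] two arcs are created — (u,A) → (v,A) and (u,B) → (v,B) — with
cost −log max(w, 10⁻⁶) and capacity `interaction_capacity` (default 1.0).
Bidirectional interactions are expanded into both ordered arcs at read time.
An artificial source S connects to every early gene's layer-A copy, every
late gene's layer-B copy connects to an artificial sink T, and every
intermediate gene owns a *transit arc* (g,A) → (g,B). These terminal/transit
arcs have cost 0 and capacity equal to the gene's group-normalised score
(capacities sum to 1 within each group). A costless, uncapacitated return
arc T → S closes the circulation so plain conservation holds at every node.

Because interaction arcs never cross layers, any S→T path enters in layer A,
crosses exactly one transit arc, and leaves from layer B: the temporal
ordering early → intermediate → late is enforced purely structurally. Early
and late genes also possess both layer copies and may be traversed as
ordinary way-points — group membership controls only where paths may begin
and end. Flow may likewise pass *through* an intermediate gene within one
layer without using its transit arc; only transit flow earns reward.

**Objective.** minimise Σₐ costₐ·fₐ − γ₁·Σ_source f − γ₂·Σ_transit f subject
to conservation and capacity bounds. All interaction costs are ≥ 0 and the
only negative coefficients sit on source and transit arcs, so the program is
bounded (total flow is capped by the unit total source capacity) and always
feasible (zero flow). Total flow is free: γ₁ and γ₂ decide how much flow is
worth pushing and thereby how many initial-response genes and intermediate
regulators enter the prediction.

**Reduction to a gene-level network.** Gene-level edge flow is the sum of
the ordered pair's two layer arcs; gene importance is total inflow from
source and interaction arcs across both copies (transit arcs are internal
and not double-counted). Entries at or below `flow_tolerance` are dropped.
Nodes are typed by group membership: SRC (early), INT (intermediate), SNK
(late), NOD (no group — predicted transient regulators). Layers are merged
in all outputs; per-layer flows are bookkeeping, not biology.

## Parameters

| parameter | default | meaning |
|---|---|---|
| γ₁ (`gamma1`) | required | reward per unit of flow entering through an initial-response gene; raises the number of early genes included |
| γ₂ (`gamma2`) | required | reward per unit of flow crossing an intermediate regulator's transit arc |
| `interaction_capacity` | 1.0 | capacity of every interaction arc; 1.0 means no single interaction can carry more than the whole normalised group budget |
| `flow_tolerance` | 10⁻⁶ | LP noise floor; flows at or below it are treated as zero |
| `weight_floor` | 10⁻⁶ | clamps −log cost of pathological near-zero reliabilities |
| low-reliability threshold | 0.3 | an included edge with reliability below this counts against a grid cell in model selection; there is no canonical cutoff, so the value is prominent and configurable |

Group-normalising the score capacities (they sum to 1 per group) makes γ
values comparable across datasets of different size and score scale; the
sweep {0.1, 0.5, 1, 2, 5} covers the practically useful range on the
reference benchmark, with a 3×3 grid {0.5, 1, 2}² used for model selection
at desk scale.

## Solving

The LP (one variable per arc, one conservation equality per node; the
constraint matrix is a node–arc incidence matrix) is solved with HiGHS
through `scipy.optimize.linprog`, which is deterministic for a fixed
problem. Variables are ordered canonically (arc kind, tail, head) so the
exported CPLEX LP text and any degenerate-optimum selection are
reproducible. Incidence matrices are totally unimodular, so with integral
capacities an integral optimum exists — the property the test suite's
exhaustive-enumeration oracle relies on. Alternative optimal bases are
possible; tests therefore compare objectives and flow supports, not exact
flow vectors.

Flow-path decomposition (used for reporting and to verify the
temporal-path property) strips S→T paths greedily: at each branch take the
arc with the largest residual flow, break ties toward the lexicographically
smaller head, subtract the bottleneck. Residual circulation on zero-cost
cycles — possible in degenerate optima — is stripped separately and
reported as cycles; sub-tolerance residue stranded at dead ends is
accumulated and reported, never silently lost. Each strip zeroes at least
one arc, so termination is guaranteed.

## Synthetic benchmark

The generator emulates the data regime this class of method is used in —
large noisy interactomes with a sparse reliable response skeleton — without
reproducing any real dataset. The reference instance plants 20 temporal
paths (early → interior → intermediate regulator → interior → late, edge
reliabilities 0.85–0.95) over 300 genes with 2000 bidirectional background
edges at reliabilities 0.1–0.3. Gene scores are uniform on [1, 3],
emulating |log₂ fold change| above a 2-fold significance cutoff. 30% of
interior genes are withheld from every scored group; recovering them as NOD
nodes is the testable analogue of identifying transient regulators.
`path_len` counts interior genes per path (excluding the designated transit
gene), split evenly around it. Scored interior genes join the intermediate
group: early/late membership would hand them terminal arcs and let flow
enter or exit mid-path, structurally bypassing planted edges. Each path has
exactly one designated transit gene so ground-truth transit recall is
well-defined.

What the generator does **not** emulate: scale-free degree distributions,
correlated reliability errors, overlapping pathways sharing genes, or
scores with realistic measurement noise. Passing the recovery tests shows
the optimisation recovers a reliability-separated planted structure under
uniform noise — it does not certify performance on real interactomes, where
reliability separation is weaker and paths interleave.

Noise perturbations add bidirectional edges with background-level weights
between previously unconnected pairs, or remove uniformly sampled
interactions (a bidirectional pair counts as one). The robustness
experiment protects planted edges from removal: at desk scale, removing 500
of ~2100 records would delete a quarter of the planted skeleton itself,
which measures the perturbation, not the method.

## Evaluation metrics

Edge recall/precision compare predicted ordered pairs against planted
edges; transit recall is the fraction of designated transit genes present
as INT nodes; NOD recall the fraction of withheld interior genes recovered
as NOD. Pathway-overlap scoring reports the longest directed path whose
every edge lies in both the prediction and a reference edge set, found by
exhaustive DFS with node-revisit protection (intersections are small; the
independent oracle in the tests enumerates all simple paths with networkx).

## Grid search and model selection

Grid mode repeats the pipeline per (γ₁, γ₂) cell — each cell's files are
byte-identical to a single run with those parameters — and writes a
statistics table. "Optimal" couples two objectives; the implementation uses
a deterministic lexicographic rule (most input-group genes, then fewest
low-reliability edges, then smallest (γ₁, γ₂)) and also exposes the Pareto
front for users who want to trade off manually. Step-specified grids are
generated in exact Fraction arithmetic so directory names carry clean
decimals.

## Design choices and limitations

- Duplicate input records (gene lists and network) keep the **maximum**
  score/weight: deterministic and order-independent.
- Scores are magnitudes: non-positive gene scores are rejected and logged
  rather than interpreted as down-regulation; users encode direction
  elsewhere (the sub-network does not distinguish activation from
  repression).
- The formulation is restricted to exactly three temporal groups; more
  groups would need more layers.
- Continuous flows are reported as-is; fractional flow is meaningful
  (importance), and no integrality is imposed.
- Problem sizes in the test and acceptance runs (300-gene reference
  instance, 3×3 selection grid, noise steps up to 500 edges, 5 seeds) are
  the package's desk-scale study conditions; the method itself scales to
  interactomes orders of magnitude larger, limited only by LP solve time.
- No per-gene significance p-values are computed; flow is the importance
  score.
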