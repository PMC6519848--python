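# Methods

## The network model

The integrated system is a directed multigraph.  Vertices carry one of seven
types — `gene`, `protein-monomer`, `protein-protein-complex`,
`protein-compound-complex`, `protein-RNA-complex`, `compound`, `reaction` —
and, except for genes and reactions, a compartment out of
{c, e, p, i, o, m}.  Edges carry one of seven types: two encoding
associations (`transcription-encoding`, `translation-encoding`), four
process associations (`educt`, `product`, `catalysis`,
`complex-formation`), and `regulation`.  Non-regulation edges are marked
`conjunct` (Boolean AND: reaction educts, complex subunits) or `disjunct`
(Boolean OR: products, isoenzymes, encoding); regulation edges carry a mode
(+1 activation, −1 inhibition, 0 combined) in the stoichiometry slot.
Parallel edges are allowed only when they differ in type; `(source, target,
type)` triples are unique.  Undirected views needed by some metrics are
derived on demand and never stored.

## Functional domain affiliation

The three-domain labeling (metabolic domain MD, protein interface PI,
regulatory domain RD) is the fixed point of a synchronous, rule-based
propagation.  The rules follow from two principles: a vertex whose entire
context is one process class belongs to that class, and a vertex bridging
both classes is interface.

*Seeds.*  A reaction whose educts and products are all compounds is MD; all
proteins, PI (protein modification); mixed composition defers.  A gene
incident to any regulation edge is RD, otherwise MD (a gene not involved in
any regulatory process is metabolic context only).  Complexes of mixed
composition — protein–compound and protein–RNA complexes — are PI by
construction, in analogy to the reaction rule: binding a metabolite or an
RNA is what makes a regulator metabolic or post-transcriptional.  Compounds
with no adjacent reaction are MD; a protein with an empty influence set is
RD if it sources regulation and MD otherwise.

*Influence.*  Which neighbors may determine a deferred vertex is a single
declarative table (`partition.INFLUENCE_TABLE`).  Compounds listen to the
reactions that produce or consume them and to their regulators — not to
complexes they are bound in, so an effector metabolite (cAMP, leucine)
stays metabolic.  Proteins listen to their encoding genes, the reactions
and complexes they act in or are produced by, and their regulators — not to
their own subunits, so an enzyme complex resolves metabolic from its
reaction while its subunits, sitting between regulated genes and the
complex, resolve to the interface.

*Propagation.*  In synchronous rounds, a deferred vertex adopts the
unanimous label of its influential set once all members are resolved, and
resolves to PI as soon as two distinct resolved labels appear (a mixed
neighborhood cannot become unanimous, and early resolution cannot change
the outcome, so determinism and iteration-order independence are
preserved).  When a round changes nothing, the remaining vertices sit on
dependency cycles with no outside information; they are recorded as
*unresolved* and assigned to the interface.  A cap of |V| rounds guards
termination (each vertex is relabeled at most once, so the cap is
unreachable in practice).

*Two-domain variant.*  PI vertices fall to the side (MD or RD) holding the
majority of their non-regulation edges, edges to other interface vertices
being uninformative; ties go to RD.  The vertex-driven baselines are pure
type lookups: genes RD, proteins PI (three-domain) or RD (two-domain),
reactions and compounds MD.

## Interface metrics

The inter-module edge fraction of domain D counts each directed edge once
and classifies it ignoring direction: c_D = external/(external+internal).
Modularity is evaluated on the undirected simple view (each directed edge
one link; reciprocal and parallel edges collapse; no self-links):

    M = Σ_j [ L(D_j, D_j)/L_G − (deg(D_j)/(2 L_G))² ]

which coincides with the standard partition-modularity definition; the
per-domain summands are reported alongside the total.  An empty link set is
an error (division by L_G).

Degree-based measures use the directed multigraph: DC(v) = k_in + k_out,
hubs are DC strictly greater than 50 (the threshold is a parameter), and
embeddedness ξ_D(v) = (1/k_v) Σ_{w∈D} (A_vw + A_wv) is reported as missing
(never zero) for isolated vertices; over all domains the ξ values of a
vertex sum to one.  Betweenness BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st is the
unnormalized Brandes count over ordered pairs, computed on the directed
simple view by default — the network is directed, and the formula itself is
direction-agnostic — with an undirected option (where each unordered pair
still contributes twice, giving k(k−1) for a k-star centre).  The null
model draws vertex subsets of the interface's size without replacement and
records the distribution of their mean BC; the interface's empirical
quantile in that distribution is the calibration statistic.  Ranking tables
break score ties lexicographically by vertex id.

## Traversing paths and feedback loops

A traversing path [u, v_1 … v_{k−1}, w] runs from one outer domain to the
other with all interior vertices distinct members of PI; downwards is
RD → MD, upwards MD → RD.  A single RD–MD edge is a *direct link*, tallied
separately, so the minimum traversing length is k = 2.  Interior
distinctness plus the domain constraint make every path simple.
Enumeration starts at the boundary edges into the interface and explores
successors depth-first in sorted-id order, which makes the stream
lexicographic in the vertex sequence and deterministic; a configurable cap
on the number of paths (default 2×10⁶) raises an error rather than
exhausting memory, since worst-case enumeration is exponential.

Path pools are summarized by length histogram, distinct interior count, and
the fraction of paths whose interior contains each vertex, unordered pair
and unordered triple — participation is reported per pool (downwards and
upwards separately), never merged.  SCC containment is the fraction of
paths all of whose vertices (endpoints included) lie in the largest
strongly connected component.

A feedback loop pairs one upwards with one downwards path closed at both
ends.  The regulatory closure is a shared endpoint (the TF ending the
upwards path regulates the gene starting the downwards one; closure length
0) or an RD-internal directed path of bounded length.  The metabolic
closure is a direct edge from the downwards end to the upwards start
(length 1) or a bounded MD-internal path; because the wording "direct path"
is ambiguous, the bound L is a parameter and results for L > 1 are reported
alongside the direct-edge count.  Closure witnesses (the within-domain
vertex sequences) are attached to every loop.

## Flat-file reconstruction

The reconstruction stage is deliberately reduced-fidelity: it implements
the documented pipeline — parse attribute-value records, validate vertex
candidates into the seven types, expand processes, assemble, extract the
largest weak component — against a miniature fixture dialect rather than a
licensed database download.  Dialect conventions: `UNIQUE-ID` keyed
records, `//` terminators, `/` continuations (joined with a single space),
`^` sub-attributes (`^COEFFICIENT`, `^COMPARTMENT`); transcription-unit
membership from the genes' `COMPONENT-OF`; enzymes via a simplified
`ENZYMES` attribute; aliases via `CANONICAL-FORM`; class membership via the
members' `TYPES`.  Reversible reactions split into `ACC`/`ACC__REV` with
swapped educt/product edges and duplicated catalysis; regulation of a
transcription unit is multiplied over its member genes (colliding
regulation triples merge, disagreeing modes combining to 0); regulating
RNAs are translated to their encoding genes; reactions citing compartments
outside {c, p, i} are dropped with a report entry, as is any process with
an unidentified participant.  Unlisted compartments default to cytosol and
absent stoichiometries to 0 (not applicable/ambiguous).  Gene → monomer
encoding uses the translation type; gene → protein-RNA-complex edges (the
RNA component mapped to its gene) use the transcription type — a
figure-level detail pinned by fixture tests as implementation-defined.

## Synthetic generator

The generator emulates the building blocks of the study system at desk
scale.  Defaults (all overridable, chosen once): 150 genes (70% metabolic,
encoding enzymes 1:1), 120 compounds, 100 reactions with 1–3 educts and 1–2
products, 20 enzymatic protein–protein complexes, one protein–RNA complex,
regulation density 0.35 (probability a gene is regulated), 30% of TFs
metabolic (active only as protein–compound complexes), 20% reversible
reactions, and a 0.15 share of non-transcriptional regulation events
(enzyme-activity and reaction regulation, plus metabolic-protein regulation
of TF genes) — these create the direct regulatory–metabolic links of the
integrated system.  Regulator out-degrees are drawn from a zipf-like weight
(exponent 1.2) to mimic global regulators; the exact law is a documented
default, not a biological claim.  Half of the metabolic TFs are wired as
product-sensing feedback regulators — effector = a product of a reaction
whose enzyme gene the TF regulates — planting the canonical
metabolite → TF → enzyme-gene loop so that feedback-loop detection has
non-trivial ground truth.  Every TF gene is itself regulated
(autoregulation permitted), because an unregulated regulator gene is
invisible to wiring-based affiliation.  Weak connectivity is enforced by
minimal grammar-sound bridges (unused compounds become educts of an
existing reaction).

Ground-truth labels are planted by construction role; vertices whose wiring
the construction leaves genuinely mixed (sRNA genes and partners,
regulation-targeted enzymes, bridge proteins) are flagged *ambiguous* and
excluded from recovery assertions — disagreement there is informative, not
a defect.  What passing recovery tests show is that the affiliation rules
read construction intent off wiring alone; what they do not show is
fidelity to any real organism's joint degree structure, compartment usage
or regulatory logic, which the generator does not attempt to match.

## Problem sizes and numerical choices

The test suite and the acceptance script run on the fixture (8 vertices)
and on generated networks of roughly 200–560 vertices; brute-force oracles
(reachability matrices, exhaustive path enumeration) are applied to random
graphs of ≤ 15 vertices across ≥ 50 seeds, sizes at which exhaustive
checking is exact and fast.  All randomness flows through explicit integer
seeds (`numpy.random.default_rng`).  Component-size ties break toward the
component containing the smallest vertex id; ranking ties break by id;
floating-point comparisons in tests use relative tolerances of 1e-6 or the
printed precision of the quantity under test.

## Known limitations

Full database semantics (promoters, terminators, sigma factors,
attenuation, protein modification chains) are out of scope of the
reconstruction stage; anything unrecognized is preserved as opaque
metadata.  The affiliation procedure's figure-level details are not uniquely
recoverable from prose — the influence table and mixed-composition seeds
above are this package's explicit, auditable choices, and on any deposited
annotation the recomputed labels should be compared against stored ones
with the disagreement set reported rather than hidden.  Flux-based analyses
(biomass capacity, essentiality) require a stoichiometric model and an LP
solver and are deliberately not part of this package.
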