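# Methods

## The model

A patient presents one primary colorectal tumor (layer T) and metastases in
up to four further layers: paracolic (P), intermediate (I) and central (C)
lymph-node metastases along the lymphatic drainage, and liver metastases
(LM). Somatic mutations, clustered by their cancer cell fractions (CCFs)
across all samples (PyClone-style input; the clustering itself is upstream
of this package), define clones: a clone is the population of cells whose
most-derived mutation cluster is a given one, and an offspring clone
carries all mutations of its ancestors.

Route inference rests on three assumptions:

1. lymphatic spread is proximal-to-distal — a source's layer never lies
   deeper than a lymphatic target's, and liver metastases never seed
   lymphatic layers (any layer may seed a liver metastasis);
2. clones do not vanish — a lesion's present-day clone content stands in
   for its history;
3. migration is rare — each metastasis is founded by exactly one seeding
   event, and subclones shared by two lesions migrated jointly.

## Pipeline

**Merged CCFs.** Multi-region lesions (primary, liver metastases) are
analyzed as single samples: per mutation, CCF = min(1, Σ CCFᵢdᵢ / Σ dᵢ)
over the lesion's regions with per-region depths dᵢ as weights; a mutation
not called in a covered region is imputed at CCF 0 with the region's median
depth. Cluster mean CCFs are arithmetic means over member mutations
(merging happens per mutation first; with unequal depths the order
matters).

**Clonality and roles.** Per cluster and lesion: clonal iff mean CCF
strictly above `clonal_ccf` (default 0.85), absent iff at or below
`absent_ccf` (default 0.05), subclonal otherwise — boundaries are exactly
the strict/non-strict reading of those inequalities. Clusters with fewer
than `min_cluster_size` (default 5) substitutions are discarded as likely
false-positive calls; an optional chromosome-span filter
(`min_chromosomes`) exists but is disabled by default because no principled
cutoff is available. The trunk is the unique cluster clonal in every lesion
(none, or several, is a structural error); non-trunk clusters present in
two or more lesions are branches; clusters private to one lesion are
leaves. Leaf clusters are attached to the tree under the deepest cluster
clonal in their lesion but are excluded from route inference — a private
subclone says nothing about where its lesion came from.

**Clone tree (pigeonhole principle).** All comparisons carry a tolerance
`epsilon` (default 0.05, the scale of the absence threshold). For two
clusters with per-lesion CCF vectors *a*, *b*:

* *reversal* (∃ lesion a > b + ε and ∃ lesion b > a + ε) means disjoint
  subclones: neither may be an ancestor of the other;
* *consistent order* (a ≥ b − ε everywhere, strictly above somewhere)
  orients the pair: the smaller cluster can never be the ancestor — but it
  does **not** force nesting, because two disjoint subclones can show a
  consistent order by chance when they co-occur in few lesions;
* *capacity*: as an ancestor bound, a cluster called clonal in a lesion
  counts as the full cancer-cell population there (capacity 1.0) — the
  clonal call already asserts ubiquity, and its measured mean sits below 1
  only through depth noise amplified by the per-mutation cap;
* *pigeonhole sum*: two clusters in disjoint subtrees must fit jointly
  inside every common ancestor, ccf(a) + ccf(b) ≤ capacity(ancestor) + ε in
  every lesion. With the trunk's capacity of 1 this subsumes the
  "joint CCF above one forces nesting" rule.

The builder assigns each non-trunk cluster a parent by depth-first search
over these constraints, preferring the **shallowest** feasible ancestor and
letting the sum constraints force depth; pairs with no order evidence
default to branching under a common parent and are nested only if no tree
exists otherwise. The preference direction is deliberate: an unforced
nesting assertion silently consumes the ancestor's residual clone (below),
whereas an unforced flat placement only leaves availability optimistic.
The search is deterministic (candidates ranked by depth, then largest
maximum CCF, then cluster ID; first valid tree wins) and refuses loudly
when the constraints admit no tree.

**Clone accounting (interval calculus).** A cluster's CCF counts every cell
carrying it, including all nested subclones, so the cluster's *own* clone
has cells only where its CCF exceeds the joint CCF of the sub-subclones
inside it — and which clusters sit inside which is exactly what the
pairwise rules cannot always identify. Route inference therefore brackets
each clone's residual per lesion:

* **certainly present** (requirement): the residual stays above
  `absent_ccf` even after subtracting the maximum-CCF set of clusters that
  could consistently sit disjointly inside it (dominated, never reversed,
  no pair jointly exceeding one);
* **possibly present** (availability): the residual survives subtracting
  only clusters provably nested inside (joint CCF above one somewhere) and
  provably pairwise disjoint (reversed);
* **most plausible** (used only to rank contested seeding directions): a
  single nesting forest assigning every dominated cluster to its tightest
  dominator — a near-zero CCF margin means the subclone saturates that host
  somewhere, strong evidence of containment — so each cluster is subtracted
  exactly once.

A lesion's **seeding clone set** is its certainly-present clones (falling
back to the deepest clonal cluster when the set is empty); its
classification is monoclonal iff every present non-leaf cluster is clonal.
A candidate **source** must possibly-possess every seeding clone of the
target and satisfy the layer constraint. Requirements being conservative
and availability optimistic guarantees a lesion's true source is never
rejected.

**Parsimonious map.** Every metastasis whose seeding set the primary can
supply is seeded by the primary (this alone minimizes the number of
metastasis-to-metastasis routes). The rest are assigned by backtracking
search over their candidates — preferring the candidate sharing the
deepest clone with the target, then the smallest lesion ID — subject to
global acyclicity. When no acyclic assignment exists, the blocking lesions
form a dependency group linked by group-private clusters (subclones
available nowhere outside the group, e.g. a marker a reseeding source
passed to its offspring): the group elects a head whose *reduced* seeding
set (group-private clusters masked, i.e. treated as arisen in situ) is
externally sourceable, and the rest of the group chains below it. Head
candidates are the roots of the within-group can-source digraph
(masked-reduced requirements vs availability); a contested pair is
oriented toward the direction that borrows fewer clones beyond the
source's most-plausible set; a remaining tie means identical compositions,
resolved by convention — the lexicographically largest lesion ID becomes
the externally seeded one — and reported as an **ambiguity group**. The
search carries a fixed budget of 2000 resolution attempts; exceeding it
(possible only when noisy clonality calls are mutually inconsistent)
raises an error rather than guessing. Each route is finally colored by its
smallest involved subclone (deepest in the tree; ties by fewer
descendants, then cluster ID) and classified as inter-layer sequential
(target layer = source layer + 1), inter-layer skip (further), or
intra-layer spread (same layer). Summary percentages are printed to one
decimal with half-up rounding so published count breakdowns reproduce
exactly (38 of 61 → 62.3).

## Synthetic data

The generator emulates the study design: a random recursive clone tree
(default 7 clusters, 5–40 substitutions each — never below the cluster
filter), a primary with 2–5 regions (default 3), lesions per layer
defaulting to 3 P, 2 I, 1 C, 1 LM (liver metastases with 2 regions), depth
264X, purity 0.7. The primary carries every clone with Dirichlet exclusive
fractions, floored so the trunk clone keeps at least 0.25 (no second
cluster reaches the clonal range — the trunk stays unique) and so internal
clusters keep a detectable exclusive fraction (a cluster CCF-identical to
its child in every sample would have been merged by the upstream
clustering). Metastases are created in layer order; each is seeded from
the primary or, with probability `fraction_metastasis_seeded` (default
0.35), from an eligible earlier lesion; founders are a random subset of
the source's clones with exclusive fraction ≥ 0.1, monoclonal with
probability `monoclonal_probability` (default 0.3, near the cohort's
observed monoclonal share), multiclonal founder fractions drawn in
[0.15, 0.8] so every founder stays clearly present-but-subclonal.

Identifiability is an explicit configuration axis. With
`private_marker_probability` = 1 every reseeding event spawns a fresh
marker cluster on the source that makes the edge recoverable; without
markers, reseeding is indistinguishable from primary seeding and the
parsimony objective will (correctly) prefer the primary. Three rules keep
the marker regime genuinely identifiable, i.e. make the true history the
unique consistent one: markers are event-private (never re-transmitted
onward, never hosts of later markers); the marker's host clone migrates
with it (otherwise "the marker arose in the recipient" would implicitly
grant the recipient the host's cells and the two orientations of the edge
become data-identical); and the source withholds at least one marker-free
clone from the migrating subset, keeping its content strictly richer than
the recipient's. Ground-truth seeding classes are recorded as a
composition reader assigns them: a monoclonally founded source that later
gained a marker subclone reads — for any method — as multiclonal.

Observations: per mutation and region, expected VAF = purity · CCF / 2
(diploid, multiplicity 1), alt count binomial at the configured depth,
CCFs back-converted from counts; regions of multi-region lesions receive
Dirichlet-perturbed clone fractions (concentration 10) to emulate spatial
heterogeneity. `noise="none"` disables both and emits exact truths. All
randomness flows from one generator seeded by `seed`, in the fixed order
tree → history → observations, so datasets are byte-identical per seed.

What the simulations do **not** emulate: copy-number change and LOH
(mutations are diploid heterozygous), clustering errors (cluster
assignments are taken as given, as in the real pipeline), FFPE artifacts,
purity misestimation, and vanished clones (assumption 2 holds by
construction). Perfect recovery in the identifiable regime therefore
demonstrates the inference logic, not robustness to those factors.

## Recovery evaluation

Route precision/recall/F1 are computed over (source, target) pairs after
collapsing each inferred ambiguity group to one lesion — within such a
group any admissible ordering counts as correct, mirroring the method's
own statement that the direction is conventional. Seeding-class accuracy
is the fraction of metastases with the correct monoclonal/multiclonal
label; tree agreement is the fraction of shared non-leaf clusters with the
correct parent. Under binomial noise at 264X, roughly one patient in eight
ends in a loud infeasibility/inconsistency error (scored 0) — boundary
noise can flip a clonality call and make the constraints contradictory;
the package reports this rather than repairing it silently. The median
route F1 over 100 noisy seeds remains 1.0.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `clonal_ccf` | 0.85 | clonal call: mean CCF strictly above |
| `absent_ccf` | 0.05 | statistical absence: mean CCF at or below; also the clone-residual threshold |
| `min_cluster_size` | 5 | discard clusters with fewer substitutions |
| `min_chromosomes` | off | optional chromosome-span filter |
| `epsilon` | 0.05 | tolerance of all pigeonhole CCF comparisons |
| `depth` | 264 | simulated sequencing depth (X) |
| `purity` | 0.7 | simulated tumor purity |
| `fraction_metastasis_seeded` | 0.35 | per-metastasis reseeding probability |
| `private_marker_probability` | 1.0 | identifiability of reseeding edges |
| `monoclonal_probability` | 0.3 | monoclonal share of primary seedings |
| `region_concentration` | 10 | Dirichlet concentration of regional heterogeneity |

## Problem sizes

The test and acceptance workloads run at desk scale by design: simulated
patients have ~7–11 clusters and 8 lesions (~2,000 mutation calls);
enumeration oracles cover up to 5 clusters × 4 lesions (1,000 instances)
and 6 lesions (500 instances); recovery benchmarks use 100 seeds per
regime. The whole suite runs in about half a minute on one CPU.

## Known limitations

* Cluster assignments and CCFs are trusted as given; there is no joint
  re-clustering or error modeling beyond the comparison tolerance.
* The chronological order of seeding events (which historical state of a
  source existed at seeding) is not modeled; only the final map is
  inferred, with present-day clone content standing in for history.
* One seeding event per metastasis: polyphyletic seeding of a single
  lesion from two sources is outside the model.
* The pigeonhole rules underdetermine the clone tree on real data; the
  shallowest-consistent tree is a deterministic, declared choice, and the
  interval clone calculus is designed so that routing is insensitive to
  the unidentified nestings. Genuinely contradictory inputs fail loudly.
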