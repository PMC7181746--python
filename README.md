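# metroutes

Inference of metastatic seeding routes in colorectal cancer from
multi-region tumor sequencing.

When a colorectal tumor spreads through the lymphatic system (paracolic →
intermediate → central lymph nodes) and to the liver, each metastasis is
founded by cells of one or more subclones of the primary tumor — or of an
earlier metastasis. Given per-mutation cancer cell fraction (CCF) estimates
(PyClone-style output: mutations grouped into clusters, with per-region CCFs
and sequencing depths), `metroutes` reconstructs, per patient:

1. **merged CCFs** for multi-region lesions — depth-weighted mean, capped at
   one: CCF = min(1, Σᵢ CCFᵢ·dᵢ / Σᵢ dᵢ);
2. **clonality calls** per cluster and lesion — clonal (mean CCF > 0.85),
   absent (≤ 0.05), subclonal in between — and trunk/branch/leaf cluster
   roles (the trunk, clonal in every lesion, is the most recent clone
   ancestor, MRCA);
3. the **clone tree** by the pigeonhole principle: two subclones are nested
   when their joint CCF exceeds a shared ancestor's capacity anywhere, and
   are disjoint (branching) when their relative CCFs reverse between
   lesions;
4. the **parsimonious metastatic map**: each metastasis gets exactly one
   source lesion such that metastasis-to-metastasis routes are minimized,
   lymphatic spread is proximal-to-distal, and the seeding clones — read
   from each lesion's clonal composition — must exist as cell populations
   in the source. Each seeding is classified monoclonal (all present
   clusters clonal) or multiclonal, and each route as inter-layer
   sequential, inter-layer skip, or intra-layer spread over the
   T → P → I → C → LM network;
5. plus a **synthetic-data generator** producing patients with known clone
   trees and seeding histories (binomial read noise at configurable depth,
   default 264X) for end-to-end benchmarking.

The package is written as scikit-learn-style estimators (`RouteAnalyzer`,
`CloneTreeBuilder`, `MetastaticMapBuilder`, `ClonalityCaller`,
`ClusterFilter`) with thin functional wrappers, and a `metroutes` command
line for TSV-in / TSV-Newick-DOT-JSON-out runs.

## Worked example

`metroutes.examples.lymphatic_reseeding_patient()` is a synthetic patient
with a two-region primary, seven paracolic nodes, two intermediate nodes
and one central node, built so that one subclone (cluster 7) is private to
P6, P7 and P8:

```python
from metroutes import RouteAnalyzer
from metroutes.examples import lymphatic_reseeding_patient

analysis = RouteAnalyzer().fit(lymphatic_reseeding_patient())
print(analysis.tree_.parent)
for r in analysis.map_.routes:
    print(r.source_lesion_id, "->", r.target_lesion_id,
          r.classification, r.mode, r.seeding_clones)
```

prints the clone tree `{'2': '1', '3': '2', '4': '3', '7': '2', '5': '2',
'6': '2'}` and

```
 P6 -> P7  multiclonal intra      clones=2;7      color=7
 P6 -> P8  multiclonal intra      clones=2;3;7    color=7
  T -> C1  multiclonal skip       clones=2;3      color=3
  T -> I1  monoclonal  skip       clones=4        color=4
  T -> I2  monoclonal  skip       clones=2        color=2
  T -> P1  multiclonal sequential clones=2;3      color=3
  T -> P2  multiclonal sequential clones=3;4;5    color=4
  T -> P5  multiclonal sequential clones=2;3;4;5  color=4
  T -> P6  multiclonal sequential clones=2;3;4    color=4
  T -> P9  multiclonal sequential clones=2;3;6    color=6
```

Reading: of the ten seeding events, eight come directly from the primary;
I1 and I2 are monoclonal (every cluster they carry is clonal, so a single
clone founded them); and because cluster 7 exists nowhere upstream, P7 and
P8 can only have been seeded by P6 — a paracolic node reseeding its own
layer — while P6 itself traces back to the primary once cluster 7 is
recognized as having arisen in situ. Each route is colored by its smallest
(most-derived) involved subclone.

The liver counterpart (`liver_crossseeding_patient()`) shows the
complementary pattern: two liver metastases with identical composition and
a private clonal subclone must have seeded one another; the direction is
not identifiable and is reported as an ambiguity group with the
conventional resolution T → LM2 → LM1.

## Command line

```bash
metroutes simulate --out sim/ --seed 4            # mutations.tsv, lesions.tsv, truth.json
metroutes run --mutations sim/mutations.tsv \
              --lesions sim/lesions.tsv --out out/  # routes.tsv, tree.newick, map.dot, summary.json
metroutes summarize --routes out/routes.tsv --lesions sim/lesions.tsv
metroutes check --mutations sim/mutations.tsv --lesions sim/lesions.tsv
```

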