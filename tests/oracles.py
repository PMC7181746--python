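"""Independent brute-force oracles used by the test suite.

These re-derive the documented constraint semantics from scratch
(enumeration over all rooted trees / all source assignments) without
touching the package's search code, so agreement genuinely checks the
implementation's constraint handling and optimization.
"""

from itertools import product

import numpy as np


def enumerate_valid_trees(ccf, status, epsilon=0.05):
    """All rooted trees over the clusters consistent with the pigeonhole
    constraints, as parent maps (trunk absent from the map).

    ``ccf``/``status`` are DataFrames (clusters x lesions). The rules:

    * the root is the unique cluster clonal in every lesion;
    * edge nesting: a child's CCF never exceeds its parent's capacity
      (capacity = 1 where the parent is clonal, its CCF otherwise) by more
      than epsilon, in any lesion;
    * reversed pairs (each strictly above the other somewhere) are never
      ancestor-related;
    * consistent-order pairs are never nested against the order;
    * two clusters in disjoint subtrees never jointly exceed any common
      ancestor's capacity by more than epsilon.
    """
    clusters = list(ccf.index)
    trunk = [c for c in clusters if (status.loc[c] == "clonal").all()]
    if len(trunk) != 1:
        return []
    root = trunk[0]
    others = [c for c in clusters if c != root]
    vec = {c: ccf.loc[c].to_numpy(dtype=float) for c in clusters}
    cap = {
        c: np.where(status.loc[c].to_numpy() == "clonal", 1.0, vec[c])
        for c in clusters
    }

    strict = {
        (a, b): bool(np.any(vec[a] > vec[b] + epsilon))
        for a in clusters
        for b in clusters
        if a != b
    }

    def ancestors(parent, node):
        out = []
        while node in parent:
            node = parent[node]
            out.append(node)
        return out

    valid = []
    for combo in product(*[[p for p in clusters if p != c] for c in others]):
        parent = dict(zip(others, combo))
        # connectivity / acyclicity
        ok = True
        anc = {}
        for c in others:
            chain = []
            node = c
            seen = {c}
            while node in parent:
                node = parent[node]
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                chain.append(node)
            if not ok or node != root:
                ok = False
                break
            anc[c] = chain
        if not ok:
            continue
        anc[root] = []
        for c, p in parent.items():
            if np.any(vec[c] > cap[p] + epsilon):
                ok = False
                break
        if not ok:
            continue
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                related = a in anc[b] or b in anc[a]
                reversed_pair = strict[(a, b)] and strict[(b, a)]
                if reversed_pair and related:
                    ok = False
                if not reversed_pair:
                    # consistent order: the strictly-smaller cluster can
                    # never be the ancestor
                    if strict[(a, b)] and b in anc[a]:
                        ok = False
                    if strict[(b, a)] and a in anc[b]:
                        ok = False
                if not related:
                    common = set(anc[a]) & set(anc[b])
                    for z in common:
                        if np.any(vec[a] + vec[b] > cap[z] + epsilon):
                            ok = False
                            break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            valid.append(parent)
    return valid


def min_metastasis_routes(candidates, primary):
    """Exhaustive minimum of metastasis-to-metastasis routes over all
    acyclic source assignments; None when no acyclic assignment exists.

    ``candidates`` maps each metastasis to its admissible source lesions.
    """
    mets = sorted(candidates)
    best = None
    for combo in product(*[candidates[m] for m in mets]):
        sigma = dict(zip(mets, combo))
        # acyclic iff following source pointers from every metastasis
        # terminates (the only terminal lesion is the primary)
        ok = True
        for start in mets:
            node, hops = start, 0
            while node in sigma:
                node = sigma[node]
                hops += 1
                if hops > len(mets):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        cost = sum(1 for s in sigma.values() if s != primary)
        if best is None or cost < best:
            best = cost
    return best
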