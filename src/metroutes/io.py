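"""Readers and writers: TSV tables, Newick clone trees, DOT metastatic maps.

Tables are UTF-8 tab-separated with a header row and no index column,
matching PyClone-era tooling conventions. CCF values are read verbatim;
capping to [0, 1] happens only inside the depth-weighted merge.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import dendropy
import pandas as pd

from .model import (
    CloneTree,
    FormatError,
    Lesion,
    MetastaticMap,
    MutationCall,
    Route,
    ValidationError,
)

log = logging.getLogger("metroutes")

_MUTATION_COLUMNS = ("mutation_id", "sample_id", "ccf", "depth", "cluster_id")
_OPTIONAL_INT = ("ref_count", "alt_count", "major_cn", "minor_cn")

ROUTE_TABLE_COLUMNS = (
    "patient_id",
    "source_lesion",
    "target_lesion",
    "seeding_clones",
    "n_seeding_clones",
    "seeding_class",
    "mode",
    "color_cluster",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def read_mutation_table(path, dialect: str = "tsv") -> List[MutationCall]:
    """Read a per-region mutation CCF table.

    Requires columns mutation_id, sample_id, ccf, depth, cluster_id;
    optional ref_count/alt_count/major_cn/minor_cn/purity are attached when
    present, other columns are ignored.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str)
    _require_columns(df, _MUTATION_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        kwargs = {}
        try:
            kwargs["ccf"] = float(getattr(row, "ccf"))
            kwargs["depth"] = int(float(getattr(row, "depth")))
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-numeric ccf/depth on line {i}")
        for col in _OPTIONAL_INT:
            if col in df.columns:
                val = getattr(row, col)
                if pd.notna(val) and val != "":
                    try:
                        kwargs[col] = int(float(val))
                    except (TypeError, ValueError):
                        raise FormatError(f"{path}: non-numeric {col} on line {i}")
        if "purity" in df.columns:
            val = getattr(row, "purity")
            if pd.notna(val) and val != "":
                try:
                    kwargs["purity"] = float(val)
                except (TypeError, ValueError):
                    raise FormatError(f"{path}: non-numeric purity on line {i}")
        records.append(
            MutationCall(
                mutation_id=str(getattr(row, "mutation_id")),
                sample_id=str(getattr(row, "sample_id")),
                cluster_id=str(getattr(row, "cluster_id")),
                **kwargs,
            )
        )
    log.info("read %d mutation calls from %s", len(records), path)
    return records


def write_mutation_table(mutations: Iterable[MutationCall], path) -> None:
    rows = []
    for m in mutations:
        rows.append(
            {
                "mutation_id": m.mutation_id,
                "sample_id": m.sample_id,
                "ccf": m.ccf,
                "depth": m.depth,
                "cluster_id": m.cluster_id,
                "ref_count": m.ref_count,
                "alt_count": m.alt_count,
                "major_cn": m.major_cn,
                "minor_cn": m.minor_cn,
                "purity": m.purity,
            }
        )
    df = pd.DataFrame(rows)
    # drop wholly-empty optional columns so round-trips are clean
    for col in ("ref_count", "alt_count", "major_cn", "minor_cn", "purity"):
        if col in df.columns and df[col].isna().all():
            df = df.drop(columns=[col])
    df.to_csv(path, sep="\t", index=False)


def read_lesion_table(path) -> List[Lesion]:
    """Read the lesion metadata table (one row per region sample).

    Columns: lesion_id, layer (one of T/P/I/C/LM), sample_id. Regions are
    grouped by lesion in file order; exactly one lesion may have layer T.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("lesion_id", "layer", "sample_id"), path)
    lesions: List[Lesion] = []
    order: List[str] = []
    regions: dict = {}
    layers: dict = {}
    for row in df.itertuples(index=False):
        lid, layer, sid = str(row.lesion_id), str(row.layer), str(row.sample_id)
        if lid not in regions:
            regions[lid] = []
            layers[lid] = layer
            order.append(lid)
        elif layers[lid] != layer:
            raise ValidationError(f"{path}: lesion {lid} listed with two layers")
        regions[lid].append(sid)
    primaries = [lid for lid in order if layers[lid] == "T"]
    if len(primaries) > 1:
        raise ValidationError(
            f"{path}: more than one lesion with layer T: {primaries}"
        )
    for lid in order:
        lesions.append(Lesion(lesion_id=lid, layer=layers[lid],
                              region_sample_ids=tuple(regions[lid])))
    log.info("read %d lesions from %s", len(lesions), path)
    return lesions


def write_lesion_table(lesions: Iterable[Lesion], path) -> None:
    rows = [
        {"lesion_id": l.lesion_id, "layer": l.layer, "sample_id": sid}
        for l in lesions
        for sid in l.region_sample_ids
    ]
    pd.DataFrame(rows, columns=["lesion_id", "layer", "sample_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_route_table(routes: Sequence[Route], path, patient_id: str = "") -> None:
    """Write the inferred routes as a TSV (header always written)."""
    rows = [
        {
            "patient_id": patient_id,
            "source_lesion": r.source_lesion_id,
            "target_lesion": r.target_lesion_id,
            "seeding_clones": ";".join(r.seeding_clones),
            "n_seeding_clones": len(r.seeding_clones),
            "seeding_class": r.classification,
            "mode": r.mode,
            "color_cluster": r.color_cluster,
        }
        for r in routes
    ]
    pd.DataFrame(rows, columns=list(ROUTE_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_route_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ROUTE_TABLE_COLUMNS, path)
    return df


def tree_to_newick(tree: CloneTree) -> str:
    """Newick string with cluster IDs as labels and branch lengths equal to
    the number of substitutions in each cluster."""
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    nodes = {}
    for cid in tree.nodes:
        node = dendropy.Node()
        node.label = cid
        n_mut = tree.n_mutations.get(cid)
        if n_mut is not None:
            node.edge.length = float(n_mut)
        nodes[cid] = node
    dtree.seed_node = nodes[tree.root]
    for child, parent in tree.parent.items():
        nodes[parent].add_child(nodes[child])
    for node in dtree.seed_node.leaf_iter():
        node.taxon = taxa.new_taxon(node.label)
        node.label = None
    return dtree.as_string(schema="newick", suppress_rooting=True).strip()


def write_tree_newick(tree: CloneTree, path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n", encoding="utf-8")


def map_to_dot(mmap: MetastaticMap, lesions: Sequence[Lesion]) -> str:
    """Render the metastatic map as a GraphViz DOT digraph.

    Nodes are lesions annotated with their layer; edges are seeding routes
    annotated with the color cluster (the smallest involved subclone).
    """
    lines = [f'digraph "{mmap.patient_id}" {{']
    for l in lesions:
        lines.append(f'  "{l.lesion_id}" [label="{l.lesion_id}\\n{l.layer}"];')
    for r in mmap.routes:
        attrs = []
        if r.color_cluster is not None:
            attrs.append(f'label="{r.color_cluster}"')
        if r.mode is not None:
            attrs.append(f'comment="{r.mode}"')
        attr_s = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(
            f'  "{r.source_lesion_id}" -> "{r.target_lesion_id}"{attr_s};'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_map_dot(mmap: MetastaticMap, lesions: Sequence[Lesion], path) -> None:
    Path(path).write_text(map_to_dot(mmap, lesions), encoding="utf-8")


def write_ccf_matrix(matrix, path) -> None:
    """Write a ClusterCCFMatrix as TSV: clusters as rows, lesions as
    columns, mean CCF cells, plus an n_mutations column."""
    df = matrix.ccf.copy()
    df.insert(0, "n_mutations", matrix.n_mutations.loc[df.index])
    df.index.name = "cluster_id"
    df.to_csv(path, sep="\t")


def read_ccf_matrix(path):
    from .model import ClusterCCFMatrix

    df = pd.read_csv(path, sep="\t", index_col="cluster_id")
    df.index = df.index.astype(str)
    n_mutations = df.pop("n_mutations")
    return ClusterCCFMatrix(ccf=df, n_mutations=n_mutations)


def write_summary_json(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
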