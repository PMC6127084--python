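"""File formats: genotype/Ct TSV, FASTA, Newick trees and JSON sidecars.

Conventions: missing genotype calls are written as the literal ``NA``;
Ct matrices use ``<assay>__repN`` columns; trees are written as Newick
with branch lengths (numbers of evolutionary changes) and bootstrap
supports as internal node labels, with a JSON sidecar giving each
node's genotype, cell count, inferred flag and xenograft T-status;
FASTA sequences are normalised to upper case on read.
"""

from __future__ import annotations

import json

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clonetree import ROOT, CloneNode, CloneTree
from .genotyping import GenotypeMatrix
from .markers import Marker, ValidationError
from .simdata import BreakpointSequence

NA_TOKEN = "NA"


# -- genotype and Ct matrices ------------------------------------------------


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    df = gm.calls.copy()
    df.insert(0, "cell_id", df.index)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_genotype_tsv(path, markers: list[Marker]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    if "cell_id" not in df.columns:
        raise ValidationError(f"{path}: missing cell_id column")
    df = df.set_index("cell_id")
    df.index.name = None
    mids = [m.id for m in markers]
    missing = [m for m in mids if m not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing marker columns {missing}")
    calls = df[mids].astype("Int64")
    return GenotypeMatrix(calls=calls, markers=list(markers))


def write_ct_tsv(ct: pd.DataFrame, path) -> None:
    out = ct.copy()
    out.insert(0, "cell_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise ValidationError(f"{path}: missing cell_id column")
    df = df.set_index("cell_id")
    df.index.name = None
    return df


# -- FASTA -------------------------------------------------------------------


def write_fasta(records: list[BreakpointSequence], path, sidecar_path=None) -> None:
    """Write sequences; planted-element offsets go to a sidecar TSV."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, path, "fasta")
    if sidecar_path is not None:
        rows = [
            {
                "sequence_id": r.id,
                "embed": r.embed,
                "start": "" if r.offset_start is None else r.offset_start,
                "end": "" if r.offset_end is None else r.offset_end,
                "strand": r.strand or "",
            }
            for r in records
        ]
        pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by id; bases normalised to upper case."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# -- Newick trees ------------------------------------------------------------


def tree_to_newick(tree: CloneTree) -> str:
    """Newick with branch lengths = change counts, supports as labels."""

    def fmt(node_id: str) -> str:
        kids = sorted(tree.children(node_id))
        label = node_id
        node = tree.nodes[node_id]
        if node.support is not None:
            label = f"{node_id}|{node.support:g}"
        blen = ""
        if tree.parent[node_id] is not None:
            blen = f":{tree.branch_length(tree.parent[node_id], node_id)}"
        if not kids:
            return f"{label}{blen}"
        inner = ",".join(fmt(k) for k in kids)
        return f"({inner}){label}{blen}"

    return fmt(ROOT) + ";"


def write_tree(tree: CloneTree, newick_path, sidecar_path=None) -> None:
    with open(newick_path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(tree.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_tree(newick_path, sidecar_path, markers: list[Marker] | None = None) -> CloneTree:
    """Rebuild a CloneTree from Newick plus its JSON sidecar.

    The sidecar is authoritative for genotypes and flags; the Newick is
    parsed (via dendropy) to recover topology, branch lengths and
    supports, and the two are cross-checked.
    """
    with open(sidecar_path) as fh:
        side = json.load(fh)
    if markers is None:
        raise ValidationError("marker definitions are required to rebuild a tree")
    dtree = dendropy.Tree.get(path=str(newick_path), schema="newick")

    nodes: dict[str, CloneNode] = {}
    parent: dict[str, str | None] = {}
    for nd in dtree.preorder_node_iter():
        raw = nd.taxon.label if nd.taxon else nd.label
        if raw is None:
            raise ValidationError(f"{newick_path}: unlabelled node in Newick")
        name, _, sup = raw.partition("|")
        meta = side["nodes"].get(name)
        if meta is None:
            raise ValidationError(f"{newick_path}: node {name!r} absent from sidecar")
        nodes[name] = CloneNode(
            id=name,
            genotype=tuple(meta["genotype"]),
            n_cells=meta["n_cells"],
            inferred=meta["inferred"],
            support=float(sup) if sup else meta.get("support"),
            t_status=meta.get("t_status"),
        )
        pd_node = nd.parent_node
        if pd_node is None:
            parent[name] = None
        else:
            praw = pd_node.taxon.label if pd_node.taxon else pd_node.label
            parent[name] = praw.partition("|")[0]
    tree = CloneTree(markers=list(markers), nodes=nodes, parent=parent)
    # cross-check: Newick branch lengths equal recomputed change counts
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None or nd.edge.length is None:
            continue
        raw = (nd.taxon.label if nd.taxon else nd.label).partition("|")[0]
        praw = (
            nd.parent_node.taxon.label
            if nd.parent_node.taxon
            else nd.parent_node.label
        ).partition("|")[0]
        if int(nd.edge.length) != tree.branch_length(praw, raw):
            raise ValidationError(
                f"{newick_path}: branch length mismatch on {praw}->{raw}"
            )
    return tree
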