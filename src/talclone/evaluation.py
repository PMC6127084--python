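"""End-to-end pipeline evaluation against simulated ground truth.

These helpers run the full chain — simulate cells, simulate qPCR
readout, call genotypes, QC, collapse to subclones, infer the
maximum-parsimony tree — and score the result against the generating
truth.  They define the package's standard *recovery pipeline*:

* QC drops cells failing controls or missing more than half their calls;
* dropout-shadow absorption at ratio 0.5 (see
  :func:`talclone.clonetree.collapse_subclones`);
* a detection threshold of 5% of kept cells (at least 2) — subclones
  below it are below the level of reliable detection.  The threshold
  must exceed the residual artefact band (single-allele dropout turns
  up to ~ado of a clone's cells into each shadow genotype, ~2–3% of
  cells for a dominant clone) while staying below the cell count an
  eroded genuine subclone retains (a 20%-frequency clone keeps ≳8% of
  cells after dropout and QC losses).

Topology recovery is judged by exact clade-set equality: the best
tree's genotype-labelled edge multiset must equal the truth's.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clonetree import CloneTree, collapse_subclones, infer_parsimony_trees
from .genotyping import build_genotype_matrix, qc_filter_cells
from .markers import Marker
from .panel import AssayPanel
from .simdata import ClonalTruth, NoiseConfig, sample_cells, simulate_ct_readout

SHADOW_RATIO = 0.5
DETECTION_FRACTION = 0.05


def default_recovery_markers(n_subclonal_snvs: int = 8) -> list[Marker]:
    """The standard simulated panel: truncal fusion + bi-allelic
    CDKN2A loss plus ``n_subclonal_snvs`` subclonal SNVs."""
    return [
        Marker("F", "STIL_TAL1", "fusion"),
        Marker("CDKN2A_del", "CDKN2A", "cn_loss"),
    ] + [Marker(f"snv{j + 1}", f"G{j + 1}", "snv") for j in range(n_subclonal_snvs)]


def true_edge_multiset(truth: ClonalTruth) -> tuple:
    return tuple(
        sorted(
            (tuple(truth.genotypes[p]), tuple(truth.genotypes[c]))
            for c, p in truth.parents.items()
            if p is not None
        )
    )


def truncal_on_root_edge(tree: CloneTree, truncal_marker_ids: list[str]) -> bool:
    """True iff every truncal lesion changes only on the edge leaving
    the germline root (and nowhere else)."""
    root_kids = tree.children("N")
    if len(root_kids) != 1:
        return False
    idx = [i for i, m in enumerate(tree.markers) if m.id in truncal_marker_ids]
    first = tree.node_units(root_kids[0])
    if any(first[i] == 0 for i in idx):
        return False
    for p, c in tree.edges():
        if p == "N":
            continue
        pu, cu = tree.node_units(p), tree.node_units(c)
        if any(cu[i] != pu[i] for i in idx):
            return False
    return True


@dataclass
class RecoveryResult:
    topology_recovered: bool
    truncal_on_root: bool
    n_subclones: int
    n_cooptimal: int
    tree: CloneTree


def run_recovery(
    truth: ClonalTruth,
    n_cells: int,
    noise: NoiseConfig,
    seed: int,
    truncal_marker_ids: list[str] | None = None,
) -> RecoveryResult:
    """Simulate → genotype → QC → collapse → infer, scored vs truth."""
    gm_true, _ = sample_cells(truth, n_cells, seed=seed)
    panel = AssayPanel.default_for(truth.markers)
    ct = simulate_ct_readout(gm_true, panel, noise, seed=seed + 1)
    gm = build_genotype_matrix(ct, panel)
    kept, _ = qc_filter_cells(gm, max_missing_frac=0.5)
    min_cells = max(2, round(DETECTION_FRACTION * kept.n_cells))
    sc = collapse_subclones(
        kept, min_cells=min_cells, absorb_dropout_shadows=SHADOW_RATIO
    )
    trees = infer_parsimony_trees(sc)
    best = trees[0]
    recovered = best.canonical_form() == true_edge_multiset(truth)
    truncal_ids = truncal_marker_ids or ["F", "CDKN2A_del"]
    return RecoveryResult(
        topology_recovered=recovered,
        truncal_on_root=truncal_on_root_edge(best, truncal_ids),
        n_subclones=sc.n_subclones,
        n_cooptimal=len(trees),
        tree=best,
    )
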