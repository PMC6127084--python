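"""Clonal phylogeny inference by maximum parsimony with irreversible characters.

Single-cell genotypes are first collapsed into *subclones* (groups of
cells sharing one complete genotype over the marker panel).  A rooted
clone tree is then sought that explains the subclone genotypes with the
fewest evolutionary changes under an ordered, irreversible character
model (Camin–Sokal style):

* sequence markers step 0 → 1 → 2 (wt → het → hom), one unit per step;
* copy-number markers step 2 → 1 → 0 copies, one unit per loss;
* reversals are forbidden (infinite cost); independent parallel origins
  of the same lesion on divergent branches are allowed, which is how
  reiterative driver mutations (e.g. multiple PTEN indels) are
  represented.

The germline root is fixed (all wild type, two copies everywhere).
Because case studies contain at most ~8 subclones the search is
exhaustive over rooted binary topologies; on each topology the unique
optimal ancestral assignment is the component-wise minimum (in change
units) of the descendant genotypes.  Zero-change edges are contracted
afterwards, so observed genotypes may occupy internal positions and
inferred (unobserved) ancestors appear only where they reduce the
score.  The **complete** set of co-optimal trees is returned, matching
the situation where two equally parsimonious histories cannot be
distinguished by the data.

:func:`brute_force_min_score` is an independent check: it enumerates
topologies through a different recursion and scores each with a generic
Sankoff dynamic program over all ancestral states rather than the
min-of-children shortcut.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import GenotypeMatrix
from .markers import (
    Marker,
    ValidationError,
    genotype_to_units,
    units_to_genotype,
)

ROOT = "N"
_BIG = 10 ** 6


class InvariantError(ValueError):
    """A tree violates the irreversible character model."""


# ---------------------------------------------------------------------------
# subclones


@dataclass
class SubcloneSet:
    """Distinct complete genotypes with their cell counts.

    ``genotypes`` are external-state tuples (zygosity 0/1/2, copies
    2/1/0), pairwise distinct, each supported by at least ``min_cells``
    cells.  ``below_threshold`` keeps the genotypes seen in fewer cells
    — candidate clones below the level of reliable detection — and
    ``n_unassigned`` counts cells whose partially-missing genotype
    matched zero or several subclones.  Counts always reconcile with
    the number of input cells.
    """

    markers: list[Marker]
    genotypes: list[tuple[int, ...]]
    counts: list[int]
    total_cells: int
    below_threshold: list[tuple[tuple[int, ...], int]] = field(default_factory=list)
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValidationError("subclone genotypes must be pairwise distinct")
        accounted = (
            sum(self.counts)
            + sum(c for _, c in self.below_threshold)
            + self.n_unassigned
        )
        if accounted != self.total_cells:
            raise ValidationError(
                f"cell counts do not reconcile: {accounted} != {self.total_cells}"
            )

    @property
    def n_subclones(self) -> int:
        return len(self.genotypes)

    def frequencies(self) -> list[float]:
        return [c / self.total_cells for c in self.counts]


def collapse_subclones(
    gm: GenotypeMatrix,
    min_cells: int = 2,
    na_policy: str = "assign_unique",
    absorb_dropout_shadows: float | None = None,
) -> SubcloneSet:
    """Merge identical complete genotype rows into subclones.

    Rows containing NA are assigned to a subclone when exactly one
    candidate genotype matches every non-NA entry
    (``na_policy="assign_unique"``); otherwise they are counted as
    unassigned.  Genotypes supported by fewer than ``min_cells`` cells
    are reported separately, never silently dropped.

    ``absorb_dropout_shadows`` (default off) enables allelic-dropout
    artefact absorption: a genotype is treated as a dropout *shadow* of
    a clone when it is a strict sub-genotype (every marker at most as
    mutated, in change units) of a genotype holding more than
    ``1 / absorb_dropout_shadows`` times its cell count, and its cells
    are merged into that clone.  Dropout at per-allele rate ε turns
    ~ε of a clone's cells into sub-genotype artefacts per heterozygous
    marker, whereas a genuine ancestral clone is sampled at a count
    commensurate with its own frequency, so a ratio well above ε (the
    default used by the recovery pipeline is 0.5) separates the two.
    """
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    if na_policy not in ("assign_unique", "drop"):
        raise ValidationError(f"unknown na_policy {na_policy!r}")
    if absorb_dropout_shadows is not None and not 0 < absorb_dropout_shadows < 1:
        raise ValidationError("absorb_dropout_shadows must be in (0,1)")
    if gm.n_cells == 0:
        raise ValidationError("cannot collapse an empty genotype matrix")

    vals = gm.calls.to_numpy(dtype="float", na_value=np.nan)
    complete = ~np.isnan(vals).any(axis=1)

    counts: dict[tuple[int, ...], int] = {}
    for row in vals[complete]:
        g = tuple(int(v) for v in row)
        counts[g] = counts.get(g, 0) + 1

    if absorb_dropout_shadows is not None:
        units = {
            g: genotype_to_units(g, gm.markers) for g in counts
        }

        def strict_subset(a, b) -> bool:
            return a != b and all(x <= y for x, y in zip(units[a], units[b]))

        # the ratio test uses pre-absorption counts throughout so that a
        # clone inflated by absorbed shadows cannot in turn swallow a
        # genuine ancestor (chains of subclones are nested genotypes)
        original = dict(counts)
        for g in sorted(list(counts), key=original.get):
            if g not in counts:
                continue
            hosts = [
                h for h in counts
                if h != g
                and original[g] <= absorb_dropout_shadows * original[h]
                and strict_subset(g, h)
            ]
            if hosts:
                host = max(hosts, key=original.get)
                counts[host] += counts.pop(g)

    candidates = list(counts)
    n_unassigned = 0
    for row in vals[~complete]:
        if na_policy == "drop":
            n_unassigned += 1
            continue
        obs = ~np.isnan(row)
        matches = [
            g for g in candidates
            if all(row[j] == g[j] for j in np.flatnonzero(obs))
        ]
        if len(matches) == 1:
            counts[matches[0]] += 1
        else:
            n_unassigned += 1

    kept = sorted(
        ((g, c) for g, c in counts.items() if c >= min_cells),
        key=lambda gc: (-gc[1], gc[0]),
    )
    below = sorted(
        ((g, c) for g, c in counts.items() if c < min_cells),
        key=lambda gc: (-gc[1], gc[0]),
    )
    return SubcloneSet(
        markers=list(gm.markers),
        genotypes=[g for g, _ in kept],
        counts=[c for _, c in kept],
        total_cells=gm.n_cells,
        below_threshold=below,
        n_unassigned=n_unassigned,
    )


# ---------------------------------------------------------------------------
# clone trees


@dataclass
class CloneNode:
    id: str
    genotype: tuple[int, ...]  # external states
    n_cells: int = 0
    inferred: bool = False
    support: float | None = None
    t_status: bool | None = None


@dataclass
class CloneTree:
    """A rooted clone tree over observed and inferred subclone genotypes."""

    markers: list[Marker]
    nodes: dict[str, CloneNode]
    parent: dict[str, str | None]

    def __post_init__(self) -> None:
        if ROOT not in self.nodes or self.parent.get(ROOT) is not None:
            raise ValidationError("clone tree must have a germline root 'N'")
        germ = tuple(m.germline_state() for m in self.markers)
        if tuple(self.nodes[ROOT].genotype) != germ:
            raise ValidationError("root genotype must be germline")

    def children(self, node_id: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == node_id]

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, p in self.parent.items() if p is not None]

    def node_units(self, node_id: str) -> tuple[int, ...]:
        return genotype_to_units(self.nodes[node_id].genotype, self.markers)

    def edge_changes(self, parent_id: str, child_id: str) -> list[str]:
        """Unit state changes on an edge, one label per step."""
        pu = self.node_units(parent_id)
        cu = self.node_units(child_id)
        labels = []
        for m, p, c in zip(self.markers, pu, cu):
            if c < p:
                raise InvariantError(
                    f"edge {parent_id}->{child_id} reverses {m.id} ({p}->{c} units)"
                )
            for step in range(p, c):
                if m.is_copy_number:
                    labels.append(f"{m.id}:{2 - step}->{2 - step - 1}copies")
                else:
                    labels.append(f"{m.id}:{step}->{step + 1}")
        return labels

    def branch_length(self, parent_id: str, child_id: str) -> int:
        return len(self.edge_changes(parent_id, child_id))

    def subtree_nodes(self, node_id: str) -> list[str]:
        out = [node_id]
        for c in self.children(node_id):
            out.extend(self.subtree_nodes(c))
        return out

    def clade_signature(self, node_id: str) -> frozenset:
        """Observed genotypes in the subtree (clade identity for bootstrap)."""
        return frozenset(
            tuple(self.nodes[n].genotype)
            for n in self.subtree_nodes(node_id)
            if not self.nodes[n].inferred and n != ROOT
        )

    def canonical_form(self) -> tuple:
        """Order-free identity: sorted multiset of genotype edges."""
        return tuple(
            sorted(
                (tuple(self.nodes[p].genotype), tuple(self.nodes[c].genotype))
                for p, c in self.edges()
            )
        )

    def to_json_dict(self) -> dict:
        return {
            "markers": [m.id for m in self.markers],
            "nodes": {
                n.id: {
                    "genotype": list(n.genotype),
                    "n_cells": n.n_cells,
                    "inferred": n.inferred,
                    "support": n.support,
                    "t_status": n.t_status,
                }
                for n in self.nodes.values()
            },
            "edges": [
                {
                    "parent": p,
                    "child": c,
                    "changes": self.edge_changes(p, c),
                    "length": self.branch_length(p, c),
                }
                for p, c in self.edges()
            ],
        }


def parsimony_score(tree: CloneTree) -> int:
    """Total unit changes over all edges (== sum of branch lengths)."""
    return sum(tree.branch_length(p, c) for p, c in tree.edges())


# -- topology enumeration (edge insertion) ----------------------------------


def _topologies_by_insertion(k: int):
    """All rooted binary leaf-labelled topologies on leaves 0..k-1.

    Standard stepwise-addition enumeration: leaf ``i`` is inserted on
    every edge (including above the root) of every tree over leaves
    ``0..i-1``; yields each topology exactly once, (2k-3)!! in total.
    """

    def insert(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            left, right = t
            for nl in insert(left, leaf):
                yield (nl, right)
            for nr in insert(right, leaf):
                yield (left, nr)

    def grown(leaf):
        if leaf == 0:
            yield 0
            return
        for t in grown(leaf - 1):
            yield from insert(t, leaf)

    yield from grown(k - 1)


def _assign_min(t, units: list[np.ndarray]):
    """Component-wise-minimum ancestral assignment and subtree cost.

    Returns ``(node_units, cost_below)`` for nested-tuple topology
    ``t``; the unique optimal assignment under the irreversible model.
    """
    if not isinstance(t, tuple):
        return units[t], 0
    lu, lc = _assign_min(t[0], units)
    ru, rc = _assign_min(t[1], units)
    here = np.minimum(lu, ru)
    cost = lc + rc + int((lu - here).sum()) + int((ru - here).sum())
    return here, cost


def _tree_from_topology(
    t, sc: SubcloneSet, units: list[np.ndarray]
) -> CloneTree:
    """Materialise a scored topology as a CloneTree with contraction."""
    markers = sc.markers
    germ_units = np.zeros(len(markers), dtype=int)
    nodes: dict[str, CloneNode] = {
        ROOT: CloneNode(ROOT, tuple(m.germline_state() for m in markers))
    }
    parent: dict[str, str | None] = {ROOT: None}
    counter = itertools.count(1)
    obs = {tuple(u): i for i, u in enumerate(map(tuple, units))}

    def build(sub, parent_id: str, parent_units: np.ndarray) -> None:
        if isinstance(sub, tuple):
            u, _ = _assign_min(sub, units)
        else:
            u = units[sub]
        if np.array_equal(u, parent_units):
            node_id = parent_id  # zero-change edge: contract into parent
        else:
            node_id = f"_tmp{next(counter)}"
            nodes[node_id] = CloneNode(
                node_id, units_to_genotype(u, markers), inferred=True
            )
            parent[node_id] = parent_id
        if isinstance(sub, tuple):
            build(sub[0], node_id, u)
            build(sub[1], node_id, u)

    build(t, ROOT, germ_units)

    # mark observed nodes, attach counts, and name clones by frequency rank
    for node_id, node in nodes.items():
        key = tuple(genotype_to_units(node.genotype, markers))
        if node_id == ROOT:
            if key in obs:  # germline cells observed in the sample
                node.n_cells = sc.counts[obs[key]]
            continue
        if key in obs:
            node.inferred = False
            node.n_cells = sc.counts[obs[key]]

    rank = {g: r for r, g in enumerate(sc.genotypes)}
    rename: dict[str, str] = {ROOT: ROOT}
    used = {ROOT}
    inferred_i = itertools.count(1)
    for node_id, node in sorted(nodes.items()):
        if node_id == ROOT:
            continue
        name = (
            f"A{next(inferred_i)}"
            if node.inferred
            else f"C{rank[tuple(node.genotype)] + 1}"
        )
        while name in used:  # duplicated genotype at two positions (rare)
            name += "'"
        used.add(name)
        rename[node_id] = name
    new_nodes = {}
    new_parent = {}
    for node_id, node in nodes.items():
        nid = rename[node_id]
        node.id = nid
        new_nodes[nid] = node
        p = parent[node_id]
        new_parent[nid] = rename[p] if p is not None else None
    return CloneTree(markers=markers, nodes=new_nodes, parent=new_parent)


def infer_parsimony_trees(sc: SubcloneSet, max_subclones: int = 10) -> list[CloneTree]:
    """All co-optimal maximum-parsimony clone trees for a subclone set.

    Exhaustive over rooted binary topologies (feasible for the ≤ ~8
    subclones seen per case); on each topology ancestral genotypes take
    the unique optimal component-wise minimum assignment.  Co-optimal
    topologies are materialised, zero-change edges contracted, and
    duplicates removed by their canonical genotype-edge multiset.
    Trees are returned in canonical sort order.
    """
    k = sc.n_subclones
    if k < 1:
        raise ValidationError("need at least one subclone")
    if k > max_subclones:
        raise ValidationError(
            f"{k} subclones exceeds the practical exhaustive-search bound "
            f"({max_subclones})"
        )
    units = [
        np.array(genotype_to_units(g, sc.markers), dtype=int) for g in sc.genotypes
    ]

    if k == 1:
        return [_tree_from_topology(0, sc, units)]

    best_score = None
    best_topologies = []
    for t in _topologies_by_insertion(k):
        root_units, below = _assign_min(t, units)
        score = below + int(root_units.sum())
        if best_score is None or score < best_score:
            best_score, best_topologies = score, [t]
        elif score == best_score:
            best_topologies.append(t)

    seen = {}
    for t in best_topologies:
        tree = _tree_from_topology(t, sc, units)
        seen.setdefault(tree.canonical_form(), tree)
    trees = [seen[key] for key in sorted(seen)]
    for tree in trees:  # invariant: contraction never changes the score
        assert parsimony_score(tree) == best_score
    return trees


# -- independent oracle ------------------------------------------------------


def _topologies_by_bipartition(leaves: tuple):
    """Rooted binary topologies via recursive leaf-set bipartition.

    A deliberately different enumeration from the stepwise-addition
    generator, used only by the brute-force oracle.
    """
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for r in range(len(rest)):
        for left_rest in itertools.combinations(rest, r):
            left = (first,) + left_rest
            right = tuple(x for x in rest if x not in left_rest)
            if not right:
                continue
            for tl in _topologies_by_bipartition(left):
                for tr in _topologies_by_bipartition(right):
                    yield (tl, tr)


def brute_force_min_score(sc: SubcloneSet) -> int:
    """Global minimum parsimony score by exhaustive Sankoff search.

    Enumerates every rooted binary topology (bipartition recursion) and
    scores each with a generic Sankoff dynamic program over all
    ancestral states per marker, with cost ``s' - s`` for ``s' >= s``
    and infinity for reversals, root fixed at germline.  Refuses more
    than 7 subclones.
    """
    k = sc.n_subclones
    if k > 7:
        raise ValidationError("brute-force oracle refuses more than 7 subclones")
    if k < 1:
        raise ValidationError("need at least one subclone")
    units = np.array(
        [genotype_to_units(g, sc.markers) for g in sc.genotypes], dtype=int
    )
    n_mark = units.shape[1]

    def sankoff(t) -> np.ndarray:
        """M[s, j] = min cost of subtree t if its root has state s at marker j."""
        if not isinstance(t, tuple):
            m = np.full((3, n_mark), _BIG)
            m[units[t], np.arange(n_mark)] = 0
            return m
        total = np.zeros((3, n_mark))
        for child in t:
            mc = sankoff(child)
            # D[s] = min over s' >= s of (s' - s) + mc[s']
            d = np.empty_like(mc)
            d[2] = mc[2]
            d[1] = np.minimum(mc[1], mc[2] + 1)
            d[0] = np.minimum(mc[0], np.minimum(mc[1] + 1, mc[2] + 2))
            total = total + d
        return total

    best = None
    for t in _topologies_by_bipartition(tuple(range(k))):
        if k == 1:
            m = sankoff(t)
        else:
            m = sankoff(t)
        # germline parent at state 0: edge cost s + subtree cost
        score = int((np.minimum.reduce([m[0], m[1] + 1, m[2] + 2])).sum())
        if best is None or score < best:
            best = score
    return best


# ---------------------------------------------------------------------------
# bootstrap and reiterative events


def bootstrap_support(
    gm: GenotypeMatrix,
    n_reps: int = 100,
    seed: int = 0,
    min_cells: int = 2,
    na_policy: str = "assign_unique",
) -> CloneTree:
    """Best clone tree with per-node bootstrap support.

    Cells (rows) are resampled with replacement ``n_reps`` times; each
    replicate is re-collapsed and re-inferred.  A node's support is the
    percentage of replicates whose best tree contains a clade with the
    same observed-genotype set.  Cells, not markers, are resampled
    because panels are small (5–10 markers) and the dominant sampling
    noise is in clone frequencies.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    sc = collapse_subclones(gm, min_cells=min_cells, na_policy=na_policy)
    best = infer_parsimony_trees(sc)[0]

    targets = {
        node_id: best.clade_signature(node_id)
        for node_id in best.nodes
        if node_id != ROOT
    }
    hits = {node_id: 0 for node_id in targets}

    rng = np.random.default_rng(seed)
    n = gm.n_cells
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        rep_gm = GenotypeMatrix(
            calls=gm.calls.iloc[idx].set_axis(range(n)),
            markers=gm.markers,
            qc=gm.qc.iloc[idx].set_axis(range(n)),
        )
        try:
            rep_sc = collapse_subclones(rep_gm, min_cells=min_cells, na_policy=na_policy)
            rep_tree = infer_parsimony_trees(rep_sc)[0]
        except ValidationError:
            continue
        rep_clades = {
            rep_tree.clade_signature(nid) for nid in rep_tree.nodes if nid != ROOT
        }
        for node_id, sig in targets.items():
            if sig in rep_clades:
                hits[node_id] += 1

    for node_id, h in hits.items():
        best.nodes[node_id].support = 100.0 * h / n_reps
    return best


def detect_reiterative_events(trees: list[CloneTree]) -> dict[str, dict]:
    """Count independent origins per gene across the co-optimal trees.

    For each gene, the number of distinct edges on which any marker of
    that gene changes is counted per tree; the minimum over co-optimal
    trees is reported (the count the data *forces*).  Genes with two or
    more origins are flagged reiterative.
    """
    if not trees:
        raise ValidationError("tree set must not be empty")
    genes = sorted({m.gene for m in trees[0].markers})
    per_tree: dict[str, list[int]] = {g: [] for g in genes}
    for tree in trees:
        counts = {g: 0 for g in genes}
        for p, c in tree.edges():
            pu, cu = tree.node_units(p), tree.node_units(c)
            changed_genes = {
                m.gene for m, a, b in zip(tree.markers, pu, cu) if b > a
            }
            for g in changed_genes:
                counts[g] += 1
        for g in genes:
            per_tree[g].append(counts[g])
    return {
        g: {"origins": min(v), "reiterative": min(v) >= 2}
        for g, v in per_tree.items()
        if max(v) > 0
    }
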