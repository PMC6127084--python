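"""Multicolour-FISH signal patterns and containment-ordered clone diagrams.

Interphase FISH scores, per cell, the number of signals for each probe:

* a **fusion-indicator** probe pair reports the number of intact
  co-localised red–green pairs — a normal cell shows 2; a cell carrying
  the fusion (an interstitial deletion joining the two genes) loses one
  red signal while retaining the green control, leaving 1 intact pair;
* **locus copy-number** probes (e.g. 9p21.3/CDKN2A, PTEN, 6q) report
  retained copies 2/1/0.

Identical per-cell state tuples are merged into patterns with
frequencies, and patterns are ordered by *lesion containment*: pattern
A is ancestral to B iff every lesion of A is at most as severe as B's
(fusion absent→present, copies only decreasing), the same irreversible
model used for the qPCR clone trees.  The resulting diagram is the
evolutionary ordering that FISH alone supports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonetree import ROOT, CloneNode, CloneTree
from .markers import Marker, ValidationError


@dataclass(frozen=True)
class FishProbe:
    id: str
    kind: str  # fusion_indicator | locus_cn

    def __post_init__(self) -> None:
        if self.kind not in ("fusion_indicator", "locus_cn"):
            raise ValidationError(f"unknown probe kind {self.kind!r}")

    def normal_count(self) -> int:
        return 2  # 2 intact pairs, or 2 copies

    def severity(self, count: int) -> int:
        """Change units away from the normal state (0 = normal)."""
        if count < 0:
            raise ValidationError(f"negative signal count for {self.id!r}")
        if count > 2:
            raise ValidationError(
                f"{self.id!r}: {count} signals exceeds the diploid state; "
                "gains cannot be ordered under the loss-only model"
            )
        if self.kind == "fusion_indicator":
            # 2 intact pairs = normal; 1 pair = fusion present
            return 2 - count if count >= 1 else 1
        return 2 - count

    def as_marker(self) -> Marker:
        kind = "fusion" if self.kind == "fusion_indicator" else "cn_loss"
        return Marker(self.id, self.id.split("_")[0], kind)


@dataclass
class FishCellTable:
    """Per-cell signal counts: one column per probe."""

    counts: pd.DataFrame
    probes: list[FishProbe]

    def __post_init__(self) -> None:
        if list(self.counts.columns) != [p.id for p in self.probes]:
            raise ValidationError("count columns must match probe list")
        if self.counts.empty:
            raise ValidationError("FISH cell table is empty")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("signal counts must be non-negative")


@dataclass
class FishPattern:
    states: tuple[int, ...]  # per-probe signal counts
    n_cells: int
    frequency_pct: float


def tabulate_fish_patterns(
    tbl: FishCellTable, min_cells: int = 1
) -> tuple[list[FishPattern], list[FishPattern]]:
    """Merge identical state tuples into frequency-annotated patterns.

    Returns ``(patterns, below_threshold)``; frequencies are percentages
    of all scored cells and conserve the cell total across both lists.
    """
    total = len(tbl.counts)
    counted: dict[tuple[int, ...], int] = {}
    for row in tbl.counts.to_numpy():
        key = tuple(int(v) for v in row)
        counted[key] = counted.get(key, 0) + 1
    ordered = sorted(counted.items(), key=lambda kv: (-kv[1], kv[0]))
    patterns, below = [], []
    for states, n in ordered:
        p = FishPattern(states=states, n_cells=n, frequency_pct=100.0 * n / total)
        (patterns if n >= min_cells else below).append(p)
    return patterns, below


def _severity(pattern: FishPattern, probes: list[FishProbe]) -> tuple[int, ...]:
    return tuple(p.severity(s) for p, s in zip(probes, pattern.states))


def contains(a: tuple[int, ...], b: tuple[int, ...]) -> bool:
    """True iff severity vector ``a`` is ancestral-or-equal to ``b``."""
    return all(x <= y for x, y in zip(a, b))


def build_containment_tree(
    patterns: list[FishPattern], probes: list[FishProbe]
) -> CloneTree:
    """Order FISH patterns into a rooted diagram by lesion containment.

    The normal state is the root (added as an inferred node when not
    observed).  Each pattern's parent is its most severe strict
    ancestor among the placed nodes; when several incomparable
    candidates tie, the pattern is attached under their meet (the
    component-wise least severe state), inserted as an inferred node —
    incomparable patterns thus become siblings under their meet.
    """
    if not patterns:
        raise ValidationError("no patterns to order")
    markers = [p.as_marker() for p in probes]
    germ = tuple(0 for _ in probes)

    # distinct signal tuples with the same lesion interpretation (e.g.
    # fusion-pair counts 0 and 1 both read "fusion present") merge here
    cells: dict[tuple[int, ...], int] = {}
    for p in patterns:
        s = _severity(p, probes)
        cells[s] = cells.get(s, 0) + p.n_cells
    sev = cells
    def genotype_of(s: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(m.units_to_state(u) for m, u in zip(markers, s))

    def maximal_strict_ancestors(s, universe):
        anc = [t for t in universe if contains(t, s) and t != s]
        return [
            t for t in anc
            if not any(contains(t, u) and t != u for u in anc)
        ]

    # pass 1: close the node set under meets of ambiguous ancestries —
    # wherever a pattern has several incomparable maximal ancestors, the
    # component-wise minimum (their meet) is added as an inferred node
    universe = set(sev) | {germ}
    changed = True
    while changed:
        changed = False
        for s in sorted(universe, key=lambda v: (sum(v), v)):
            maximal = maximal_strict_ancestors(s, universe)
            if len(maximal) > 1:
                meet = tuple(np.minimum.reduce([np.array(t) for t in maximal]))
                if meet not in universe:
                    universe.add(meet)
                    changed = True

    # pass 2: parents from the closed set — the unique maximal strict
    # ancestor, or the meet of several incomparable ones (present by
    # closure), making ambiguous patterns siblings under their meet
    ids: dict[tuple[int, ...], str] = {germ: ROOT}
    counter = itertools.count(1)
    inferred_counter = itertools.count(1)
    for s in sorted(universe, key=lambda v: (sum(v), v)):
        if s == germ:
            continue
        ids[s] = f"P{next(counter)}" if s in sev else f"A{next(inferred_counter)}"

    nodes: dict[str, CloneNode] = {
        ROOT: CloneNode(
            ROOT,
            tuple(m.germline_state() for m in markers),
            n_cells=sev.get(germ, 0),
            inferred=germ not in sev,
        )
    }
    parent: dict[str, str | None] = {ROOT: None}
    for s, node_id in ids.items():
        if s == germ:
            continue
        nodes[node_id] = CloneNode(
            node_id, genotype_of(s), n_cells=sev.get(s, 0), inferred=s not in sev
        )
        maximal = maximal_strict_ancestors(s, universe)
        if len(maximal) == 1:
            parent_vec = maximal[0]
        else:
            parent_vec = tuple(np.minimum.reduce([np.array(t) for t in maximal]))
        parent[node_id] = ids[parent_vec]

    return CloneTree(markers=markers, nodes=nodes, parent=parent)
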