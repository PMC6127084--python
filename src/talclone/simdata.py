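"""Synthetic clonal-evolution scenarios with known ground truth.

This module generates the data structures the rest of the pipeline
consumes, with full knowledge of the underlying truth so every stage can
be tested end to end:

* a clonal tree (:class:`ClonalTruth`) whose root is the germline state
  and whose first leukaemic node carries the truncal lesions (the
  subtype-defining fusion and, typically, bi-allelic CDKN2A loss);
* per-cell true genotypes sampled from the subclone frequencies;
* duplicated multiplex qPCR Ct readouts with allelic dropout,
  per-well amplification failure and Gaussian Ct noise;
* xenograft resamples under a re-weighted subclone distribution
  (engraftment bottleneck / clonal selection);
* breakpoint-flanking DNA sequences with or without a planted
  recombination signal sequence (RSS).

The Ct generative model is deliberately simple: a diploid baseline Ct,
one cycle added per halving of the detectable template (so one cycle
per lost copy), Gaussian well noise, and a no-amplification sentinel
when no template remains.  Allelic dropout is modelled as a per-cell,
per-allele loss before amplification — duplicate wells share the cell's
surviving alleles but fail independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import (
    Marker,
    ValidationError,
    as_marker,
    genotype_to_units,
    units_to_genotype,
)
from .panel import AssayPanel

ROOT = "N"  #: germline root node label

#: default sentinel for "no amplification" wells
NO_AMP = -1.0


@dataclass
class NoiseConfig:
    """Noise model for the single-cell qPCR readout.

    allelic_dropout_rate
        Probability, per allele per cell, that the allele is lost before
        amplification (whole-genome-amplification dropout).  Shared by
        both duplicate wells.
    assay_failure_rate
        Probability, per well, that amplification fails outright.
    ct_baseline
        Ct of a diploid (two-template) well, cycles.
    ct_per_copy_shift
        Cycles added per halving of template (default 1.0/copy lost).
    ct_sd
        Gaussian well-to-well Ct noise, cycles.
    no_amp_sentinel
        Value written for non-amplifying wells.
    """

    allelic_dropout_rate: float = 0.0
    assay_failure_rate: float = 0.0
    ct_baseline: float = 24.0
    ct_per_copy_shift: float = 1.0
    ct_sd: float = 0.0
    no_amp_sentinel: float = NO_AMP

    def __post_init__(self) -> None:
        for name in ("allelic_dropout_rate", "assay_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.ct_sd < 0:
            raise ValidationError("ct_sd must be >= 0")


@dataclass
class ClonalTruth:
    """A ground-truth clonal tree.

    ``parents`` maps each node to its parent (the germline root ``N``
    has parent ``None``); ``genotypes`` holds external-state vectors
    over ``markers`` for every node including the root; ``frequencies``
    are the population fractions of the leukaemic clones (root
    excluded) and sum to 1.
    """

    markers: list[Marker]
    parents: dict[str, str | None]
    genotypes: dict[str, tuple[int, ...]]
    frequencies: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if ROOT not in self.parents or self.parents[ROOT] is not None:
            raise ValidationError("truth must contain a germline root 'N'")
        germ = tuple(m.germline_state() for m in self.markers)
        if tuple(self.genotypes[ROOT]) != germ:
            raise ValidationError("root genotype must be germline (all wt, 2 copies)")
        for node, parent in self.parents.items():
            if parent is None:
                continue
            pu = genotype_to_units(self.genotypes[parent], self.markers)
            cu = genotype_to_units(self.genotypes[node], self.markers)
            if any(c < p for p, c in zip(pu, cu)):
                raise ValidationError(
                    f"irreversibility violated on edge {parent}->{node}"
                )
        freqs = np.array([self.frequencies[c] for c in self.clones()])
        if (freqs < 0).any() or not np.isclose(freqs.sum(), 1.0):
            raise ValidationError(
                f"clone frequencies must be >= 0 and sum to 1 (sum={freqs.sum():.6f})"
            )

    def clones(self) -> list[str]:
        """Leukaemic clone labels, root excluded, in insertion order."""
        return [n for n in self.parents if n != ROOT]

    def genotype_frame(self) -> pd.DataFrame:
        """Clone × marker table of external states."""
        return pd.DataFrame(
            {c: list(self.genotypes[c]) for c in self.clones()},
            index=[m.id for m in self.markers],
        ).T

    def path_to_root(self, node: str) -> list[str]:
        path = [node]
        while self.parents[path[-1]] is not None:
            path.append(self.parents[path[-1]])
        return path

    def to_json_dict(self) -> dict:
        return {
            "markers": [
                {"id": m.id, "gene": m.gene, "kind": m.kind} for m in self.markers
            ],
            "edges": [
                {"parent": p, "child": c}
                for c, p in self.parents.items()
                if p is not None
            ],
            "genotypes": {n: list(g) for n, g in self.genotypes.items()},
            "frequencies": dict(self.frequencies),
            "seed": self.seed,
        }


def _antichain(parents: dict[str, str | None], nodes: list[str], k: int,
               rng: np.random.Generator) -> list[str] | None:
    """Find k pairwise non-ancestral nodes, or None."""

    def ancestors(n):
        out = set()
        while parents[n] is not None:
            n = parents[n]
            out.add(n)
        return out

    anc = {n: ancestors(n) for n in nodes}
    for _ in range(50):
        order = list(rng.permutation(nodes))
        chosen: list[str] = []
        for n in order:
            if all(n not in anc[c] and c not in anc[n] for c in chosen):
                chosen.append(n)
            if len(chosen) == k:
                return chosen
    return None


def make_truth(
    n_subclones: int,
    markers,
    truncal_markers,
    reiterative_spec=None,
    frequencies=None,
    seed: int = 0,
) -> ClonalTruth:
    """Build a random ground-truth clonal tree.

    The first leukaemic node C1 carries every truncal marker (fusions
    go heterozygous, copy-number losses go bi-allelic, i.e. 0 copies);
    each later clone attaches to a uniformly chosen existing clone and
    acquires the next markers from the non-truncal pool, dealt evenly
    across the ``n_subclones - 1`` subclonal edges.  ``reiterative_spec``
    is a list of ``(gene, n_hits)`` pairs: each requested gene receives
    ``n_hits`` extra indel markers placed on pairwise non-ancestral
    clones (parallel evolution, never stacked on one lineage).

    Deterministic for a fixed seed.
    """
    if n_subclones < 1:
        raise ValidationError("n_subclones must be >= 1")
    markers = [as_marker(m) for m in markers]
    truncal = list(truncal_markers)
    ids = {m.id for m in markers}
    missing = [t for t in truncal if t not in ids]
    if missing:
        raise ValidationError(f"truncal markers not in marker list: {missing}")

    rng = np.random.default_rng(seed)

    reit_markers: list[Marker] = []
    if reiterative_spec:
        for gene, n_hits in reiterative_spec:
            for i in range(n_hits):
                reit_markers.append(Marker(f"{gene}_hit{i + 1}", gene, "indel"))
    all_markers = markers + reit_markers
    midx = {m.id: j for j, m in enumerate(all_markers)}

    # topology: C1 truncal, others attach to a random existing clone
    clones = [f"C{i + 1}" for i in range(n_subclones)]
    parents: dict[str, str | None] = {ROOT: None, "C1": ROOT}
    for i, c in enumerate(clones[1:], start=1):
        parents[c] = clones[int(rng.integers(0, i))]

    germ = tuple(m.germline_state() for m in all_markers)
    units = {ROOT: [0] * len(all_markers)}

    def acquire(node: str, marker: Marker, n_units: int) -> None:
        units[node][midx[marker.id]] = max(units[node][midx[marker.id]], n_units)

    # truncal edge: fusions/SNVs het, CN losses bi-allelic
    units["C1"] = [0] * len(all_markers)
    for t in truncal:
        m = all_markers[midx[t]]
        acquire("C1", m, 2 if m.is_copy_number else 1)

    # deal remaining markers evenly over the subclonal edges
    pool = [m for m in markers if m.id not in truncal]
    sub_edges = clones[1:]
    if pool and not sub_edges:
        raise ValidationError(
            "non-truncal markers supplied but n_subclones == 1 leaves no subclonal edge"
        )
    for j, m in enumerate(pool):
        node = sub_edges[j % len(sub_edges)]
        if node not in units:
            units[node] = [0] * len(all_markers)
        acquire(node, m, 2 if m.is_copy_number else 1)

    # inherit down the tree (children gain parents' units)
    def depth(c):
        d, n = 0, c
        while parents[n] is not None:
            n, d = parents[n], d + 1
        return d

    for c in sorted(clones, key=depth):
        if c == "C1":
            continue
        if c not in units:
            units[c] = [0] * len(all_markers)
        pu = units[parents[c]]
        units[c] = [max(a, b) for a, b in zip(units[c], pu)]

    # reiterative hits on pairwise non-ancestral clones
    if reit_markers:
        need = len(reit_markers)
        chain = _antichain(parents, clones, need, rng)
        if chain is None:
            raise ValidationError(
                f"cannot place {need} reiterative hits on non-ancestral branches "
                f"of a {n_subclones}-clone tree"
            )
        for m, node in zip(reit_markers, chain):
            units[node][midx[m.id]] = 1
            # propagate to descendants
            for c in sorted(clones, key=depth):
                p = parents[c]
                if p in units and p != ROOT:
                    units[c] = [max(a, b) for a, b in zip(units[c], units[p])]

    if frequencies is None:
        freqs = np.full(n_subclones, 1.0 / n_subclones)
    else:
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.shape != (n_subclones,):
            raise ValidationError(
                f"frequency vector length {freqs.size} != {n_subclones} subclones"
            )
        if not np.isclose(freqs.sum(), 1.0) or (freqs < 0).any():
            raise ValidationError("frequencies must be >= 0 and sum to 1")

    genotypes = {ROOT: germ}
    for c in clones:
        genotypes[c] = units_to_genotype(units[c], all_markers)

    return ClonalTruth(
        markers=all_markers,
        parents=parents,
        genotypes=genotypes,
        frequencies={c: float(f) for c, f in zip(clones, freqs)},
        seed=seed,
    )


def sample_cells(
    truth: ClonalTruth, n_cells: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw cells multinomially from the clone frequencies.

    Returns the noise-free genotype matrix (cells × markers, external
    states) and the true clone label of each cell.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    clones = truth.clones()
    freqs = np.array([truth.frequencies[c] for c in clones])
    labels = rng.choice(clones, size=n_cells, p=freqs)
    rows = np.array([truth.genotypes[c] for c in labels], dtype=int)
    cells = [f"cell{i + 1}" for i in range(n_cells)]
    gm = pd.DataFrame(rows, index=cells, columns=[m.id for m in truth.markers])
    return gm, pd.Series(labels, index=cells, name="clone")


def simulate_xenograft(
    truth: ClonalTruth,
    n_cells: int,
    engrafting_clones: dict[str, float] | None = None,
    selection_strength: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample cells after an engraftment bottleneck.

    Either supply ``engrafting_clones`` (clone → new frequency; a single
    clone at weight 1.0 models a clonal sweep) or ``selection_strength``
    ``s >= 0`` which re-weights each clone by ``freq * (1 + s * n_changes)``
    — stronger selection favours more-mutated clones.
    """
    if engrafting_clones is not None:
        if not engrafting_clones:
            raise ValidationError("engrafting clone set must not be empty")
        unknown = set(engrafting_clones) - set(truth.clones())
        if unknown:
            raise ValidationError(f"engrafting clones not in truth: {sorted(unknown)}")
        w = np.array([engrafting_clones.get(c, 0.0) for c in truth.clones()])
    elif selection_strength is not None:
        if selection_strength < 0:
            raise ValidationError("selection_strength must be >= 0")
        w = np.array(
            [
                truth.frequencies[c]
                * (1.0 + selection_strength
                   * sum(genotype_to_units(truth.genotypes[c], truth.markers)))
                for c in truth.clones()
            ]
        )
    else:
        raise ValidationError("supply engrafting_clones or selection_strength")
    if w.sum() <= 0:
        raise ValidationError("engraftment weights sum to zero")
    w = w / w.sum()
    xeno = ClonalTruth(
        markers=truth.markers,
        parents=dict(truth.parents),
        genotypes=dict(truth.genotypes),
        frequencies={c: float(f) for c, f in zip(truth.clones(), w)},
        seed=seed,
    )
    return sample_cells(xeno, n_cells, seed=seed)


def simulate_ct_readout(
    true_genotypes: pd.DataFrame,
    panel: AssayPanel,
    noise: NoiseConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate duplicated qPCR wells from true genotypes.

    Per cell, each allele of each marker survives with probability
    ``1 - allelic_dropout_rate`` (shared across the duplicate wells);
    each well then fails independently with ``assay_failure_rate``.
    Surviving template ``t`` amplifies at
    ``Ct = ct_baseline + ct_per_copy_shift * (2 - t) + N(0, ct_sd)``;
    zero surviving template yields the no-amplification sentinel.
    """
    rng = np.random.default_rng(seed)
    mids = [m.id for m in panel.markers]
    missing = [m for m in mids if m not in true_genotypes.columns]
    if missing:
        raise ValidationError(f"genotype matrix lacks panel markers: {missing}")

    n = len(true_genotypes)
    states = true_genotypes[mids].to_numpy(dtype=int)
    ado = noise.allelic_dropout_rate

    # surviving mutant/wt allele (or copy) counts per cell per marker
    surv_mut = np.zeros_like(states)
    surv_wt = np.zeros_like(states)
    for j, m in enumerate(panel.markers):
        if m.is_copy_number:
            copies = states[:, j]
            surv_mut[:, j] = rng.binomial(copies, 1.0 - ado)  # surviving copies
        else:
            mut = states[:, j]
            wt = 2 - mut
            surv_mut[:, j] = rng.binomial(mut, 1.0 - ado)
            surv_wt[:, j] = rng.binomial(wt, 1.0 - ado)

    def well(template: np.ndarray) -> np.ndarray:
        """Ct values for one well given surviving template counts."""
        ct = (
            noise.ct_baseline
            + noise.ct_per_copy_shift * (2.0 - template)
            + (rng.normal(0.0, noise.ct_sd, size=n) if noise.ct_sd > 0 else 0.0)
        )
        fail = rng.random(n) < noise.assay_failure_rate
        out = np.where((template > 0) & ~fail, ct, noise.no_amp_sentinel)
        return out

    data = {}
    for a in panel.assays:
        if a.assay_class == "control":
            template = np.full(n, 2)
        else:
            j = mids.index(a.marker_id)
            m = panel.marker(a.marker_id)
            if a.assay_class == "copy_number":
                template = surv_mut[:, j]
            elif a.detects == "mutant":
                template = surv_mut[:, j]
            else:
                template = surv_wt[:, j]
        for r in range(a.n_replicates):
            data[f"{a.id}__rep{r + 1}"] = well(template)

    return pd.DataFrame(data, index=true_genotypes.index)


# ---------------------------------------------------------------------------
# breakpoint sequences

RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAACC"
_BASES = np.array(list("ACGT"))


@dataclass
class BreakpointSequence:
    id: str
    seq: str
    embed: str  # none | consensus_rss | cryptic_caca
    offset_start: int | None = None  # 0-based half-open over the whole element
    offset_end: int | None = None
    strand: str | None = None
    spacer: int | None = None


def make_breakpoint_sequences(
    n: int,
    length: int,
    embed: str = "none",
    spacer: int = 23,
    seed: int = 0,
) -> list[BreakpointSequence]:
    """Random breakpoint-flanking sequences, optionally with a planted motif.

    ``embed="consensus_rss"`` plants the consensus heptamer, a 12- or
    23-bp spacer and the consensus nonamer at a uniformly chosen offset
    on a uniformly chosen strand; ``embed="cryptic_caca"`` plants a bare
    CACA tetramer.  Planted coordinates are recorded 0-based half-open
    on the forward strand.
    """
    if embed not in ("none", "consensus_rss", "cryptic_caca"):
        raise ValidationError(f"unknown embed mode {embed!r}")
    motif_len = {"none": 0, "cryptic_caca": 4,
                 "consensus_rss": 7 + spacer + 9}[embed]
    if embed == "consensus_rss" and spacer not in (12, 23):
        raise ValidationError("spacer must be 12 or 23")
    if length < motif_len:
        raise ValidationError(
            f"length {length} too small for embed {embed!r} ({motif_len} bp)"
        )
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        seq = _BASES[rng.integers(0, 4, size=length)]
        rec = BreakpointSequence(id=f"bp{i + 1}", seq="", embed=embed)
        if embed != "none":
            if embed == "consensus_rss":
                spacer_seq = "".join(_BASES[rng.integers(0, 4, size=spacer)])
                element = RSS_HEPTAMER + spacer_seq + RSS_NONAMER
                rec.spacer = spacer
            else:
                element = "CACA"
            start = int(rng.integers(0, length - len(element) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = element if strand == "+" else _revcomp(element)
            seq[start:start + len(element)] = list(planted)
            rec.offset_start, rec.offset_end = start, start + len(element)
            rec.strand = strand
        rec.seq = "".join(seq)
        records.append(rec)
    return records


def _revcomp(s: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return s.translate(comp)[::-1]
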