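"""Subclone configurations of the three index STIL-TAL1+ T-ALL cases.

These are the marker panels and subclone genotypes of the three cases
that underwent single-cell multiplex qPCR (6116, CUL76 and 6030), as
supported by the published evolutionary diagrams.  Genotype states are
transcribed at the level the diagrams resolve: presence/absence of the
patient-specific fusion, bi-allelic CDKN2A loss on the truncal edge,
and the subclonal SNV/indel/copy-number drivers of each case.  Only
the structure (which subclone carries which lesion) is encoded here;
frequencies passed to the simulator are illustrative defaults used by
the examples.

Case 6116 is the canonical co-optimal-ambiguity configuration: the
latest clone carries both the FREM2 and the PIK3CD mutation, so two
equally parsimonious histories exist depending on which single-mutant
clone it descends from.

Case 6030 carries reiterative PTEN inactivation: three independent
exon 7 indels plus one exon 8 mutation, on divergent branches, with
one subclone (C6) holding two exon 7 indels on separate alleles.
"""

from __future__ import annotations

from .markers import Marker
from .simdata import ROOT, ClonalTruth


def case_6116(frequencies=None) -> ClonalTruth:
    """Four diagnostic subclones; FREM2/PIK3CD co-optimal ambiguity."""
    markers = [
        Marker("STIL_TAL1_F", "STIL_TAL1", "fusion"),
        Marker("CDKN2A_del", "CDKN2A", "cn_loss"),
        Marker("FREM2_mut", "FREM2", "snv"),
        Marker("PIK3CD_mut", "PIK3CD", "snv"),
        Marker("NOTCH1_mut", "NOTCH1", "snv"),
    ]
    # states: fusion, CDKN2A copies, FREM2, PIK3CD, NOTCH1
    genotypes = {
        ROOT: (0, 2, 0, 0, 0),
        "C1": (1, 0, 0, 0, 0),  # truncal only
        "C2": (1, 0, 1, 0, 0),  # +FREM2
        "C3": (1, 0, 0, 1, 0),  # +PIK3CD
        "C4": (1, 0, 1, 1, 1),  # latest clone: both, +NOTCH1
    }
    parents = {ROOT: None, "C1": ROOT, "C2": "C1", "C3": "C1", "C4": "C2"}
    freqs = frequencies or {"C1": 0.35, "C2": 0.30, "C3": 0.20, "C4": 0.15}
    return ClonalTruth(markers=markers, parents=parents, genotypes=genotypes,
                       frequencies=freqs)


def case_cul76(frequencies=None) -> ClonalTruth:
    """Three subclones; truncal fusion + CDKN2A + LMO2 loss."""
    markers = [
        Marker("STIL_TAL1_F", "STIL_TAL1", "fusion"),
        Marker("CDKN2A_del", "CDKN2A", "cn_loss"),
        Marker("LMO2_del", "LMO2", "cn_loss"),
        Marker("PTEN_del", "PTEN", "cn_loss"),
        Marker("NOTCH1_ex34", "NOTCH1", "snv"),
        Marker("SORC3_mut", "SORC3", "snv"),  # passenger, aids structure
    ]
    genotypes = {
        ROOT: (0, 2, 2, 2, 0, 0),
        "C1": (1, 0, 0, 2, 0, 0),
        "C2": (1, 0, 0, 2, 1, 1),  # +NOTCH1 (+passenger)
        "C3": (1, 0, 0, 1, 0, 0),  # +PTEN loss
    }
    parents = {ROOT: None, "C1": ROOT, "C2": "C1", "C3": "C1"}
    freqs = frequencies or {"C1": 0.45, "C2": 0.30, "C3": 0.25}
    return ClonalTruth(markers=markers, parents=parents, genotypes=genotypes,
                       frequencies=freqs)


def case_6030(frequencies=None) -> ClonalTruth:
    """Seven subclones; reiterative PTEN inactivation (3× exon 7 + exon 8).

    C6 carries two independent exon 7 indels (bi-allelic inactivation);
    C7 — the clone that swept the xenograft — carries the exon 8
    mutation, present in het and hom form among its cells.
    """
    markers = [
        Marker("STIL_TAL1_F", "STIL_TAL1", "fusion"),
        Marker("CDKN2A_del", "CDKN2A", "cn_loss"),
        Marker("PTEN_ex7_i1", "PTEN", "indel"),
        Marker("PTEN_ex7_i2", "PTEN", "indel"),
        Marker("PTEN_ex7_i3", "PTEN", "indel"),
        Marker("PTEN_ex8", "PTEN", "indel"),
        Marker("del_6q", "6q", "cn_loss"),
    ]
    genotypes = {
        ROOT: (0, 2, 0, 0, 0, 0, 2),
        "C1": (1, 0, 0, 0, 0, 0, 2),  # truncal only
        "C2": (1, 0, 1, 0, 0, 0, 2),  # +exon7 indel1
        "C3": (1, 0, 0, 1, 0, 0, 2),  # +exon7 indel2
        "C4": (1, 0, 0, 0, 1, 0, 2),  # +exon7 indel3
        "C5": (1, 0, 1, 0, 0, 0, 1),  # indel1 branch +6q loss
        "C6": (1, 0, 0, 1, 1, 0, 2),  # two exon7 indels, separate alleles
        "C7": (1, 0, 0, 0, 0, 1, 2),  # +exon8 (xenograft read-out clone)
    }
    parents = {
        ROOT: None, "C1": ROOT, "C2": "C1", "C3": "C1", "C4": "C1",
        "C5": "C2", "C6": "C3", "C7": "C1",
    }
    freqs = frequencies or {
        "C1": 0.20, "C2": 0.15, "C3": 0.13, "C4": 0.12,
        "C5": 0.10, "C6": 0.10, "C7": 0.20,
    }
    return ClonalTruth(markers=markers, parents=parents, genotypes=genotypes,
                       frequencies=freqs)


#: fraction of C7 cells whose exon 8 mutation is homozygous, by
#: compartment — the diagnostic/xenograft zygosity contrast tracked
#: for case 6030
C7_EXON8_HOM_FRACTION = {"diagnostic": 0.47, "xenograft": 0.88}


def case_6030_c7_zygosity(compartment: str, frequencies=None) -> ClonalTruth:
    """C7 of case 6030 split into het and hom exon 8 sub-populations.

    In the diagnostic sample 47% of C7 cells carry the exon 8 mutation
    homozygously (the rest heterozygously); after xenografting the
    homozygous fraction rises to 88% and no wild-type cells remain.
    """
    if compartment not in C7_EXON8_HOM_FRACTION:
        raise ValueError(f"compartment must be diagnostic/xenograft, got {compartment!r}")
    hom = C7_EXON8_HOM_FRACTION[compartment]
    markers = [
        Marker("STIL_TAL1_F", "STIL_TAL1", "fusion"),
        Marker("CDKN2A_del", "CDKN2A", "cn_loss"),
        Marker("PTEN_ex8", "PTEN", "indel"),
    ]
    genotypes = {
        ROOT: (0, 2, 0),
        "C7het": (1, 0, 1),
        "C7hom": (1, 0, 2),
    }
    parents = {ROOT: None, "C7het": ROOT, "C7hom": "C7het"}
    freqs = frequencies or {"C7het": 1.0 - hom, "C7hom": hom}
    return ClonalTruth(markers=markers, parents=parents, genotypes=genotypes,
                       frequencies=freqs)
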