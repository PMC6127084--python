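"""Cohort driver-frequency summaries and diagnosis-vs-xenograft comparison.

The cohort grid records, per sample and per driver, one of ``loss``
(copy-number loss), ``gain``, ``mutation`` or ``wt``.  Frequencies are
always reported with their numerator and denominator.  The compartment
comparison asks which diagnostic subclones *read out* in a xenograft
("T-status"): a diagnostic subclone is T-positive iff some xenograft
subclone matches its genotype, by default under NA-tolerant equality
(all co-observed markers equal) because dropout differs between
compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .clonetree import SubcloneSet
from .markers import ValidationError

STATUSES = frozenset({"loss", "gain", "mutation", "wt"})


def load_cohort_table(path=None) -> pd.DataFrame:
    """Load a sample × driver status grid (CSV, ``sample_id`` first).

    Without a path, loads the packaged synthetic cohort grid — a
    constructed 20-sample stand-in reproducing the reported marginal
    driver frequencies of this leukaemia subtype (see the file's
    docstring row in ``data/``).
    """
    if path is None:
        ref = resources.files("talclone").joinpath("data/cohort_table_synthetic.csv")
        with resources.as_file(ref) as p:
            tbl = pd.read_csv(p)
    else:
        tbl = pd.read_csv(path)
    if tbl.columns[0] != "sample_id":
        raise ValidationError("first cohort column must be sample_id")
    tbl = tbl.set_index("sample_id")
    bad = set(np.unique(tbl.to_numpy().astype(str))) - STATUSES
    if bad:
        raise ValidationError(f"invalid status values in cohort table: {sorted(bad)}")
    if tbl.index.duplicated().any():
        raise ValidationError("duplicate sample ids in cohort table")
    return tbl


@dataclass
class FrequencyResult:
    rule: str
    numerator: int
    denominator: int

    @property
    def pct(self) -> float:
        return 100.0 * self.numerator / self.denominator

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "pct": self.pct,
        }


#: named driver predicates over the cohort grid
DRIVER_RULES = {
    # inactivation by hotspot exon 7 mutation OR locus copy-number loss
    "pten_inactivation": lambda t: (t["PTEN_exon7"] == "mutation")
    | (t["PTEN_cn"] == "loss"),
    "loss_9p": lambda t: t["CDKN2A_9p"] == "loss",
    "loss_6q": lambda t: t["del_6q"] == "loss",
    "notch1_mutation": lambda t: t["NOTCH1"] == "mutation",
}


def driver_frequency(tbl: pd.DataFrame, rule: str) -> FrequencyResult:
    """Fraction of cohort samples satisfying a named driver predicate.

    ``rule`` is either a key of :data:`DRIVER_RULES` or
    ``"<column>=<status>"`` for an ad-hoc single-column predicate.
    """
    if rule in DRIVER_RULES:
        try:
            mask = DRIVER_RULES[rule](tbl)
        except KeyError as e:
            raise ValidationError(f"cohort table lacks column {e} for rule {rule!r}")
    elif "=" in rule:
        col, status = rule.split("=", 1)
        if col not in tbl.columns:
            raise ValidationError(f"unknown cohort column {col!r}")
        mask = tbl[col] == status
    else:
        raise ValidationError(f"unknown driver rule {rule!r}")
    return FrequencyResult(rule=rule, numerator=int(mask.sum()), denominator=len(tbl))


# ---------------------------------------------------------------------------
# diagnosis vs xenograft


def _genotypes_match(a, b, policy: str) -> bool:
    if policy == "exact":
        return tuple(a) == tuple(b)
    # NA-tolerant: equal on all co-observed markers (None = unobserved)
    return all(x == y for x, y in zip(a, b) if x is not None and y is not None)


@dataclass
class CompartmentComparison:
    """Per-subclone read-out status and frequency shifts."""

    subclones: list[dict] = field(default_factory=list)
    emergent: list[dict] = field(default_factory=list)  # xenograft-only genotypes
    match_policy: str = "na_tolerant"

    def n_t_positive(self) -> int:
        return sum(1 for s in self.subclones if s["t_status"])

    def max_abs_frequency_shift(self) -> float:
        if not self.subclones:
            return 0.0
        return max(abs(s["frequency_shift"]) for s in self.subclones)

    def to_dict(self) -> dict:
        return {
            "match_policy": self.match_policy,
            "subclones": list(self.subclones),
            "emergent": list(self.emergent),
            "n_t_positive": self.n_t_positive(),
        }


def compare_compartments(
    diag: SubcloneSet,
    xeno: SubcloneSet,
    match_policy: str = "na_tolerant",
) -> CompartmentComparison:
    """Compare diagnostic subclones with a xenograft compartment.

    A diagnostic subclone has T-status true iff a xenograft subclone
    matches its genotype under ``match_policy``; its xenograft
    frequency is the summed frequency of all matching xenograft
    subclones.  Xenograft genotypes matching no diagnostic subclone are
    flagged emergent.  Detection is symmetric: swapping the
    compartments swaps emergent and extinct labels.
    """
    if match_policy not in ("exact", "na_tolerant"):
        raise ValidationError(f"unknown match policy {match_policy!r}")
    if [m.id for m in diag.markers] != [m.id for m in xeno.markers]:
        raise ValidationError("compartments must be genotyped on the same marker panel")

    xfreq = xeno.frequencies()
    comparison = CompartmentComparison(match_policy=match_policy)
    for g, f in zip(diag.genotypes, diag.frequencies()):
        matches = [
            j for j, xg in enumerate(xeno.genotypes)
            if _genotypes_match(g, xg, match_policy)
        ]
        fx = float(sum(xfreq[j] for j in matches))
        comparison.subclones.append(
            {
                "genotype": list(g),
                "diagnostic_frequency": float(f),
                "xenograft_frequency": fx,
                "t_status": bool(matches),
                "frequency_shift": fx - float(f),
            }
        )
    for xg, xf in zip(xeno.genotypes, xfreq):
        if not any(_genotypes_match(xg, g, match_policy) for g in diag.genotypes):
            comparison.emergent.append(
                {"genotype": list(xg), "xenograft_frequency": float(xf)}
            )
    return comparison


def zygosity_fractions(states) -> tuple[tuple[float, float, float], int]:
    """(wt, het, hom) proportions over non-NA cells of one subclone.

    ``states`` holds per-cell zygosity states (0/1/2, NA allowed) for a
    single sequence marker.  Returns the proportions (summing to 1)
    and the NA count, which is reported rather than imputed.
    """
    s = pd.Series(states)
    na = int(s.isna().sum())
    obs = s.dropna().astype(int)
    if obs.empty:
        raise ValidationError("all cells are NA for this marker; zygosity undefined")
    if not obs.isin([0, 1, 2]).all():
        raise ValidationError("zygosity states must be 0 (wt), 1 (het) or 2 (hom)")
    n = len(obs)
    fractions = tuple(float((obs == k).sum()) / n for k in (0, 1, 2))
    return fractions, na
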