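"""Genotype calling from duplicated single-cell qPCR Ct matrices.

Each assay is run in duplicate wells.  Calling is deliberately
conservative:

* a mutation-specific assay is *positive* only if **both** duplicates
  amplify below ``ct_max``, *negative* if both fail to amplify, and
  *missing* when the duplicates disagree (discordance is treated as an
  artefact, never as evidence);
* copy number is called from the mean ΔCt between the locus assay and a
  diploid reference control, banded into 2 / 1 / 0 copies, with
  bi-allelic loss requiring both locus wells silent while the controls
  amplify;
* a cell whose control assays fail is entirely uncallable (all NA) and
  is flagged for removal in QC.

Zygosity of a sequence marker defaults to heterozygous on a positive
mutant-specific assay; it is upgraded to homozygous only when the panel
carries a paired wild-type-allele assay and that assay is negative
(mirroring zygosity resolution by single-cell Sanger sequencing, which
this pipeline abstracts as an extra assay column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import Marker, ValidationError
from .panel import AssayPanel

NA = pd.NA


@dataclass
class CallThresholds:
    """Tunable calling parameters.

    ct_max
        Latest cycle accepted as genuine amplification (default 38).
    delta_ct_bands
        Two increasing ΔCt cutpoints (b1, b2) separating 2 / 1 / 0
        copies: ΔCt < b1 → 2, b1 ≤ ΔCt < b2 → 1, ΔCt ≥ b2 → 0.
        Defaults (0.5, 1.5) match a 1-cycle-per-copy-halving response.
    no_amp_sentinel
        Sentinel value marking non-amplifying wells.
    """

    ct_max: float = 38.0
    delta_ct_bands: tuple[float, float] = (0.5, 1.5)
    no_amp_sentinel: float = -1.0

    def __post_init__(self) -> None:
        b1, b2 = self.delta_ct_bands
        if not b1 < b2:
            raise ValidationError(f"ΔCt bands must be increasing, got ({b1}, {b2})")


@dataclass
class GenotypeMatrix:
    """Called genotypes: cells × markers plus per-cell QC flags.

    ``calls`` uses pandas nullable integers — sequence markers hold
    zygosity states 0/1/2, copy-number markers hold copies 2/1/0, NA
    marks an uncallable entry.  ``qc`` has ``controls_passed`` (bool)
    and ``n_missing`` (NA count) per cell.
    """

    calls: pd.DataFrame
    markers: list[Marker]
    qc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        mids = [m.id for m in self.markers]
        if list(self.calls.columns) != mids:
            raise ValidationError("call columns must match the marker list")
        vals = self.calls.to_numpy(dtype="float", na_value=np.nan)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValidationError("genotype states must be 0/1/2 (or copies 2/1/0) or NA")
        if self.qc.empty:
            self.qc = pd.DataFrame(
                {
                    "controls_passed": True,
                    "n_missing": self.calls.isna().sum(axis=1).astype(int),
                },
                index=self.calls.index,
            )

    @property
    def n_cells(self) -> int:
        return len(self.calls)

    def missing_fraction(self) -> pd.Series:
        return self.calls.isna().mean(axis=1)


def _amplified(ct: float, thr: CallThresholds) -> bool:
    return ct != thr.no_amp_sentinel and ct < thr.ct_max


def call_mutation_assay(replicate_cts, thresholds: CallThresholds | None = None) -> str:
    """Call one duplicated mutation-specific assay for one cell.

    Returns ``"positive"`` when both wells amplify below ``ct_max``,
    ``"negative"`` when neither does, and ``"missing"`` when the
    duplicates disagree.
    """
    thr = thresholds or CallThresholds()
    amps = [_amplified(float(c), thr) for c in replicate_cts]
    if all(amps):
        return "positive"
    if not any(amps):
        return "negative"
    return "missing"


def call_copy_number(
    assay_cts, control_cts, thresholds: CallThresholds | None = None
):
    """Call copies (2/1/0/NA) from a duplicated locus assay vs control.

    Controls must both amplify; otherwise the call is NA.  Both locus
    wells silent with passing controls is bi-allelic loss (0).  A
    discordant locus duplicate is NA.  Otherwise the mean ΔCt
    (locus − control) is banded by ``delta_ct_bands``.
    """
    thr = thresholds or CallThresholds()
    ctrl_amp = [_amplified(float(c), thr) for c in control_cts]
    if not all(ctrl_amp):
        return NA
    assay_amp = [_amplified(float(c), thr) for c in assay_cts]
    if not any(assay_amp):
        return 0
    if not all(assay_amp):
        return NA
    delta = float(np.mean([float(c) for c in assay_cts])) - float(
        np.mean([float(c) for c in control_cts])
    )
    b1, b2 = thr.delta_ct_bands
    if delta < b1:
        return 2
    if delta < b2:
        return 1
    return 0


def build_genotype_matrix(
    ct: pd.DataFrame,
    panel: AssayPanel,
    thresholds: CallThresholds | None = None,
) -> GenotypeMatrix:
    """Apply the calling rules marker-wise over a Ct matrix.

    The Ct matrix must carry one ``<assay>__repN`` column per declared
    replicate of every panel assay.
    """
    thr = thresholds or CallThresholds()
    expected = panel.well_columns()
    missing = [c for c in expected if c not in ct.columns]
    if missing:
        raise ValidationError(f"Ct matrix lacks panel well columns: {missing[:5]}")

    def reps(assay_id: str, n: int) -> list[pd.Series]:
        return [ct[f"{assay_id}__rep{r + 1}"] for r in range(n)]

    n_cells = len(ct)
    controls = panel.control_assays()
    controls_passed = np.ones(n_cells, dtype=bool)
    for a in controls:
        for col in reps(a.id, a.n_replicates):
            amp = (col.to_numpy() != thr.no_amp_sentinel) & (col.to_numpy() < thr.ct_max)
            controls_passed &= amp

    calls = pd.DataFrame(index=ct.index, dtype="Int64")
    for m in panel.markers:
        assays = panel.assays_for_marker(m.id)
        if m.is_copy_number:
            a = assays[0]
            ctrl = panel.assay(a.control_id)
            col = [
                call_copy_number(
                    [ct.at[i, f"{a.id}__rep{r + 1}"] for r in range(a.n_replicates)],
                    [ct.at[i, f"{ctrl.id}__rep{r + 1}"] for r in range(ctrl.n_replicates)],
                    thr,
                )
                for i in ct.index
            ]
            calls[m.id] = pd.array(col, dtype="Int64")
        else:
            mut = next(a for a in assays if a.detects == "mutant")
            wt = next((a for a in assays if a.detects == "wildtype"), None)
            col = []
            for i in ct.index:
                mcall = call_mutation_assay(
                    [ct.at[i, f"{mut.id}__rep{r + 1}"] for r in range(mut.n_replicates)],
                    thr,
                )
                if mcall == "missing":
                    col.append(NA)
                elif mcall == "negative":
                    col.append(0)
                else:
                    state = 1
                    if wt is not None:
                        wcall = call_mutation_assay(
                            [
                                ct.at[i, f"{wt.id}__rep{r + 1}"]
                                for r in range(wt.n_replicates)
                            ],
                            thr,
                        )
                        if wcall == "negative":
                            state = 2
                        elif wcall == "missing":
                            col.append(NA)
                            continue
                    col.append(state)
            calls[m.id] = pd.array(col, dtype="Int64")

    # a cell with failed controls is entirely uncallable
    calls.loc[~controls_passed, :] = NA

    qc = pd.DataFrame(
        {
            "controls_passed": controls_passed,
            "n_missing": calls.isna().sum(axis=1).astype(int),
        },
        index=ct.index,
    )
    return GenotypeMatrix(calls=calls, markers=list(panel.markers), qc=qc)


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_kept + sum(self.removed.values()) != self.n_input:
            raise ValidationError("QC report does not reconcile: kept + removed != input")

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept, "removed": dict(self.removed)}


def qc_filter_cells(
    gm: GenotypeMatrix, max_missing_frac: float = 0.3
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop cells failing controls or exceeding the missing-call budget."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValidationError("max_missing_frac must be in [0,1]")
    ctrl_fail = ~gm.qc["controls_passed"].to_numpy(dtype=bool)
    too_missing = (gm.missing_fraction().to_numpy() > max_missing_frac) & ~ctrl_fail
    keep = ~ctrl_fail & ~too_missing
    filtered = GenotypeMatrix(
        calls=gm.calls.loc[keep].copy(),
        markers=gm.markers,
        qc=gm.qc.loc[keep].copy(),
    )
    report = QCReport(
        n_input=gm.n_cells,
        n_kept=int(keep.sum()),
        removed={
            "control_failure": int(ctrl_fail.sum()),
            "too_many_missing": int(too_missing.sum()),
        },
    )
    return filtered, report
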