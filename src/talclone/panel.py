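"""Multiplex qPCR assay panel definitions.

A panel lists the assays run on every single cell, each in duplicate
wells.  Three assay classes exist:

* ``mutation_specific`` — amplifies only when a target allele is
  present.  By default an assay detects the *mutant* allele; a paired
  wild-type-allele assay (``detects="wildtype"``) may be added to the
  panel so that zygosity (het vs hom) can be resolved for a sequence
  marker.
* ``copy_number`` — amplifies from any remaining copy of the locus; the
  call is made from the Ct shift relative to a reference control assay.
* ``control`` — a diploid reference locus used both as the copy-number
  reference and as a per-cell quality-control check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .markers import Marker, ValidationError

ASSAY_CLASSES = ("mutation_specific", "copy_number", "control")


@dataclass(frozen=True)
class Assay:
    id: str
    assay_class: str  # mutation_specific | copy_number | control
    marker_id: str | None = None
    detects: str = "mutant"  # mutant | wildtype (mutation_specific only)
    control_id: str | None = None  # copy_number only
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.assay_class not in ASSAY_CLASSES:
            raise ValidationError(f"unknown assay class {self.assay_class!r}")
        if self.assay_class != "control" and self.marker_id is None:
            raise ValidationError(f"assay {self.id!r} needs a target marker")
        if self.assay_class == "copy_number" and self.control_id is None:
            raise ValidationError(
                f"copy-number assay {self.id!r} needs a reference control assay"
            )
        if self.detects not in ("mutant", "wildtype"):
            raise ValidationError(f"detects must be mutant/wildtype, got {self.detects!r}")


@dataclass
class AssayPanel:
    """The set of assays applied to each cell."""

    assays: list[Assay]
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate assay ids in panel")
        if not self.control_assays():
            raise ValidationError("panel must contain at least one control assay")
        marker_ids = {m.id for m in self.markers}
        for a in self.assays:
            if a.assay_class != "control" and a.marker_id not in marker_ids:
                raise ValidationError(
                    f"assay {a.id!r} targets unknown marker {a.marker_id!r}"
                )
        for m in self.markers:
            if not self.assays_for_marker(m.id):
                raise ValidationError(f"marker {m.id!r} has no assay in the panel")

    def control_assays(self) -> list[Assay]:
        return [a for a in self.assays if a.assay_class == "control"]

    def assays_for_marker(self, marker_id: str) -> list[Assay]:
        return [a for a in self.assays if a.marker_id == marker_id]

    def assay(self, assay_id: str) -> Assay:
        for a in self.assays:
            if a.id == assay_id:
                return a
        raise KeyError(assay_id)

    def marker(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.id == marker_id:
                return m
        raise KeyError(marker_id)

    def well_columns(self) -> list[str]:
        """Ct-matrix column names, one per assay replicate."""
        cols = []
        for a in self.assays:
            cols.extend(f"{a.id}__rep{r + 1}" for r in range(a.n_replicates))
        return cols

    @classmethod
    def default_for(
        cls,
        markers: list[Marker],
        include_wildtype_assays: bool = False,
        control_id: str = "CTRL_diploid",
    ) -> "AssayPanel":
        """Build a standard panel: one assay per marker plus one control.

        Sequence markers get a mutant-specific assay (optionally paired
        with a wild-type-allele assay for zygosity); copy-number markers
        get a copy-number assay referenced to the control.
        """
        assays = [Assay(id=control_id, assay_class="control")]
        for m in markers:
            if m.is_copy_number:
                assays.append(
                    Assay(
                        id=f"{m.id}__cn",
                        assay_class="copy_number",
                        marker_id=m.id,
                        control_id=control_id,
                    )
                )
            else:
                assays.append(
                    Assay(id=f"{m.id}__mut", assay_class="mutation_specific", marker_id=m.id)
                )
                if include_wildtype_assays:
                    assays.append(
                        Assay(
                            id=f"{m.id}__wt",
                            assay_class="mutation_specific",
                            marker_id=m.id,
                            detects="wildtype",
                        )
                    )
        return cls(assays=assays, markers=list(markers))

    # -- YAML round trip -------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "markers": [
                {"id": m.id, "gene": m.gene, "kind": m.kind} for m in self.markers
            ],
            "assays": [
                {
                    "id": a.id,
                    "class": a.assay_class,
                    "marker": a.marker_id,
                    "detects": a.detects,
                    "control": a.control_id,
                    "replicates": a.n_replicates,
                }
                for a in self.assays
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AssayPanel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        markers = [Marker(d["id"], d["gene"], d["kind"]) for d in doc["markers"]]
        assays = [
            Assay(
                id=d["id"],
                assay_class=d["class"],
                marker_id=d.get("marker"),
                detects=d.get("detects") or "mutant",
                control_id=d.get("control"),
                n_replicates=d.get("replicates", 2),
            )
            for d in doc["assays"]
        ]
        return cls(assays=assays, markers=markers)
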