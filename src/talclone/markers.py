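"""Marker definitions and genotype-state encoding.

Two marker families are tracked per cell:

* **Sequence markers** (``fusion``, ``snv``, ``indel``) carry ordered
  zygosity states ``0`` (wild type), ``1`` (heterozygous), ``2``
  (homozygous).
* **Copy-number markers** (``cn_loss``) carry the number of retained
  copies ``2``, ``1``, ``0``.

Internally every state is also expressed in *change units*: the number
of irreversible steps away from the germline state (0 for germline
everywhere).  For sequence markers the unit count equals the state; for
copy-number markers it is ``2 - copies``.  The unit representation makes
the irreversibility constraint ("states never revert along a lineage")
a simple monotonicity condition and gives parsimony a uniform unit cost
per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SEQUENCE_KINDS = frozenset({"fusion", "snv", "indel"})
CN_KINDS = frozenset({"cn_loss"})
MARKER_KINDS = SEQUENCE_KINDS | CN_KINDS

#: maximum number of irreversible steps any marker supports
MAX_UNITS = 2


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass(frozen=True)
class Marker:
    """A tracked genetic lesion.

    Parameters
    ----------
    id:
        Unique marker identifier, e.g. ``"PTEN_ex7_indel1"``.
    gene:
        Gene symbol the lesion affects (several markers may share a
        gene, as with reiterative PTEN indels).
    kind:
        One of ``fusion``, ``snv``, ``indel`` (sequence markers) or
        ``cn_loss`` (copy-number marker).
    """

    id: str
    gene: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise ValidationError(
                f"unknown marker kind {self.kind!r} for {self.id!r}; "
                f"expected one of {sorted(MARKER_KINDS)}"
            )

    @property
    def is_copy_number(self) -> bool:
        return self.kind in CN_KINDS

    def germline_state(self) -> int:
        """State of a normal cell: 0 (wt) or 2 copies."""
        return 2 if self.is_copy_number else 0

    def state_to_units(self, state: int) -> int:
        """Convert an external state to change units from germline."""
        if self.is_copy_number:
            if state not in (0, 1, 2):
                raise ValidationError(
                    f"copy-number state for {self.id!r} must be 0/1/2 copies, got {state!r}"
                )
            return 2 - state
        if state not in (0, 1, 2):
            raise ValidationError(
                f"zygosity state for {self.id!r} must be 0/1/2, got {state!r}"
            )
        return state

    def units_to_state(self, units: int) -> int:
        """Inverse of :meth:`state_to_units`."""
        if units not in (0, 1, 2):
            raise ValidationError(f"units must be 0/1/2, got {units!r}")
        return 2 - units if self.is_copy_number else units


def as_marker(spec) -> Marker:
    """Coerce a ``Marker`` or an ``(id, gene, kind)`` tuple."""
    if isinstance(spec, Marker):
        return spec
    return Marker(*spec)


def genotype_to_units(genotype, markers: list[Marker]) -> tuple[int, ...]:
    """Convert an external genotype vector to change units."""
    if len(genotype) != len(markers):
        raise ValidationError(
            f"genotype length {len(genotype)} != {len(markers)} markers"
        )
    return tuple(m.state_to_units(int(g)) for m, g in zip(markers, genotype))


def units_to_genotype(units, markers: list[Marker]) -> tuple[int, ...]:
    """Convert change units back to external states."""
    return tuple(m.units_to_state(int(u)) for m, u in zip(markers, units))


def units_matrix(states: np.ndarray, markers: list[Marker]) -> np.ndarray:
    """Vectorised state→units conversion; NaN passes through."""
    out = np.asarray(states, dtype=float).copy()
    for j, m in enumerate(markers):
        if m.is_copy_number:
            out[:, j] = 2.0 - out[:, j]
    return out
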