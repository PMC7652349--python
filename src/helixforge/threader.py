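"""Partial threading: copy template backbone onto the target through the MSA.

A target residue receives coordinates exactly when its MSA column holds a
residue in both the target and template rows; columns gapped in the
template leave the residue unmodeled — no coordinate is ever invented
here. Completing those gaps is the hybridization stage's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .errors import ValidationError
from .geometry import ATOM_INDEX, ideal_cb
from .io_formats import BackboneCoords, ReceptorEntry, write_disulfide_pairs

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class ThreadedModel:
    """A partial thread of one target onto one template."""

    target_id: str
    template_id: str
    sequence: str
    coords: BackboneCoords
    #: target position -> template position the backbone was copied from
    provenance: Dict[int, int]

    @property
    def coverage(self) -> float:
        return len(self.provenance) / len(self.sequence)

    def to_entry(self, **kwargs) -> ReceptorEntry:
        return ReceptorEntry(
            id=f"{self.target_id}_on_{self.template_id}",
            sequence=self.sequence, coords=self.coords, **kwargs,
        )


def partial_thread(target_row: str, template_row: str,
                   template_entry: ReceptorEntry,
                   target_id: str = "target") -> ThreadedModel:
    """Thread a target MSA row onto a template's coordinates.

    For every column non-gap in both rows the target residue takes the
    template residue's N/CA/C/O backbone plus an ideal CB (side chains are
    rebuilt downstream; evaluation is CA-based). Deterministic: identical
    inputs give identical models.
    """
    if len(target_row) != len(template_row):
        raise ValidationError(
            f"row widths differ: {len(target_row)} vs {len(template_row)}"
        )
    if template_entry.coords is None:
        raise ValidationError(f"{template_entry.id}: template has no coordinates")
    target_seq = target_row.replace(GAP, "")
    coords = BackboneCoords.empty(len(target_seq))
    provenance: Dict[int, int] = {}
    t_pos = p_pos = 0
    for tc, pc in zip(target_row, template_row):
        if tc != GAP:
            t_pos += 1
        if pc != GAP:
            p_pos += 1
        if tc == GAP or pc == GAP:
            continue
        if not template_entry.coords.is_modeled(p_pos):
            continue  # unresolved template residue: leave target unmodeled
        src = template_entry.coords.array[p_pos - 1]
        dst = coords.array[t_pos - 1]
        for name in ("N", "CA", "C", "O"):
            dst[ATOM_INDEX[name]] = src[ATOM_INDEX[name]]
        dst[ATOM_INDEX["CB"]] = ideal_cb(
            dst[ATOM_INDEX["N"]], dst[ATOM_INDEX["CA"]], dst[ATOM_INDEX["C"]]
        )
        provenance[t_pos] = p_pos
    return ThreadedModel(
        target_id=target_id, template_id=template_entry.id,
        sequence=target_seq, coords=coords, provenance=provenance,
    )


def make_disulfide_file(entry: ReceptorEntry, path=None) -> str:
    """Disulfide restraint lines ("resi_a resi_b", sorted by first index).

    The conserved TM3-ECL2 bond is emitted from the entry's annotations
    unless the receptor is flagged disulfide-free (e.g. the lipid receptors
    lacking the conserved bond), in which case the file is empty and a
    warning is logged. Additional ECL3 pairs are appended as annotated.
    """
    if entry.disulfide_free:
        log.warning("%s: flagged disulfide-free; writing empty restraints", entry.id)
        pairs = []
    else:
        for a, b in entry.disulfides:
            for pos in (a, b):
                if entry.sequence[pos - 1] != "C":
                    raise ValidationError(
                        f"{entry.id}: residue {pos} is not cysteine"
                    )
        pairs = sorted(tuple(sorted(p)) for p in entry.disulfides)
    text = "".join(f"{a} {b}\n" for a, b in pairs)
    if path is not None:
        write_disulfide_pairs(pairs, path)
    return text
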