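"""Slat decorations: poly-T brushes, sticky ends, blocker strands.

* **Poly-T brushes** passivate ribbon edges: without them, blunt helix ends
  stack non-specifically and ribbons aggregate into clumps.  Brushes are
  appended to the 5' and/or 3' ends and annotated non-binding.
* **Sticky ends** (3 or 4 nt) drive closure of coiled ribbons into tubes:
  one ribbon edge presents the overhang, the other its reverse complement.
  With a tightly coiled layout (11.0 bp/turn) closure gives constant-
  diameter tubes; a loosely coiled (shifted-phase) layout closes into tubes
  of varying diameter.
* **Blockers** sequester chosen nuc-y-slats (exact reverse complements of
  their cores), switching off seed-initiated growth.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence, Tuple

import numpy as np

from .blueprint import Domain, SlatBlueprint, SlatRecord
from .layout import twist_report
from .screens import revcomp

__all__ = ["decorate"]

_ALLOWED_STICKY = (0, 3, 4)
_BASES = "ACGT"


def _append(slat: SlatRecord, dom: Domain, end: str) -> SlatRecord:
    if end == "5":
        return replace(slat, domains=(dom,) + slat.domains)
    return replace(slat, domains=slat.domains + (dom,))


def decorate(
    blueprint: SlatBlueprint,
    brush_length: int = 0,
    brush_end: str = "3",
    sticky_end_length: int = 0,
    blockers: Sequence[int] = (),
    rng_seed: int = 0,
) -> SlatBlueprint:
    """Return a decorated copy of a sequence-assigned blueprint."""
    if brush_end not in ("5", "3", "both"):
        raise ValueError("brush_end must be '5', '3' or 'both'")
    if sticky_end_length not in _ALLOWED_STICKY:
        raise ValueError(
            f"sticky_end_length must be one of {_ALLOWED_STICKY} "
            "(half-turn-compatible overhangs)"
        )
    if brush_length < 0:
        raise ValueError("brush_length must be non-negative")
    if not blueprint.sequences_assigned:
        raise ValueError("assign sequences before decorating")

    x_slats = list(blueprint.x_slats)
    y_slats = list(blueprint.y_slats)
    if not x_slats or not y_slats:
        raise ValueError("sticky ends/brushes need slats with edge domains")

    decorations = dict(blueprint.decorations)

    if brush_length > 0:
        brush = Domain(
            length=brush_length, kind="brush", sequence="T" * brush_length
        )
        ends = ("5", "3") if brush_end == "both" else (brush_end,)
        for end in ends:
            x_slats = [_append(s, brush, end) for s in x_slats]
            y_slats = [_append(s, brush, end) for s in y_slats]
        decorations["brush"] = {"length": brush_length, "end": brush_end}
    else:
        decorations.setdefault("brush", None)

    if sticky_end_length > 0:
        rng = np.random.default_rng(rng_seed)
        overhang = "".join(_BASES[i] for i in rng.integers(0, 4, sticky_end_length))
        top = Domain(length=sticky_end_length, kind="sticky", sequence=overhang)
        bottom = Domain(
            length=sticky_end_length, kind="sticky", sequence=revcomp(overhang)
        )
        # one ribbon edge (y-slat 5' termini) carries the overhang, the other
        # (x-slat 3' termini) its complement, so the coiled sheet can seal
        y_slats = [_append(s, top, "5") for s in y_slats]
        x_slats = [_append(s, bottom, "3") for s in x_slats]
        coil = twist_report(blueprint.layout).coil_class
        decorations["sticky_end"] = {
            "length": sticky_end_length,
            "overhang": overhang,
            "closure": "closed-tube" if coil != "flat" else "edge-joined-ribbon",
            "diameter": {
                "tight-coil": "constant",
                "loose-coil": "varying",
                "flat": "n/a",
            }[coil],
        }

    extra = list(blueprint.extra_slats)
    for idx in blockers:
        target = next(
            (s for s in blueprint.nuc_y_slats if s.index == idx), None
        )
        if target is None:
            raise ValueError(f"no nuc-y-slat with index {idx}")
        seq = revcomp(target.sequence)
        extra.append(
            SlatRecord(
                name=f"blocker-{idx:02d}",
                role="blocker",
                index=idx,
                domains=(
                    Domain(length=len(seq), kind="binding", sequence=seq),
                ),
            )
        )
    if blockers:
        decorations["blockers"] = sorted(blockers)

    return replace(
        blueprint,
        x_slats=tuple(x_slats),
        y_slats=tuple(y_slats),
        extra_slats=tuple(extra),
        decorations=decorations,
    )
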