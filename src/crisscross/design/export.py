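"""Exports: FASTA slat files and 96-well plate layout CSVs."""

from __future__ import annotations

import string
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .blueprint import SlatBlueprint, SlatRecord

__all__ = ["export_sequences", "plate_layout"]

_ROWS = string.ascii_uppercase[:8]  # A..H
_COLS = range(1, 13)


def _well_order() -> List[str]:
    """Column-major well order: A1, B1, ..., H1, A2, ..."""
    return [f"{r}{c}" for c in _COLS for r in _ROWS]


def _ordered_slats(
    blueprint: SlatBlueprint, repeat_units: int = 1
) -> List[SlatRecord]:
    out = list(blueprint.nuc_y_slats)
    for unit in range(repeat_units):
        for s in blueprint.x_slats + blueprint.y_slats:
            if repeat_units == 1:
                out.append(s)
            else:
                out.append(
                    SlatRecord(
                        name=f"{s.name}-u{unit}",
                        role=s.role,
                        index=s.index,
                        domains=s.domains,
                        crossover_every_half_turn=s.crossover_every_half_turn,
                    )
                )
    out.extend(blueprint.extra_slats)
    return out


def plate_layout(slats: Sequence[SlatRecord]) -> pd.DataFrame:
    """96-well, column-major plate assignment; overflow spills to plate 2+."""
    wells = _well_order()
    rows = []
    for i, s in enumerate(slats):
        rows.append(
            {
                "plate": i // 96 + 1,
                "well": wells[i % 96],
                "name": s.name,
                "role": s.role,
                "sequence": s.sequence,
            }
        )
    return pd.DataFrame(rows)


def export_sequences(
    blueprint: SlatBlueprint,
    out_dir: str | Path,
    basename: str = "slats",
    formats: Sequence[str] = ("fasta", "plate"),
    repeat_units: int = 1,
) -> Dict[str, Path]:
    """Write the slat set as FASTA and/or a plate-layout CSV.

    Ordering is deterministic (nuc-y, then x/y per repeat unit, then extras),
    so identical blueprints export byte-identical files.  Raises if any
    sequence is unassigned.
    """
    if not blueprint.sequences_assigned:
        raise ValueError("assign sequences before exporting")
    if repeat_units < 1:
        raise ValueError("repeat_units must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slats = _ordered_slats(blueprint, repeat_units)
    paths: Dict[str, Path] = {}
    if "fasta" in formats:
        records = [
            SeqRecord(
                Seq(s.sequence),
                id=s.name,
                description=(
                    f"role={s.role} n={blueprint.n} "
                    f"bp_per_turn={blueprint.layout.bp_per_turn} "
                    f"domains={len(s.domains)}"
                ),
            )
            for s in slats
        ]
        fasta = out_dir / f"{basename}.fasta"
        SeqIO.write(records, str(fasta), "fasta")
        paths["fasta"] = fasta
    if "plate" in formats:
        csv = out_dir / f"{basename}_plate.csv"
        plate_layout(slats).to_csv(csv, index=False)
        paths["plate"] = csv
    unknown = set(formats) - {"fasta", "plate"}
    if unknown:
        raise ValueError(f"unknown export formats: {sorted(unknown)}")
    return paths
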