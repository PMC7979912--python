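"""Genome-seeded nucleators: fold a ssDNA analyte into a crisscross seed.

Instead of a pre-formed DNA-origami seed, a set of six nuc-x-slats can fold
a 190-nt window of a single-stranded DNA genome (e.g. a phage genome) into a
nucleus that presents standard v6 y-handles — coupling ribbon growth to the
presence of the target sequence, the basis for amplification-free detection.

Each nuc-x-slat devotes one contiguous genome-binding segment (the reverse
complement of its block of the window; blocks are near-equal consecutive
pieces, 4 x 32 nt + 2 x 31 nt) plus ``n = 6`` handle domains presenting
y-slat-recruiting sequences.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .blueprint import Domain, SlatBlueprint, SlatRecord
from .layout import generate_domain_layout
from .screens import revcomp

__all__ = ["WINDOW_NT", "design_genome_nucleators"]

#: length of the genome window folded by the nucleator set, nt
WINDOW_NT = 190
#: number of nuc-x-slats in the set
N_SLATS = 6


def _blocks(total: int, parts: int) -> List[int]:
    base, rem = divmod(total, parts)
    return [base + 1 if i < rem else base for i in range(parts)]


def design_genome_nucleators(
    genome_sequence: str,
    window_start: int,
    blueprint: SlatBlueprint | None = None,
    rng_seed: int = 0,
) -> List[SlatRecord]:
    """Six nuc-x-slats folding ``genome[window_start : window_start+190]``.

    The genome-binding domains tile the window without gaps or overlaps
    (concatenating their reverse complements, last slat first, reconstructs
    the reverse complement of the window).  Handle domains present v6
    y-slat-binding sequences: drawn from ``blueprint``'s distal x-domain
    classes when a sequence-assigned v6 blueprint is given, otherwise random
    (seeded) placeholders.
    """
    genome = str(genome_sequence).upper()
    if window_start < 0 or window_start + WINDOW_NT > len(genome):
        raise ValueError(
            f"window [{window_start}, {window_start + WINDOW_NT}) out of "
            f"range for genome of length {len(genome)}"
        )
    window = genome[window_start : window_start + WINDOW_NT]
    bad = set(window) - set("ACGT")
    if bad:
        raise ValueError(
            f"genome window contains ambiguous/invalid bases: {sorted(bad)}"
        )

    layout = generate_domain_layout(6) if blueprint is None else blueprint.layout
    if layout.n != N_SLATS:
        raise ValueError("genome nucleators are defined for v6 (n = 6) designs")
    handle_lengths = layout.domain_lengths[layout.n :]

    if blueprint is not None:
        if not blueprint.sequences_assigned:
            raise ValueError("blueprint must have sequences assigned")
        handle_sets = [
            [d.sequence for d in x.domains if d.kind == "binding"][layout.n :]
            for x in blueprint.x_slats[:N_SLATS]
        ]
    else:
        rng = np.random.default_rng(rng_seed)
        handle_sets = [
            ["".join("ACGT"[i] for i in rng.integers(0, 4, ln)) for ln in handle_lengths]
            for _ in range(N_SLATS)
        ]

    slats = []
    pos = window_start
    for k, size in enumerate(_blocks(WINDOW_NT, N_SLATS)):
        block = genome[pos : pos + size]
        domains = [
            Domain(
                length=size,
                kind="genome",
                cls=("genome", pos, pos + size),
                sequence=revcomp(block),
            )
        ]
        for ln, seq in zip(handle_lengths, handle_sets[k]):
            domains.append(
                Domain(length=ln, kind="binding", cls=("nucx-handle", k), sequence=seq)
            )
        slats.append(
            SlatRecord(
                name=f"nuc-x-{k:02d}",
                role="nuc-x",
                index=k,
                domains=tuple(domains),
            )
        )
        pos += size
    return slats
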