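"""Half-turn domain layouts and twist variants.

Each binding domain of an ssDNA slat spans half a turn of the double helix it
forms with its crossing partner, so domains are 5 or 6 nt and every window of
four consecutive domains must sum to two full turns: 21 nt at the canonical
B-form twist of 10.5 bp/turn, 22 nt when the lattice is underwound to
11.0 bp/turn.  The repeating 5/6 pattern (and its phase) sets the ribbon's
global twist: the canonical 10.5 pattern gives flat ribbons, a shifted 10.5
phase gives loosely coiled ribbons, and 11.0 bp/turn gives tightly coiled
ribbons that can close into tubes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = ["DomainLayout", "generate_domain_layout", "TwistReport", "twist_report"]

# period-4 domain patterns realizing an integer two-turn window with 5/6-nt
# domains; bp_per_turn -> base pattern (phase 0)
_PATTERNS: Dict[float, Tuple[int, int, int, int]] = {
    10.0: (5, 5, 5, 5),
    10.5: (5, 5, 5, 6),
    11.0: (5, 6, 5, 6),
    11.5: (5, 6, 6, 6),
    12.0: (6, 6, 6, 6),
}


@dataclass(frozen=True)
class DomainLayout:
    """Ordered 5/6-nt domain lengths of one slat (x-slat orientation)."""

    n: int
    bp_per_turn: float
    phase: int
    domain_lengths: Tuple[int, ...]

    @property
    def num_domains(self) -> int:
        return 2 * self.n

    @property
    def total_length(self) -> int:
        """Slat core length in nucleotides."""
        return sum(self.domain_lengths)

    @property
    def window_sum(self) -> int:
        """Nucleotides per four-domain (two-turn) window."""
        return int(round(2 * self.bp_per_turn))

    def four_window_sums(self) -> Tuple[int, ...]:
        d = self.domain_lengths
        return tuple(sum(d[i : i + 4]) for i in range(len(d) - 3))


def generate_domain_layout(
    n: int, bp_per_turn: float = 10.5, phase: int = 0
) -> DomainLayout:
    """Deterministic 2n-domain layout for half coordination ``n``.

    ``phase`` rotates the repeating pattern (0..3); a non-zero phase at
    10.5 bp/turn leaves the window sums intact but changes where the 6-nt
    domains fall, which coils the ribbon.  Raises ``ValueError`` for a
    ``bp_per_turn`` that no 5/6-nt half-turn pattern can realize (the
    two-turn window must be an integer between 20 and 24).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if bp_per_turn not in _PATTERNS:
        raise ValueError(
            f"bp_per_turn {bp_per_turn} is not attainable with 5/6-nt "
            f"half-turn domains; choose from {sorted(_PATTERNS)}"
        )
    pattern = _PATTERNS[bp_per_turn]
    phase %= 4
    rotated = pattern[phase:] + pattern[:phase]
    lengths = tuple(rotated[i % 4] for i in range(2 * n))
    return DomainLayout(
        n=n, bp_per_turn=bp_per_turn, phase=phase, domain_lengths=lengths
    )


@dataclass(frozen=True)
class TwistReport:
    bp_per_turn: float
    winding: str  # 'canonical' | 'underwound' | 'overwound'
    phase_shifted: bool
    coil_class: str  # 'flat' | 'loose-coil' | 'tight-coil'


def twist_report(layout: DomainLayout) -> TwistReport:
    """Qualitative ribbon morphology implied by a layout.

    Canonical 10.5 bp/turn -> flat ribbon; 10.5 with a shifted domain phase
    -> loose coiling; under- (or over-) winding away from 10.5 -> tight
    coiling, the precursor to tube closure with sticky ends.
    """
    if layout.bp_per_turn == 10.5:
        winding = "canonical"
        coil = "loose-coil" if layout.phase else "flat"
    else:
        winding = "underwound" if layout.bp_per_turn > 10.5 else "overwound"
        coil = "tight-coil"
    return TwistReport(
        bp_per_turn=layout.bp_per_turn,
        winding=winding,
        phase_shifted=bool(layout.phase),
        coil_class=coil,
    )
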