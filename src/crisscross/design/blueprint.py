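"""Slat sets and the x-y crossing map.

A ribbon design consists of three slat classes:

* **x-slats** (bottom layer, never crossing over — they follow the seed's
  helical direction),
* **y-slats** (top layer, crossing over every half turn),
* **nuc-y-slats** — the ``2n`` unique first-generation y-slats a seed
  captures to initiate growth; modeled here with their seed-proximal half
  replaced by seed-handle domains and their distal half carrying the
  standard periodic y-binding domains that recruit the first x-slats.

Sequence identity is periodic with a repeat of ``r`` x-roles and ``r``
y-roles, where ``r`` is ``2n`` (``full``), ``n`` (``n_pairs``) or ``n/2``
(``half_n_pairs`` — material-saving symmetric designs).  Every crossing
pairs x-role ``a`` domain ``d`` with y-role ``(a + d) mod r`` domain
``2n - 1 - d``; the map is a bijection, so each binding site is specific to
exactly one conjugate site.  y-slat domain lengths run in reverse x order so
that every crossing pairs equal-length half-turn domains.

All strands are written 5'->3'; domain indices are 0-based along the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Tuple

from .layout import DomainLayout

__all__ = ["Domain", "SlatRecord", "SlatBlueprint", "build_blueprint"]

_SYMMETRY_REPEAT = {"full": 2, "n_pairs": 1, "half_n_pairs": 0.5}


@dataclass(frozen=True)
class Domain:
    """One half-turn segment of a slat."""

    length: int
    kind: str  # 'binding' | 'seed-handle' | 'genome' | 'brush' | 'sticky'
    cls: Optional[Tuple] = None  # crossing-class key for binding domains
    sequence: Optional[str] = None

    def with_sequence(self, seq: str) -> "Domain":
        if len(seq) != self.length:
            raise ValueError(
                f"sequence length {len(seq)} != domain length {self.length}"
            )
        return replace(self, sequence=seq)


@dataclass(frozen=True)
class SlatRecord:
    """A single slat species: ordered domains, 5'->3'."""

    name: str
    role: str  # 'x' | 'y' | 'nuc-y' | 'nuc-x'
    index: int
    domains: Tuple[Domain, ...]
    crossover_every_half_turn: bool = False  # strand routing: True for y-slats

    @property
    def sequence(self) -> str:
        parts = []
        for d in self.domains:
            if d.sequence is None:
                raise ValueError(f"slat {self.name}: unassigned domain sequence")
            parts.append(d.sequence)
        return "".join(parts)

    @property
    def core_length(self) -> int:
        return sum(d.length for d in self.domains if d.kind != "brush")


@dataclass(frozen=True)
class SlatBlueprint:
    """A complete slat set for one ribbon design."""

    layout: DomainLayout
    symmetry_mode: str
    repeat: int  # r: distinct x (and y) sequence roles
    x_slats: Tuple[SlatRecord, ...]
    y_slats: Tuple[SlatRecord, ...]
    nuc_y_slats: Tuple[SlatRecord, ...]
    extra_slats: Tuple[SlatRecord, ...] = ()  # blockers, genome nucleators...
    decorations: Dict[str, object] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.layout.n

    def all_slats(self) -> Tuple[SlatRecord, ...]:
        return self.nuc_y_slats + self.x_slats + self.y_slats + self.extra_slats

    def crossings(self) -> Iterator[Tuple[Tuple, int, int, int, int]]:
        """Yield (class, x_role, x_domain, y_role, y_domain) for every crossing."""
        w = self.layout.num_domains
        for a in range(self.repeat):
            for d in range(w):
                b = (a + d) % self.repeat
                dy = w - 1 - d
                yield ((a, d), a, d, b, dy)

    @property
    def sequences_assigned(self) -> bool:
        return all(
            dom.sequence is not None for s in self.all_slats() for dom in s.domains
        )


def build_blueprint(layout: DomainLayout, symmetry_mode: str = "full") -> SlatBlueprint:
    """Construct the slat set (sequences unassigned) for a layout.

    ``full`` uses ``2n`` distinct x- and y-roles per repeat; ``n_pairs`` and
    ``half_n_pairs`` exploit the lattice symmetry to cut the unique-sequence
    count to ``n`` or ``n/2`` pairs.  The nuc-y set always has ``2n`` members
    regardless of symmetry (each seed handle is unique).
    """
    if symmetry_mode not in _SYMMETRY_REPEAT:
        raise ValueError(
            f"unknown symmetry mode {symmetry_mode!r}; "
            f"choose from {sorted(_SYMMETRY_REPEAT)}"
        )
    n = layout.n
    r_frac = _SYMMETRY_REPEAT[symmetry_mode] * n
    if r_frac != int(r_frac):
        raise ValueError("half_n_pairs symmetry requires even n")
    r = int(r_frac)
    w = layout.num_domains
    x_lengths = layout.domain_lengths
    y_lengths = tuple(reversed(x_lengths))

    x_slats = tuple(
        SlatRecord(
            name=f"x-{a:02d}",
            role="x",
            index=a,
            domains=tuple(
                Domain(length=x_lengths[d], kind="binding", cls=(a, d))
                for d in range(w)
            ),
        )
        for a in range(r)
    )
    y_slats = tuple(
        SlatRecord(
            name=f"y-{b:02d}",
            role="y",
            index=b,
            domains=tuple(
                Domain(
                    length=y_lengths[dy],
                    kind="binding",
                    cls=((b - (w - 1 - dy)) % r, w - 1 - dy),
                )
                for dy in range(w)
            ),
            crossover_every_half_turn=True,
        )
        for b in range(r)
    )
    # nuc-y: 2n unique species; seed-proximal half -> unique handle domains,
    # distal half -> the distal binding domains of the corresponding y-role
    nuc_y = []
    for j in range(2 * n):
        b = j % r
        base = y_slats[b].domains
        domains = []
        for dy in range(w):
            if dy < n:
                domains.append(
                    Domain(length=y_lengths[dy], kind="seed-handle", cls=("nuc", j, dy))
                )
            else:
                domains.append(base[dy])
        nuc_y.append(
            SlatRecord(
                name=f"nuc-y-{j:02d}",
                role="nuc-y",
                index=j,
                domains=tuple(domains),
                crossover_every_half_turn=True,
            )
        )
    return SlatBlueprint(
        layout=layout,
        symmetry_mode=symmetry_mode,
        repeat=r,
        x_slats=x_slats,
        y_slats=y_slats,
        nuc_y_slats=tuple(nuc_y),
    )
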