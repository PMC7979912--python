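"""Bond-topology models of the three monomer architectures.

Three ways of tiling a quasi-1D assembly are compared:

* ``ST`` — square tiles on a cylindrical (tube) square lattice, half
  coordination ``n = 2``: a tile at the growth front binds two nearest
  neighbours.
* ``HT`` — hexagonal tiles on a cylindrical triangular lattice, ``n = 3``.
* ``CS`` — crisscross slats: elongated monomers carrying a linear array of
  ``2n`` weak binding sites, each specific to one conjugate site on one of
  ``2n`` distinct perpendicular slats.  Slats reach far beyond nearest
  neighbours, so ``n`` is a free design parameter.

An architecture knows its placement lattice: given a set of occupied
placements and a candidate placement it reports how many bonds the incoming
monomer would form.  Free energies live in :mod:`crisscross.landscape`.

Placements are architecture-specific hashable tuples:

* tubes: ``(row, col)`` with ``col`` taken modulo the circumference;
* slats:  ``('x', i)`` or ``('y', j)`` — layer plus rail index.  An x-slat at
  rail ``i`` crosses y-slats ``i .. i+2n-1`` (0-based, stagger one rail per
  slat), so a slat arriving at a complete ribbon front always finds exactly
  ``n`` of its ``2n`` partners already in place.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import FrozenSet, Hashable, Iterable, Tuple

__all__ = [
    "Architecture",
    "SquareTileTube",
    "HexTileTube",
    "CrisscrossSlats",
    "AssemblyState",
    "build_architecture",
    "attachment_bonds",
]

Placement = Hashable
State = Tuple[Placement, ...]


class Architecture(ABC):
    """Abstract bond topology with half coordination ``n``."""

    kind: str
    n: int

    @property
    def full_coordination(self) -> int:
        return 2 * self.n

    @abstractmethod
    def neighbors(self, placement: Placement) -> Iterable[Placement]:
        """Placements that share a bond with ``placement`` when both occupied."""

    @abstractmethod
    def origin(self) -> Placement:
        """Canonical placement for the first monomer."""

    @abstractmethod
    def canonicalize(self, state: Iterable[Placement]) -> State:
        """Translation/rotation-invariant canonical form of an occupancy set."""

    def bonds_gained(self, occupied: FrozenSet[Placement], placement: Placement) -> int:
        if placement in occupied:
            raise ValueError(f"placement {placement!r} already occupied")
        return sum(1 for nb in self.neighbors(placement) if nb in occupied)

    def candidate_placements(self, occupied: FrozenSet[Placement]) -> set:
        """All unoccupied placements adjacent-by-bond to the assembly."""
        if not occupied:
            return {self.origin()}
        cand = set()
        for p in occupied:
            for nb in self.neighbors(p):
                if nb not in occupied:
                    cand.add(nb)
        return cand

    def bond_count(self, occupied: Iterable[Placement]) -> int:
        """Total bonds of an occupancy set (each pair counted once)."""
        occ = frozenset(occupied)
        total = sum(
            1 for p in occ for nb in self.neighbors(p) if nb in occ
        )
        assert total % 2 == 0
        return total // 2


@dataclass(frozen=True)
class SquareTileTube(Architecture):
    """Square-tile nanotube: square lattice wrapped to a cylinder.

    ``circumference`` tiles around the tube; rows extend along the tube axis.
    """

    circumference: int
    kind: str = field(default="ST", init=False)
    n: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        if self.circumference < 1:
            raise ValueError("circumference must be a positive integer")
        if self.circumference == 1:
            warnings.warn(
                "circumference 1 is a degenerate 1-wide chain", stacklevel=3
            )

    def neighbors(self, placement):
        r, c = placement
        m = self.circumference
        nbs = [(r + 1, c), (r - 1, c)]
        if m > 1:
            nbs += [(r, (c + 1) % m), (r, (c - 1) % m)]
        # circumference 2: left and right neighbour coincide; keep single bond
        return set(nbs)

    def origin(self):
        return (0, 0)

    def canonicalize(self, state):
        state = list(state)
        m = self.circumference
        rmin = min(r for r, _ in state)
        best = None
        for dc in range(m):
            t = tuple(sorted((r - rmin, (c + dc) % m) for r, c in state))
            if best is None or t < best:
                best = t
        return best


@dataclass(frozen=True)
class HexTileTube(Architecture):
    """Hexagonal-tile nanotube: triangular (6-neighbour) lattice on a cylinder.

    Axial coordinates; ``col`` wraps modulo the circumference.
    """

    circumference: int
    kind: str = field(default="HT", init=False)
    n: int = field(default=3, init=False)

    def __post_init__(self) -> None:
        if self.circumference < 1:
            raise ValueError("circumference must be a positive integer")
        if self.circumference == 1:
            warnings.warn(
                "circumference 1 is a degenerate 1-wide chain", stacklevel=3
            )

    def neighbors(self, placement):
        r, c = placement
        m = self.circumference
        raw = [
            (r + 1, c), (r - 1, c),
            (r, c + 1), (r, c - 1),
            (r + 1, c - 1), (r - 1, c + 1),
        ]
        return {(rr, cc % m) for rr, cc in raw if (rr, cc % m) != (r, c)}

    def origin(self):
        return (0, 0)

    def canonicalize(self, state):
        state = list(state)
        m = self.circumference
        rmin = min(r for r, _ in state)
        best = None
        for dc in range(m):
            t = tuple(sorted((r - rmin, (c + dc) % m) for r, c in state))
            if best is None or t < best:
                best = t
        return best


@dataclass(frozen=True)
class CrisscrossSlats(Architecture):
    """Crisscross-slat ribbon with half coordination ``n``.

    Each slat carries ``2n`` binding sites (the ribbon is ``2n`` sites wide).
    x-slat ``i`` crosses y-slats ``i .. i + 2n - 1``; equivalently y-slat
    ``j`` crosses x-slats ``j - 2n + 1 .. j``.  Site indices along a slat run
    ``0 .. 2n-1``: site ``d`` of x-slat ``i`` meets y-slat ``i + d``, which
    receives it on its own site ``2n - 1 - d``.
    """

    half_coordination: int
    kind: str = field(default="CS", init=False)

    def __post_init__(self) -> None:
        if self.half_coordination < 1:
            raise ValueError("half coordination n must be >= 1")
        object.__setattr__(self, "n", self.half_coordination)

    @property
    def width(self) -> int:
        """Binding sites per slat (ribbon width)."""
        return 2 * self.n

    def neighbors(self, placement):
        layer, i = placement
        w = self.width
        if layer == "x":
            return {("y", i + d) for d in range(w)}
        if layer == "y":
            return {("x", i - d) for d in range(w)}
        raise ValueError(f"unknown layer {layer!r}")

    def origin(self):
        return ("y", 0)

    def canonicalize(self, state):
        # diagonal translation (i -> i+t on both layers) preserves bonds, and
        # so does the x<->y mirror (x_i -> y_{-i}, y_j -> x_{-j}).
        state = list(state)

        def shifted(st):
            t = min(i for _, i in st)
            return tuple(sorted((layer, i - t) for layer, i in st))

        mirror = [("y" if layer == "x" else "x", -i) for layer, i in state]
        return min(shifted(state), shifted(mirror))


@dataclass(frozen=True)
class AssemblyState:
    """A connected assembly: occupancy set plus monomer/bond counts."""

    occupied: FrozenSet[Placement]
    N: int
    B: int
    seeded: bool = False

    @classmethod
    def from_occupancy(
        cls, arch: Architecture, occupied: Iterable[Placement], seeded: bool = False
    ) -> "AssemblyState":
        occ = frozenset(occupied)
        if occ and not _is_connected(arch, occ):
            raise ValueError("assembly must be connected via bonds")
        return cls(occupied=occ, N=len(occ), B=arch.bond_count(occ), seeded=seeded)

    @classmethod
    def empty(cls) -> "AssemblyState":
        return cls(occupied=frozenset(), N=0, B=0)

    def attach(self, arch: Architecture, placement: Placement) -> "AssemblyState":
        b = attachment_bonds(arch, self, placement)
        return AssemblyState(
            occupied=self.occupied | {placement},
            N=self.N + 1,
            B=self.B + b,
            seeded=self.seeded,
        )


def _is_connected(arch: Architecture, occ: FrozenSet[Placement]) -> bool:
    it = iter(occ)
    seen = {next(it)}
    frontier = list(seen)
    while frontier:
        p = frontier.pop()
        for nb in arch.neighbors(p):
            if nb in occ and nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return len(seen) == len(occ)


def attachment_bonds(
    arch: Architecture, assembly: AssemblyState, placement: Placement
) -> int:
    """Bonds a monomer at ``placement`` would form with ``assembly``.

    The first monomer on an empty assembly forms 0 bonds; at a complete
    crisscross ribbon front an incoming slat forms exactly ``n``.
    """
    if placement in assembly.occupied:
        raise ValueError(f"placement {placement!r} already occupied")
    if assembly.N == 0:
        return 0
    b = arch.bonds_gained(assembly.occupied, placement)
    if b == 0:
        raise ValueError(
            f"placement {placement!r} is not adjacent-by-bond to the assembly"
        )
    return b


def build_architecture(
    kind: str,
    n: int | None = None,
    circumference: int | None = None,
    width: int | None = None,
) -> Architecture:
    """Construct an architecture by kind.

    ``ST``/``HT`` need ``circumference`` (tiles around the tube); ``CS`` needs
    ``n`` (or equivalently ``width = 2n``).
    """
    kind = kind.upper()
    if kind == "ST":
        if n not in (None, 2):
            raise ValueError("square tiles have half coordination n = 2")
        if circumference is None:
            raise ValueError("ST requires a circumference")
        return SquareTileTube(circumference=circumference)
    if kind == "HT":
        if n not in (None, 3):
            raise ValueError("hexagonal tiles have half coordination n = 3")
        if circumference is None:
            raise ValueError("HT requires a circumference")
        return HexTileTube(circumference=circumference)
    if kind == "CS":
        if n is None:
            if width is None:
                raise ValueError("CS requires n (or width = 2n)")
            if width % 2:
                raise ValueError("CS width must be even (2n binding sites)")
            n = width // 2
        elif width is not None and width != 2 * n:
            raise ValueError("CS width must equal 2n")
        return CrisscrossSlats(half_coordination=n)
    raise ValueError(f"unsupported architecture kind {kind!r}")
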