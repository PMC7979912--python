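"""Free-energy landscapes, critical nuclei and nucleation barriers.

The free energy of an assembly is ``G = N*g_mc - B*g_se`` (decades).  The
kinetic barrier to spontaneous nucleation is set by the critical nucleus: the
assembly along the minimal-barrier pathway past which growth is net downhill.

Two related quantities are exposed on a :class:`Landscape`:

``barrier``
    The free energy *of the critical nucleus*.  The nucleus composition is the
    one selected under near-reversible conditions (``epsilon -> 0``) — for
    crisscross slats the complete ``n x n`` junction of ``2n`` slats with
    ``n**2`` bonds — and its ``G`` is evaluated at the working ``epsilon``.
    Because ``g_se = (g_mc + epsilon)/n``, this makes the barrier fall with
    slope exactly ``-B*/n`` per decade of ``epsilon`` while the composition is
    unchanged, which is how extra coordination (large ``n``) protects the
    barrier under fast, irreversible growth.

``peak``
    ``max(G_profile)`` along the minimal-barrier pathway at the working
    conditions.  For the tube architectures near the benchmark conditions the
    pathway maximum *is* the critical nucleus, so ``peak == barrier``.  For
    slats at ``epsilon > 0`` the staircase pathway transiently overshoots the
    junction (early slats attach with fewer than ``n`` bonds), so
    ``peak >= barrier``.

The minimal-barrier pathway itself is found by exact best-first (Dijkstra on
the running maximum of ``G``) over canonicalized connected assemblies, with an
independent exhaustive dynamic program over all connected attachment orders
available as an oracle for testing.  For crisscross slats the analytic
staircase pathway (slats added in alternating perpendicular order, the k-th
pair attaching with ``k-1`` and ``k`` bonds) is used; it is verified minimal
against the exact search on small systems.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .architectures import (
    Architecture,
    AssemblyState,
    CrisscrossSlats,
    HexTileTube,
    SquareTileTube,
)
from .energies import EnergyParams, gse_from_epsilon

__all__ = [
    "Landscape",
    "UnbracketedError",
    "free_energy",
    "critical_nucleus",
    "exhaustive_min_peak",
    "barrier_vs_epsilon",
    "relative_nucleation_rate",
    "landscape_with_seed",
    "match_architectures",
    "MatchResult",
    "eps0_barrier",
]


class UnbracketedError(RuntimeError):
    """The free-energy profile is still rising at ``max_size``."""


def free_energy(assembly: AssemblyState, params: EnergyParams) -> float:
    """``G = N*g_mc - B*g_se`` in decades; the empty assembly has G = 0."""
    return assembly.N * params.g_mc - assembly.B * params.g_se


@dataclass(frozen=True)
class Landscape:
    """Minimal-barrier assembly pathway and its critical nucleus."""

    pathway: Tuple[Tuple, ...]  # occupancy tuples, one per profile entry past 0
    G_profile: Tuple[float, ...]  # G after 0, 1, 2, ... attachments
    critical_size: int  # N of the critical nucleus
    bonds_at_critical: int  # B of the critical nucleus
    barrier: float  # G of the critical nucleus, decades
    seeded: bool = False

    @property
    def peak(self) -> float:
        """Maximum of the free-energy profile (pathway maximum)."""
        return max(self.G_profile)


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------


def _best_first(
    arch: Architecture, g_mc: float, g_se: float, max_size: int
) -> Tuple[List[Tuple], List[float]]:
    """Minimal-barrier pathway by Dijkstra on the running G maximum.

    States are canonicalized occupancy tuples; priority is
    ``(peak G so far, G, canonical labels)``.  Returns the optimal chain of
    states (size 1..max_size) and their free energies.
    """
    start = arch.canonicalize([arch.origin()])
    g0 = g_mc
    best: Dict[Tuple, Tuple[float, float, Tuple | None]] = {
        start: (g0, g0, None)
    }  # state -> (peak, G, parent)
    pq = [(g0, g0, start)]
    terminal = None
    while pq:
        peak, G, state = heapq.heappop(pq)
        cur = best.get(state)
        if cur is None or (peak, G) > (cur[0], cur[1]):
            continue
        if len(state) == max_size:
            terminal = state
            break
        occ = frozenset(state)
        for cand in arch.candidate_placements(occ):
            b = arch.bonds_gained(occ, cand)
            G2 = G + g_mc - b * g_se
            peak2 = max(peak, G2)
            child = arch.canonicalize(list(state) + [cand])
            prev = best.get(child)
            if prev is None or (peak2, G2) < (prev[0], prev[1]):
                best[child] = (peak2, G2, state)
                heapq.heappush(pq, (peak2, G2, child))
    if terminal is None:
        raise RuntimeError("search exhausted without reaching max_size")
    chain: List[Tuple] = []
    s: Tuple | None = terminal
    while s is not None:
        chain.append(s)
        s = best[s][2]
    chain.reverse()
    profile = [best[s][1] for s in chain]
    return chain, profile


def exhaustive_min_peak(
    arch: Architecture, g_mc: float, g_se: float, max_size: int
) -> float:
    """Oracle: minimal pathway maximum over *all* connected attachment orders.

    Layered dynamic program on raw (uncanonicalized) occupancy sets grown from
    the origin placement; every attachment order of every connected assembly
    of ``max_size`` monomers is covered.  Exponential — testing only.
    """
    origin = arch.origin()
    layer: Dict[frozenset, float] = {frozenset([origin]): g_mc}
    G_of = {frozenset([origin]): g_mc}
    for _ in range(max_size - 1):
        nxt: Dict[frozenset, float] = {}
        for occ, peak in layer.items():
            G = G_of[occ]
            for cand in arch.candidate_placements(occ):
                b = arch.bonds_gained(occ, cand)
                G2 = G + g_mc - b * g_se
                child = occ | {cand}
                p2 = max(peak, G2)
                if p2 < nxt.get(child, math.inf):
                    nxt[child] = p2
                    G_of[child] = G2
        layer = nxt
    return min(layer.values())


# ---------------------------------------------------------------------------
# crisscross staircase (analytic minimal pathway)
# ---------------------------------------------------------------------------


def _staircase_states(n: int, length: int) -> List[Tuple]:
    """Occupancy chain of the crisscross staircase pathway.

    Order: y at rail 0, x at rail 0, y at 1, x at -1, y at 2, x at -2, ...
    (the k-th y attaches with k-1 bonds, the k-th x with k), followed by
    steady-state additions (y at rail n+t, x at rail 1+t) making n bonds each.
    """
    placements: List[Tuple] = []
    for k in range(1, n + 1):
        placements.append(("y", k - 1))
        placements.append(("x", -(k - 1)))
    t = 0
    while len(placements) < length:
        placements.append(("y", n + t))
        if len(placements) < length:
            placements.append(("x", 1 + t))
        t += 1
    states = []
    for i in range(1, length + 1):
        states.append(tuple(placements[:i]))
    return states


def _staircase_landscape(
    arch: CrisscrossSlats, params: EnergyParams, max_size: int
) -> Landscape:
    n = arch.n
    if max_size < 2 * n + 1:
        raise UnbracketedError(
            f"max_size {max_size} cannot bracket the 2n = {2 * n} slat "
            "critical nucleus; increase max_size"
        )
    states = _staircase_states(n, max_size)
    profile = [0.0]
    occ: set = set()
    B = 0
    for st in states:
        new = st[-1]
        b = arch.bonds_gained(frozenset(occ), new) if occ else 0
        occ.add(new)
        B += b
        profile.append(len(occ) * params.g_mc - B * params.g_se)
    # past the junction every addition makes n bonds: dG = -epsilon
    if params.epsilon < 0:
        raise UnbracketedError(
            "epsilon < 0: the profile rises without bound (growth subcritical)"
        )
    nucleus_N = 2 * n
    nucleus_B = n * n
    barrier = nucleus_N * params.g_mc - nucleus_B * params.g_se
    return Landscape(
        pathway=tuple(states),
        G_profile=tuple(profile),
        critical_size=nucleus_N,
        bonds_at_critical=nucleus_B,
        barrier=barrier,
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _default_max_size(arch: Architecture) -> int:
    if isinstance(arch, CrisscrossSlats):
        return 2 * arch.n + 4
    return max(3 * arch.circumference, 9)


def critical_nucleus(
    arch: Architecture,
    params: EnergyParams,
    max_size: int | None = None,
    method: str = "auto",
) -> Landscape:
    """Minimal-barrier landscape and critical nucleus of an architecture.

    ``method='auto'`` uses the analytic staircase for crisscross slats and
    exact best-first search for tubes; ``method='search'`` forces the exact
    search (any architecture).  Raises :class:`UnbracketedError` when the
    profile is still rising at ``max_size``.
    """
    if max_size is None:
        max_size = _default_max_size(arch)
    if max_size < 2:
        raise UnbracketedError("max_size too small to bracket any maximum")
    if method == "auto" and isinstance(arch, CrisscrossSlats):
        return _staircase_landscape(arch, params, max_size)
    if method not in ("auto", "search"):
        raise ValueError(f"unknown method {method!r}")
    chain, profile = _best_first(arch, params.g_mc, params.g_se, max_size)
    full = [0.0] + profile
    peak = max(full)
    # critical nucleus: first state achieving the pathway maximum (at exact
    # plateaus — eps = 0 — later states merely tie, they do not raise G)
    idx = min(i for i, g in enumerate(full) if g >= peak - 1e-12)
    if idx >= len(full) - 1:
        raise UnbracketedError(
            f"profile still rising at max_size={max_size}; barrier unbracketed"
        )
    nucleus = chain[idx - 1] if idx >= 1 else ()
    B = arch.bond_count(nucleus) if nucleus else 0
    return Landscape(
        pathway=tuple(chain),
        G_profile=tuple(full),
        critical_size=idx,
        bonds_at_critical=B,
        barrier=peak,
    )


@dataclass(frozen=True)
class BarrierPoint:
    epsilon: float
    barrier: float
    critical_size: int


def barrier_vs_epsilon(
    arch: Architecture,
    params_at_eps0: EnergyParams,
    eps_grid: Sequence[float],
    max_size: int | None = None,
) -> List[BarrierPoint]:
    """Nucleation barrier versus irreversibility ``epsilon``.

    ``params_at_eps0`` fixes the monomer cost; at each grid point the bond
    energy is re-derived as ``g_se = (g_mc + eps)/n``.  The barrier is
    non-increasing in ``epsilon``, as is the critical nucleus size.
    """
    eps_grid = list(eps_grid)
    if any(e < 0 for e in eps_grid):
        raise ValueError("eps_grid must be non-negative")
    if any(b > a for a, b in zip(eps_grid[1:], eps_grid)):
        raise ValueError("eps_grid must be increasing")
    out = []
    for eps in eps_grid:
        p = params_at_eps0.at_epsilon(eps, arch.n)
        ls = critical_nucleus(arch, p, max_size=max_size)
        out.append(BarrierPoint(eps, ls.barrier, ls.critical_size))
    return out


def relative_nucleation_rate(barrier_a: float, barrier_b: float) -> float:
    """Orders of magnitude by which nucleation over ``barrier_a`` is slower.

    Barriers are in decades, so the answer is simply ``barrier_a - barrier_b``.
    """
    return barrier_a - barrier_b


def landscape_with_seed(arch: Architecture, params: EnergyParams) -> Landscape:
    """Seeded free-energy profile for a crisscross architecture.

    The seed is modeled purely energetically: a pre-formed edge presenting
    ``2n`` handle sites captures the ``2n`` nucleating y-slats at no net cost
    (the seed pre-pays the nucleation barrier), after which every slat
    addition at the front makes ``n`` bonds, i.e. ``dG = g_mc - n*g_se =
    -epsilon`` per slat.
    """
    if not isinstance(arch, CrisscrossSlats):
        raise ValueError("seeded landscapes are defined for CS architectures")
    n = arch.n
    capture = [0.0] * (2 * n + 1)
    growth = [-params.epsilon * (k + 1) for k in range(2 * n)]
    profile = capture + growth
    states = _staircase_states(n, len(profile) - 1)
    return Landscape(
        pathway=tuple(states),
        G_profile=tuple(profile),
        critical_size=0,
        bonds_at_critical=0,
        barrier=0.0,
        seeded=True,
    )


# ---------------------------------------------------------------------------
# near-reversible barriers and architecture matching
# ---------------------------------------------------------------------------


def eps0_barrier(arch: Architecture, g_mc: float) -> float:
    """Nucleation barrier at near-reversible conditions (``epsilon -> 0``).

    Closed forms (verified against the exact search in the test suite):

    * CS(n):   ``n * g_mc``        — the complete n x n junction.
    * ST(m):   ``g_mc * (m+1)/2``  — a single ring of m tiles plus the first
      tile of the next ring.
    * HT(m):   ``g_mc * (2m+1)/3`` — likewise on the triangular lattice.

    The ring formulas require circumference >= 3 (at m <= 2 the wrap bond
    degenerates and the closed forms do not apply).
    """
    if isinstance(arch, CrisscrossSlats):
        return arch.n * g_mc
    m = arch.circumference
    if m < 3:
        raise ValueError("tube ring-barrier formulas require circumference >= 3")
    if isinstance(arch, SquareTileTube):
        return g_mc * (m + 1) / 2
    if isinstance(arch, HexTileTube):
        return g_mc * (2 * m + 1) / 3
    raise ValueError(f"unsupported architecture {arch!r}")


@dataclass(frozen=True)
class MatchResult:
    architecture: Architecture
    params: EnergyParams
    barrier_eps0: float


class MatchError(RuntimeError):
    """No feasible parameterization matches the reference barrier."""


def match_architectures(
    reference_arch: Architecture,
    reference_params: EnergyParams,
    target_kind: str,
    max_circumference: int = 64,
) -> MatchResult:
    """Parameterize ``target_kind`` to match the reference's eps->0 barrier.

    At ``epsilon -> 0`` the bond energy is pinned to ``g_se = g_mc/n``, so the
    only free knobs are the target's monomer cost (its standard-state offset)
    and, for tubes, the integer circumference.  The circumference is chosen so
    the solved monomer cost lies closest to the reference's (keeping the
    architectures at comparable concentrations), then ``g_mc`` is solved
    exactly; the matched barriers agree to machine precision.
    """
    b0 = eps0_barrier(reference_arch, reference_params.g_mc)
    kind = target_kind.upper()
    if kind == "CS":
        n = reference_arch.n if isinstance(reference_arch, CrisscrossSlats) else 6
        arch = CrisscrossSlats(half_coordination=n)
        g_mc = b0 / arch.n
        params = EnergyParams.for_architecture(arch.n, 0.0, g_mc=g_mc)
        return MatchResult(arch, params, eps0_barrier(arch, g_mc))
    if kind not in ("ST", "HT"):
        raise ValueError(f"unsupported target kind {target_kind!r}")
    best: Tuple[float, int] | None = None
    for m in range(3, max_circumference + 1):
        g_mc = 2 * b0 / (m + 1) if kind == "ST" else 3 * b0 / (2 * m + 1)
        d = abs(g_mc - reference_params.g_mc)
        if best is None or d < best[0]:
            best = (d, m)
    if best is None:
        raise MatchError(
            f"no circumference in [3, {max_circumference}] matches the "
            f"reference barrier {b0:.3f}"
        )
    m = best[1]
    arch = SquareTileTube(m) if kind == "ST" else HexTileTube(m)
    g_mc = 2 * b0 / (m + 1) if kind == "ST" else 3 * b0 / (2 * m + 1)
    params = EnergyParams.for_architecture(arch.n, 0.0, g_mc=g_mc)
    return MatchResult(arch, params, eps0_barrier(arch, g_mc))
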