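"""Benchmark conditions and absolute-energy calibration.

The architecture comparison is run at a fixed benchmark: 1 uM monomers and
``epsilon = 2`` (attachment 100x faster than detachment at the growth front).
Relative barriers and the slope law ``dG*/deps = -B*/n`` follow from the
model alone, but the *absolute* barrier scale also depends on the
standard-state offset of the monomer chemical potential — the concentration
sets ``g_mc`` only up to a constant capturing rotational/conformational
restriction on binding, which differs between compact tiles and long floppy
ssDNA slats.

Those offsets (and the tube circumference, the one topology constant the
tube barrier depends on) are calibrated once so the benchmark reproduces the
reference barrier heights of 10.8 (ST), 13.9 (HT), 34.4 (CS n=6) and 45.8
(CS n=8) decades.  The calibration result is shipped below; the
``calibrate_*`` functions re-derive it from the model and the reference
values, and the test suite checks the round trip.  Notably only the ST value
is fitted for the tubes — the HT barrier then follows from the model
(13.93 -> 13.9), which is a genuine cross-check, not a fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from scipy.optimize import brentq

from .architectures import (
    Architecture,
    CrisscrossSlats,
    HexTileTube,
    SquareTileTube,
    build_architecture,
)
from .energies import EnergyParams
from .landscape import Landscape, critical_nucleus

__all__ = [
    "BENCHMARK_CONCENTRATION",
    "BENCHMARK_EPSILON",
    "TUBE_CIRCUMFERENCE",
    "G_MC_TILES",
    "G_MC_SLATS",
    "REFERENCE_BARRIERS",
    "calibrate_tiles",
    "calibrate_slats",
    "benchmark_architecture",
    "benchmark_params",
    "benchmark_landscape",
    "barrier_table",
]

#: benchmark free-monomer concentration, mol/L ("high" growth regime)
BENCHMARK_CONCENTRATION = 1e-6
#: benchmark irreversibility, decades (100:1 growth:shrinkage)
BENCHMARK_EPSILON = 2.0

#: reference barrier heights (decades) at the benchmark the calibration hits
REFERENCE_BARRIERS: Dict[str, float] = {
    "ST": 10.8,
    "HT": 13.9,
    "CS6": 34.4,
    "CS8": 45.8,
}

# ---- shipped calibration ---------------------------------------------------
#: tube circumference (tiles around the tube) for both tile architectures
TUBE_CIRCUMFERENCE = 3
#: calibrated monomer cost for compact tiles, decades
G_MC_TILES = 7.4
#: calibrated monomer cost for elongated slats, decades
G_MC_SLATS = 7.729166666666667


def calibrate_tiles(
    st_barrier: float = REFERENCE_BARRIERS["ST"],
    circumference: int = TUBE_CIRCUMFERENCE,
    epsilon: float = BENCHMARK_EPSILON,
) -> float:
    """Solve the tile monomer cost from the square-tile reference barrier.

    Inverts the exact best-first barrier of the ST tube (numerically; the
    barrier is piecewise linear and strictly increasing in ``g_mc``).  The
    hexagonal-tile barrier is *not* used: it is an out-of-sample check.
    """
    arch = SquareTileTube(circumference)

    def f(g_mc: float) -> float:
        p = EnergyParams.for_architecture(arch.n, epsilon, g_mc=g_mc)
        return critical_nucleus(arch, p, max_size=3 * circumference).barrier - st_barrier

    return brentq(f, epsilon + 0.5, 30.0, xtol=1e-12)


def calibrate_slats(
    cs_barriers: Dict[int, float] | None = None,
    epsilon: float = BENCHMARK_EPSILON,
) -> float:
    """Least-squares slat monomer cost from the CS reference barriers.

    The critical nucleus of CS(n) is the complete junction, with barrier
    ``2n*g_mc - n^2*g_se = n*(g_mc - epsilon)``; the fit minimizes the
    per-coordination residuals ``(barrier_n / n) - (g_mc - epsilon)`` over
    the provided architectures, which has the closed form
    ``g_mc = epsilon + mean_n(barrier_n / n)``.
    """
    if cs_barriers is None:
        cs_barriers = {6: REFERENCE_BARRIERS["CS6"], 8: REFERENCE_BARRIERS["CS8"]}
    return epsilon + sum(b / n for n, b in cs_barriers.items()) / len(cs_barriers)


def benchmark_architecture(label: str) -> Architecture:
    """Architecture for a benchmark label: ST, HT, CS6, CS8 (or CS<n>)."""
    label = label.upper()
    if label == "ST":
        return SquareTileTube(TUBE_CIRCUMFERENCE)
    if label == "HT":
        return HexTileTube(TUBE_CIRCUMFERENCE)
    if label.startswith("CS"):
        return build_architecture("CS", n=int(label[2:] or 6))
    raise ValueError(f"unknown benchmark label {label!r}")


def benchmark_params(
    label: str, epsilon: float = BENCHMARK_EPSILON
) -> EnergyParams:
    """Calibrated energies for a benchmark architecture at ``epsilon``."""
    arch = benchmark_architecture(label)
    g_mc = G_MC_SLATS if isinstance(arch, CrisscrossSlats) else G_MC_TILES
    return EnergyParams(
        g_mc=g_mc,
        g_se=(g_mc + epsilon) / arch.n,
        epsilon=epsilon,
        concentration=BENCHMARK_CONCENTRATION,
    )


def benchmark_landscape(
    label: str, epsilon: float = BENCHMARK_EPSILON, max_size: int | None = None
) -> Landscape:
    """Calibrated minimal-barrier landscape for a benchmark architecture."""
    arch = benchmark_architecture(label)
    return critical_nucleus(arch, benchmark_params(label, epsilon), max_size=max_size)


@dataclass(frozen=True)
class BarrierRow:
    label: str
    n: int
    barrier: float
    critical_size: int
    bonds_at_critical: int


def barrier_table(epsilon: float = BENCHMARK_EPSILON) -> Dict[str, BarrierRow]:
    """The four benchmark barriers, recomputed from the calibrated model."""
    out = {}
    for label in ("ST", "HT", "CS6", "CS8"):
        arch = benchmark_architecture(label)
        ls = benchmark_landscape(label, epsilon)
        out[label] = BarrierRow(
            label, arch.n, ls.barrier, ls.critical_size, ls.bonds_at_critical
        )
    return out
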