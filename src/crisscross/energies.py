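"""kTAM energy bookkeeping in decades (log10 units).

In the kinetic Tile Assembly Model an assembly ``A`` of ``N`` monomers joined
by ``B`` bonds has free energy

    G(A) = N * g_mc - B * g_se            [decades]

where ``g_mc`` is the entropic cost of immobilising one monomer (set by its
free concentration, ``g_mc = log10(c0 / c)`` with reference ``c0 = 1 M``) and
``g_se`` the strength of one binding-site pair.  Working in decades means a
barrier difference of ``x`` translates directly into a ``10^x``-fold change of
the spontaneous-nucleation rate.

The irreversibility parameter ``epsilon`` is the log10 ratio of the attachment
rate to the detachment rate for a monomer held by its full half coordination
``n`` bonds:

    epsilon = n * g_se - g_mc        <=>        g_se = (g_mc + epsilon) / n

``epsilon -> 0`` is near-reversible growth; ``epsilon = 2`` means growth is
100x faster than shrinkage at the ribbon/tube front.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "EnergyParams",
    "gse_from_epsilon",
    "epsilon_from_gse",
    "gmc_from_concentration",
]

#: reference (standard-state) concentration for the monomer cost, mol/L
C0 = 1.0


def gmc_from_concentration(concentration: float, c0: float = C0) -> float:
    """Monomer cost in decades: ``g_mc = log10(c0 / c)``. 1 uM -> 6.0."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    return math.log10(c0 / concentration)


def gse_from_epsilon(epsilon: float, n: int, g_mc: float) -> float:
    """Per-bond energy from the irreversibility parameter.

    ``g_se = (g_mc + epsilon) / n``; at ``epsilon = 0`` this recovers the
    near-reversible condition ``g_se = g_mc / n``.
    """
    if n < 1:
        raise ValueError("half coordination n must be >= 1")
    if g_mc <= 0:
        raise ValueError("g_mc must be positive")
    return (g_mc + epsilon) / n


def epsilon_from_gse(g_se: float, n: int, g_mc: float) -> float:
    """Inverse of :func:`gse_from_epsilon`: ``epsilon = n*g_se - g_mc``."""
    if n < 1:
        raise ValueError("half coordination n must be >= 1")
    return n * g_se - g_mc


@dataclass(frozen=True)
class EnergyParams:
    """kTAM energies in decades.

    Attributes
    ----------
    g_mc:
        Monomer (chemical-potential) cost per attached monomer.
    g_se:
        Energy gained per satisfied binding-site pair.
    epsilon:
        Irreversibility, ``n*g_se - g_mc`` for the architecture this parameter
        set belongs to.
    concentration:
        Free monomer concentration in mol/L, if the parameters were derived
        from one (informational; ``g_mc`` is authoritative).
    """

    g_mc: float
    g_se: float
    epsilon: float
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.g_mc <= 0:
            raise ValueError("g_mc must be positive")
        if self.g_se <= 0:
            raise ValueError("g_se must be positive")

    @classmethod
    def for_architecture(
        cls,
        n: int,
        epsilon: float,
        *,
        concentration: float | None = None,
        g_mc: float | None = None,
    ) -> "EnergyParams":
        """Build params for half coordination ``n`` at a given ``epsilon``.

        Exactly one of ``concentration`` and ``g_mc`` must be given.
        """
        if (concentration is None) == (g_mc is None):
            raise ValueError("give exactly one of concentration or g_mc")
        if g_mc is None:
            g_mc = gmc_from_concentration(concentration)
        return cls(
            g_mc=g_mc,
            g_se=gse_from_epsilon(epsilon, n, g_mc),
            epsilon=epsilon,
            concentration=concentration,
        )

    def at_epsilon(self, epsilon: float, n: int) -> "EnergyParams":
        """Same monomer cost, re-derived bond energy at a new ``epsilon``."""
        return replace(
            self, epsilon=epsilon, g_se=gse_from_epsilon(epsilon, n, self.g_mc)
        )
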