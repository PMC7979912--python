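"""Sequence screens: self-structure proxy and base-stacking polarity.

Self-structure is screened with a longest-self-complement proxy: the length
of the longest stem that two non-overlapping subsequences of one strand
could form (a hairpin with any loop size).  Designs reject stems of 6 nt or
more by default.  A hook for an external thermodynamic folder can replace
this proxy where full secondary-structure energies are wanted.

Stacking polarity compares coaxial-stacking strength across the nicked
domain junctions of y-slats versus x-slats, using a nearest-neighbor
nick-stacking free-energy table (kcal/mol, more negative = stronger).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

from .blueprint import SlatBlueprint, SlatRecord

__all__ = [
    "score_self_structure",
    "find_self_structure",
    "STACKING_DG",
    "StackingReport",
    "stacking_polarity",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def score_self_structure(sequence: str) -> int:
    """Length of the longest self-complementary stem in ``sequence``.

    The stem pairs ``seq[i..i+k-1]`` with the reverse complement of
    ``seq[j..j+k-1]`` for some non-overlapping ``i + k <= j``; 0 means no
    base of the strand can pair with any other.  A perfect palindrome of
    length ``2k`` scores ``k``.  O(L^2).
    """
    return find_self_structure(sequence)[0]


def find_self_structure(sequence: str) -> Tuple[int, Tuple[int, int], Tuple[int, int]]:
    """As :func:`score_self_structure`, also locating the two stem arms.

    Returns ``(k, (i0, i1), (j0, j1))`` with half-open arm intervals; arms
    are ``(0, 0)`` when the score is 0.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    L = len(seq)
    best = 0
    arms = ((0, 0), (0, 0))
    # run[i][j]: pairing run closing outward at (i, j): seq[i] pairs seq[j],
    # seq[i+1] pairs seq[j-1], ...; recursion steps inward by two indices
    run = [[0] * L for _ in range(L)]
    for gap in range(1, L):
        for i in range(0, L - gap):
            j = i + gap
            if _COMPLEMENT[seq[i]] == seq[j]:
                inner = run[i + 1][j - 1] if gap >= 3 else 0
                r = inner + 1
                run[i][j] = r
                usable = min(r, (gap + 1) // 2)
                if usable > best:
                    best = usable
                    arms = ((i, i + usable), (j - usable + 1, j + 1))
    return best, arms[0], arms[1]


#: nearest-neighbor nick coaxial-stacking free energies, kcal/mol, for the
#: dinucleotide step read 5'->3'; reverse-complement steps share a value.
STACKING_DG: Dict[str, float] = {
    "AA": -1.04, "TT": -1.04,
    "AC": -2.04, "GT": -2.04,
    "AG": -1.29, "CT": -1.29,
    "AT": -1.27,
    "CA": -0.78, "TG": -0.78,
    "CC": -1.97, "GG": -1.97,
    "CG": -1.44,
    "GA": -1.66, "TC": -1.66,
    "GC": -2.70,
    "TA": -0.12,
}


def _junction_energy(slat: SlatRecord, table: Mapping[str, float]) -> float:
    """Sum of stacking energies at the nicked junctions between domains."""
    total = 0.0
    doms = [d for d in slat.domains if d.kind != "brush"]
    for a, b in zip(doms, doms[1:]):
        if a.sequence is None or b.sequence is None:
            raise ValueError(f"slat {slat.name}: unassigned domain sequence")
        step = (a.sequence[-1] + b.sequence[0]).upper()
        if step not in table:
            raise ValueError(f"stacking table missing step {step!r}")
        total += table[step]
    return total


@dataclass(frozen=True)
class StackingReport:
    x_total: float  # kcal/mol summed over x-slat junctions
    y_total: float
    per_slat: Dict[str, float]

    @property
    def polarity(self) -> float:
        """y minus x total; negative means stacking is stronger along y."""
        return self.y_total - self.x_total

    @property
    def y_stronger(self) -> bool:
        return self.y_total < self.x_total


def stacking_polarity(
    blueprint: SlatBlueprint, stacking_table: Mapping[str, float] | None = None
) -> StackingReport:
    """Compare junction stacking along the y versus x slat classes.

    Designs are expected to stack more strongly in y than in x (so that the
    y-direction seam zips preferentially); ``y_stronger`` flags compliance.
    """
    table = STACKING_DG if stacking_table is None else dict(stacking_table)
    missing = {a + b for a in "ACGT" for b in "ACGT"} - set(table)
    if missing:
        raise ValueError(f"incomplete stacking table; missing {sorted(missing)}")
    per: Dict[str, float] = {}
    x_total = y_total = 0.0
    for slat in blueprint.x_slats:
        e = _junction_energy(slat, table)
        per[slat.name] = e
        x_total += e
    for slat in blueprint.y_slats:
        e = _junction_energy(slat, table)
        per[slat.name] = e
        y_total += e
    return StackingReport(x_total=x_total, y_total=y_total, per_slat=per)
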