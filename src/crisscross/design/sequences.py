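"""Orthogonal sequence assignment for slat blueprints.

Every crossing class gets one duplex sequence (the x-side strand; the y side
is its reverse complement), drawn per domain length from a shared orthogonal
pool.  Pools are sampled from the quaternary parity code (base values
A=0, C=1, G=2, T=3 summing to 0 mod 4), whose members are pairwise Hamming
distance >= 2 *by construction* — necessary because a v6 full design needs
~100 distinct 5-nt domains, close enough to the distance-2 packing bound
that naive rejection sampling stalls.  On top of the code membership, pool
candidates must satisfy a GC-content window and a homopolymer cap.

After assembly, whole slats are re-screened (homopolymer runs across domain
junctions, the self-complement hairpin proxy, y-over-x stacking polarity)
and offending domains are resampled a bounded number of times; an
infeasible constraint set raises with diagnostics rather than looping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Set, Tuple

import numpy as np

from .blueprint import Domain, SlatBlueprint, SlatRecord
from .screens import find_self_structure, revcomp, stacking_polarity

__all__ = ["SequenceConstraints", "assign_sequences", "DesignInfeasible"]

_BASES = "ACGT"
_VAL = {b: i for i, b in enumerate(_BASES)}


class DesignInfeasible(RuntimeError):
    """Sequence constraints could not be satisfied within bounded retries."""


@dataclass(frozen=True)
class SequenceConstraints:
    """Tunable sequence-design rules.

    max_homopolymer : longest allowed single-base run (per slat)
    gc_min, gc_max : GC-fraction window per binding domain
    min_hamming : orthogonality floor between same-length domains
    max_self_stem : reject slats with a self-complementary stem >= this
    require_y_stacking : resample until stacking is stronger along y than x
    max_rounds : bound on whole-design repair rounds
    """

    max_homopolymer: int = 4
    gc_min: float = 0.3
    gc_max: float = 0.7
    min_hamming: int = 2
    max_self_stem: int = 6
    require_y_stacking: bool = True
    max_rounds: int = 300


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _parity_fix(seq: List[str]) -> str:
    """Adjust the last base so the digit sum is 0 mod 4 (code membership)."""
    s = sum(_VAL[b] for b in seq[:-1])
    seq[-1] = _BASES[(-s) % 4]
    return "".join(seq)


class _Pool:
    """Draws orthogonal domain sequences of one length from the parity code."""

    def __init__(self, length: int, constraints: SequenceConstraints):
        self.length = length
        self.c = constraints
        self.used: Set[str] = set()

    def draw(self, rng: np.random.Generator, attempts: int = 5000) -> str:
        c = self.c
        for _ in range(attempts):
            seq = [_BASES[i] for i in rng.integers(0, 4, self.length)]
            s = _parity_fix(seq)
            if s in self.used:
                continue
            if not (c.gc_min <= _gc(s) <= c.gc_max):
                continue
            if _max_run(s) > c.max_homopolymer:
                continue
            if c.min_hamming > 2:
                # code guarantees distance >= 2; larger floors need checking
                if any(
                    sum(a != b for a, b in zip(s, u)) < c.min_hamming
                    for u in self.used
                ):
                    continue
            self.used.add(s)
            return s
        raise DesignInfeasible(
            f"could not draw a new {self.length}-nt domain after {attempts} "
            f"attempts ({len(self.used)} already in use); constraints too tight"
        )

    def release(self, seq: str) -> None:
        self.used.discard(seq)


def _find_max_run(seq: str) -> Tuple[int, int]:
    """(length, start) of the longest homopolymer run."""
    best, best_start = 1, 0
    run, start = 1, 0
    for i in range(1, len(seq)):
        if seq[i] == seq[i - 1]:
            run += 1
        else:
            run, start = 1, i
        if run > best:
            best, best_start = run, start
    return best, best_start


def _offending_classes(slat: SlatRecord, c: SequenceConstraints) -> List[Tuple]:
    """Crossing classes of the domains implicated in a whole-slat violation."""
    seq = slat.sequence
    spans: List[Tuple[int, int]] = []
    run, start = _find_max_run(seq)
    if run > c.max_homopolymer:
        spans.append((start, start + run))
    stem, arm1, arm2 = find_self_structure(seq)
    if stem >= c.max_self_stem:
        spans.extend([arm1, arm2])
    if not spans:
        return []
    classes: List[Tuple] = []
    pos = 0
    for dom in slat.domains:
        lo, hi = pos, pos + dom.length
        if dom.cls is not None and any(lo < b and a < hi for a, b in spans):
            classes.append(dom.cls)
        pos = hi
    return classes


def assign_sequences(
    blueprint: SlatBlueprint,
    rng_seed: int,
    constraints: SequenceConstraints | None = None,
) -> SlatBlueprint:
    """Assign sequences to every domain of a blueprint, reproducibly.

    Returns a new blueprint; raises :class:`DesignInfeasible` (with the
    failing constraint in the message) when bounded retries are exhausted.
    """
    c = constraints or SequenceConstraints()
    rng = np.random.default_rng(rng_seed)
    # separate pools per domain kind: ribbon-binding domains and seed-handle
    # domains are each internally orthogonal (Hamming >= 2); a single global
    # 5-nt pool would exceed the distance-2 code capacity (256 words before
    # composition filters) for full v8-scale designs
    pools: Dict[Tuple[str, int], _Pool] = {}

    def pool(group: str, length: int) -> _Pool:
        key = (group, length)
        if key not in pools:
            pools[key] = _Pool(length, c)
        return pools[key]

    def pool_of(cls: Tuple) -> str:
        return "handle" if cls[0] == "nuc" else "binding"

    # one x-side sequence per crossing class, one per seed-handle domain
    class_seq: Dict[Tuple, str] = {}
    for cls, _a, d, _b, _dy in blueprint.crossings():
        length = blueprint.layout.domain_lengths[d]
        class_seq[cls] = pool("binding", length).draw(rng)
    for slat in blueprint.nuc_y_slats:
        for dom in slat.domains:
            if dom.kind == "seed-handle" and dom.cls not in class_seq:
                class_seq[dom.cls] = pool("handle", dom.length).draw(rng)

    def materialize() -> SlatBlueprint:
        def fill(slat: SlatRecord, y_side: bool) -> SlatRecord:
            doms = []
            for dom in slat.domains:
                if dom.kind == "binding":
                    s = class_seq[dom.cls]
                    doms.append(dom.with_sequence(revcomp(s) if y_side else s))
                elif dom.kind == "seed-handle":
                    doms.append(dom.with_sequence(class_seq[dom.cls]))
                else:
                    doms.append(dom)
            return replace(slat, domains=tuple(doms))

        return replace(
            blueprint,
            x_slats=tuple(fill(s, False) for s in blueprint.x_slats),
            y_slats=tuple(fill(s, True) for s in blueprint.y_slats),
            nuc_y_slats=tuple(fill(s, True) for s in blueprint.nuc_y_slats),
        )

    # repair loop: resample the classes implicated in any whole-slat violation
    for round_no in range(c.max_rounds):
        bp = materialize()
        offending: List[Tuple] = []
        for s in bp.all_slats():
            offending.extend(_offending_classes(s, c))
        if not offending:
            if c.require_y_stacking and not stacking_polarity(bp).y_stronger:
                # resample one class to tilt the junction stacking balance
                cls = list(class_seq)[int(rng.integers(0, len(class_seq)))]
                pool(pool_of(cls), len(class_seq[cls])).release(class_seq[cls])
                class_seq[cls] = pool(pool_of(cls), len(class_seq[cls])).draw(rng)
                continue
            return bp
        # one arm of each stem/run is enough to break it; resample each
        # implicated class with probability 1/2 (at least one per round)
        pending = sorted(set(offending), key=str)
        chosen = [cls for cls in pending if rng.random() < 0.5]
        if not chosen:
            chosen = [pending[int(rng.integers(0, len(pending)))]]
        for cls in chosen:
            old = class_seq[cls]
            pool(pool_of(cls), len(old)).release(old)
            class_seq[cls] = pool(pool_of(cls), len(old)).draw(rng)
    raise DesignInfeasible(
        f"slat-level constraints unsatisfied after {c.max_rounds} repair "
        f"rounds (homopolymer <= {c.max_homopolymer}, self-stem < "
        f"{c.max_self_stem}, y-stacking={c.require_y_stacking})"
    )
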