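#!/usr/bin/env python
"""Nucleation barriers of tile versus slat architectures.

Computes, with the calibrated model at the benchmark conditions (1 uM
monomers, eps = 2): the four barrier heights (ST, HT, CS n=6, CS n=8), the
relative spontaneous-nucleation rates in orders of magnitude, barrier-vs-
epsilon curves for all four architectures, and the seeded versus unseeded
landscape for v6 slats.

Finding: square- and hexagonal-tile tubes retain barriers of only 10.8 and
13.9 decades under fast growth, while crisscross slats hold 34.4 (n=6) and
45.8 (n=8) — spontaneous nucleation of v6 slats is ~24 orders of magnitude
slower than square tiles at the same conditions, because the slat barrier
falls with slope -n per decade of irreversibility only from a much larger
near-reversible value.

Writes results/barriers.json and results/barrier_curves.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from crisscross.calibration import (
    BENCHMARK_EPSILON,
    barrier_table,
    benchmark_architecture,
    benchmark_params,
)
from crisscross.io import write_json
from crisscross.landscape import (
    barrier_vs_epsilon,
    critical_nucleus,
    landscape_with_seed,
    relative_nucleation_rate,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    table = barrier_table()
    gaps = {
        "CS6_vs_ST_decades": relative_nucleation_rate(
            table["CS6"].barrier, table["ST"].barrier
        ),
        "CS8_vs_ST_decades": relative_nucleation_rate(
            table["CS8"].barrier, table["ST"].barrier
        ),
        "HT_vs_ST_decades": relative_nucleation_rate(
            table["HT"].barrier, table["ST"].barrier
        ),
    }
    print("barrier heights at the benchmark (decades):")
    for label, row in table.items():
        print(
            f"  {label:>4}: {row.barrier:6.2f}  "
            f"(critical nucleus N={row.critical_size}, B={row.bonds_at_critical})"
        )
    print(
        "relative spontaneous-nucleation rates: "
        f"CS6 {gaps['CS6_vs_ST_decades']:.1f} and CS8 "
        f"{gaps['CS8_vs_ST_decades']:.1f} decades slower than ST; "
        f"HT only {gaps['HT_vs_ST_decades']:.1f}"
    )

    rows = []
    for label in ("ST", "HT", "CS6", "CS8"):
        arch = benchmark_architecture(label)
        p0 = benchmark_params(label, 0.0)
        for pt in barrier_vs_epsilon(arch, p0, np.linspace(0.0, 3.0, 61)):
            rows.append(
                {
                    "architecture": label,
                    "epsilon": pt.epsilon,
                    "barrier": pt.barrier,
                    "critical_size": pt.critical_size,
                }
            )
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "barrier_curves.csv", index=False)

    cs6 = benchmark_architecture("CS6")
    p = benchmark_params("CS6", BENCHMARK_EPSILON)
    seeded = landscape_with_seed(cs6, p)
    unseeded = critical_nucleus(cs6, p)
    print(
        f"seeded pathway max {max(seeded.G_profile):.1f} vs unseeded barrier "
        f"{unseeded.barrier:.1f} decades: the seed pre-pays the entire barrier"
    )

    write_json(
        {
            "barriers": {k: v for k, v in table.items()},
            "gaps": gaps,
            "seeded_profile": list(seeded.G_profile),
            "unseeded_profile": list(unseeded.G_profile),
        },
        OUT / "barriers.json",
    )
    print(f"-> {OUT / 'barriers.json'}, {OUT / 'barrier_curves.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
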