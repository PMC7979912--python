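# Methods

## Assembly model and energy bookkeeping

All architectures are scored with the kinetic Tile Assembly Model. An
assembly of `N` monomers and `B` satisfied binding-site pairs has free
energy `G = N·g_mc − B·g_se`, in decades (log10 units) so that barrier
differences read directly as orders of magnitude of spontaneous-nucleation
rate. `g_mc = log10(c0/c)` with reference `c0 = 1 M` (1 µM → 6.0 decades,
before the standard-state offsets described under *Calibration*). The
irreversibility `ε = n·g_se − g_mc` is the log10 attachment:detachment
ratio for a monomer held by its full half coordination `n`; `ε → 0` is
near-reversible growth and `ε = 2` the fast-growth benchmark (100:1).

Bond topologies:

* **ST** — square lattice wrapped to a cylinder (tube), 4 neighbours,
  `n = 2`;
* **HT** — triangular lattice on a cylinder, 6 neighbours, `n = 3`;
* **CS** — crisscross slats on two perpendicular rails; x-slat `i` crosses
  y-slats `i..i+2n−1` (one-rail stagger), so every slat has `2n` specific
  partners, and an arriving slat at a complete ribbon front always finds
  exactly `n` of them in place.

## Critical nuclei and the two barrier readings

The minimal-barrier pathway (the attachment order minimizing the running
maximum of `G`) is found exactly by best-first search — Dijkstra where the
path cost is the peak `G` so far — over canonicalized connected states
(translations, tube rotations and the slat x↔y mirror are merged). An
independent oracle, a layered dynamic program over *all* connected
attachment orders on raw occupancy sets, is used in the tests to confirm
the search exactly on assemblies of up to 8 monomers for every
architecture. For slats the analytic *staircase* pathway (alternating
perpendicular additions; the k-th pair attaches with `k−1` and `k` bonds)
is used directly and is verified minimal against the exact search.

A `Landscape` reports two numbers:

* `barrier` — the free energy **of the critical nucleus**, whose
  composition is fixed at its near-reversible (`ε → 0`) value and whose
  `G` is evaluated at the working `ε`. For CS this nucleus is the complete
  `n × n` junction (`N = 2n`, `B* = n²`), giving
  `barrier = 2n·g_mc − n²·g_se = n·(g_mc − ε)` and the exact slope law
  `d(barrier)/dε = −B*/n = −n`. For the tubes at the benchmark the nucleus
  is a ring plus one tile and coincides with the pathway maximum.
* `peak` — `max(G_profile)` along the minimal pathway at the working
  conditions. For CS at `ε > 0` the staircase transiently overshoots the
  junction (its early slats attach with fewer than `n` bonds while the
  late ones attach with more), so `peak ≥ barrier`; the overshoot is ~2.8
  decades for v6 at the benchmark. The reported nucleation barrier is the
  nucleus free energy, matching how barrier curves are conventionally
  drawn for these systems; both numbers are exposed.

A size-capped search cannot by itself certify an `ε → 0` tube barrier at
large circumference `m`: compact flat patches reach any capped size with
peak `≈ g_mc·(w+h)/2`, below the ring barrier, yet cannot grow without
wrapping. Closed forms are therefore used for near-reversible tube
barriers — ST: `g_mc·(m+1)/2`, HT: `g_mc·(2m+1)/3`, valid for `m ≥ 3` —
and verified against the exact search at small `m`, where wrapping is
reached within the search horizon.

## Calibration

Relative barriers, the ordering and the slope law follow from the model
alone. The *absolute* barrier scale additionally contains a standard-state
offset of the monomer chemical potential (rotational/conformational
restriction on binding), which plausibly differs between compact tiles and
long floppy ssDNA slats, plus one topology constant for the tubes (their
circumference). These were calibrated once against the reference barrier
heights for the benchmark (1 µM, ε = 2): 10.8 (ST), 13.9 (HT), 34.4
(CS n=6), 45.8 (CS n=8) decades.

* Tubes: circumference 3 (the smallest non-degenerate tube) and a tile
  monomer cost of `g_mc = 7.4`, solved by inverting the exact ST barrier
  numerically against 10.8. The HT value is **not fitted**: with the same
  two constants the model yields 13.93 → 13.9, an out-of-sample check that
  the lattice/energy form is right.
* Slats: `g_mc = 7.72917`, the least-squares solution of
  `n·(g_mc − 2) = {34.4, 45.8}` over `n = {6, 8}` (the two values agree to
  0.017, so a single constant reproduces both: 34.375 → 34.4,
  45.833 → 45.8).

The derived gaps are then 23.6 decades (CS6 − ST) and 3.13 → 3.1 (HT − ST).
The `calibrate_tiles`/`calibrate_slats` functions re-derive these constants
from the model at run time and the shipped values are checked against them
in the tests.

## Architecture matching at ε → 0

At `ε → 0` the constraint `ε = n·g_se − g_mc` pins `g_se = g_mc/n`, so
matching a target architecture to a reference barrier solves for the
target's `g_mc` (continuous) and, for tubes, an integer circumference
chosen so the solved `g_mc` lies closest to the reference's. Matches are
exact by construction; small-circumference matches are re-verified through
the exhaustive search in the tests.

## Seeded landscapes

The seed is modeled energetically, not structurally: a pre-formed edge
presenting `2n` handle sites captures the `2n` nucleating y-slats at zero
net cost (the seed pre-pays the nucleation barrier), after which every
front addition makes `n` bonds, `ΔG = −ε` per slat. The seeded profile is
therefore flat through nucleator capture and strictly downhill afterwards,
never exceeding 0 — against an unseeded barrier of 34.4 decades for v6.

## Stochastic growth model

Each seeded ribbon elongates at intrinsic velocity `v` (nm/s) while in a
*growing* state, pauses in a *stalled* state (rates `k_stall`, `k_resume`;
the two-state pause process starts at stationarity), and stops permanently
at `k_term`, which acts in both states (phenomenology for growth-front
poisoning, e.g. by truncated slats). These choices make the mean length

```
E[L(t)] = (v_eff/k_term)(1 − e^(−k_term·t)),   v_eff = v·k_resume/(k_resume+k_stall)
```

*exact* rather than asymptotic, so the simulation/analytic agreement test
(n = 10⁴ ribbons, 3 standard errors) is a sharp check. The returned
standard deviation is exact for `k_stall = 0` and slightly understates the
spread otherwise. Lengths convert to monomer kinetics via `δ = 1.5 nm` of
ribbon extension per slat; `k_on = v_eff/(δ·[slat])`.

Fitting: weighted least squares of the mean-length solution to
per-timepoint means (weights = standard error of the mean), with
`(v_eff, k_term)` bounded non-negative. Confidence intervals use the
case-resampling bootstrap within timepoints (200 resamples, seed 1729 by
default) with the **basic** (reflected) interval, which corrects the small
upward skew of the nonlinear estimates; at study scale (150 ribbons × 5
timepoints, 10 % noise) both parameters recover with < 5 % bias and ≥ 90 %
coverage over 100 replicates. `J` (spontaneous nucleation, mol/L/s) is
fitted only when unseeded ribbon counts are supplied, as a zero-intercept
slope. The polydispersity index is `PDI = E[L²]/E[L]²` (weight-average over
number-average; 1 = monodisperse, 2 = exponential).

## Gel quantification

Conversions are exact chains: slats per ribbon `L/δ`; ribbons to molar via
Avogadro and the reaction volume; ribbon mass via slat length (default
66 nt including brush) × 330 g/mol/nt. Unseeded ribbon concentration is
read off a single seeded control lane (intensity assumed linear in loaded
ribbon mass; near-complete seed conversion, fraction 1.0 by default) with
loaded-volume correction; dividing by the nucleation-phase duration of the
two-step protocol gives mol/L/s. Any lane below the detection floor
(200 fM-equivalent, ≈ 65 pg ssDNA per lane for 5-µm v6 ribbons) is
*censored*: it yields only an upper bound, never a point estimate.
Reporting rounds to 2 significant figures for counts and 1 for rates;
full precision is kept internally.

## Synthetic data: what it does and does not emulate

The generator produces ground-truth-labeled datasets with the statistical
structure the analyses assume. TEM length samples are **cross-sectional**
(each timepoint draws an independent set of ribbons, as when different
micrograph fields are traced — this matters: longitudinal sampling would
correlate the timepoint means and invalidate the bootstrap), with
mean-one multiplicative lognormal measurement noise (default sd 5 %, a
placeholder for the unreported tracing error, exposed in the API), a
minimum measurable length of 50 nm (objects shorter than that are not
counted; the tracing protocol keeps recording until its target count of
130–168 measurable filaments), and per-condition sample sizes drawn from
130–168. Gel lanes get multiplicative Gaussian intensity noise (2 %) and
pass through the same censoring floor as real lanes.

Preset conditions: `optimal_fast` (hot, fast growth: `v = 0.75 nm/s` from
an on-rate of 0.5×10⁶ /M/s at 1 µM slats, stalled fraction 2/3 so
`v_eff = 0.25 nm/s`, `k_term = 2×10⁻⁵ /s`; mean ≈ 0.9 µm at 1 h and > 4 µm
by 8 h, saturating) and `suboptimal_slow` (cool: `v = 0.12`,
`k_term = 5×10⁻⁶`; ≈ 0.14 µm at 1 h, ≈ 3 µm by 25 h, near-linear).
`unseeded_nucleation` drives the two-step gel protocol at `J = 2 aM/s`
over a 100-h nucleation phase — about an order of magnitude above the
detection floor, so the recovery round trip is exercised on a measurable
lane while `J = 0` exercises the censored path. Passing tests on these
data show the estimators are correct *under the model's assumptions*; they
do not validate the model against entanglement, aggregation, field-of-view
bias, or temperature dependence, none of which are emulated.

## Sequence design

Slat cores are arrays of `2n` half-turn domains of 5 or 6 nt; every window
of four consecutive domains sums to two full turns (21 nt at 10.5 bp/turn,
22 at 11.0; patterns for 10.0/11.5/12.0 exist but are unused by the named
variants). y-slat domain lengths run in reverse x order so every crossing
pairs equal-length domains. Sequence identity repeats with period `2n`
(`full`), `n` or `n/2` roles; the crossing map pairs x-role `a`, domain `d`
with y-role `(a+d) mod r`, domain `2n−1−d` — a bijection, checked by brute
force. The `2n` nuc-y species carry unique seed-handle domains on their
seed-proximal half and the standard periodic y domains distally.

Orthogonality uses pools drawn from the quaternary parity code (digit sum
≡ 0 mod 4), whose members are pairwise Hamming ≥ 2 *by construction*; this
matters because a full v6 design needs ~108 distinct 5-nt binding domains,
close to the distance-2 packing bound where rejection sampling stalls.
Binding domains and seed-handle domains use separate pools (a single
global 5-nt pool cannot hold a full v8-scale design: the code caps at 256
words before composition filters); cross-pool interactions are covered by
the whole-slat screens instead. Per-domain rules: GC fraction in
[0.3, 0.7], homopolymer run ≤ 4. Whole-slat screens after assembly:
homopolymer runs across junctions, and a longest-self-complement hairpin
proxy (the longest stem two non-overlapping subsequences could form,
computed by an O(L²) dynamic program verified against an O(L⁴) brute
force), rejecting stems ≥ 6 nt; violations trigger targeted resampling of
the implicated domain classes, bounded, with diagnostics on failure. A
full v8 design at 10.5 bp/turn genuinely exceeds the 5-nt pool capacity at
the default GC window and correctly raises; it becomes feasible at
GC ∈ [0.2, 0.8]. The proxy deliberately replaces a thermodynamic folder;
the screen functions accept arbitrary sequences so an external folder can
be slotted in.

Base-stacking polarity sums a published-style nearest-neighbor
nick-stacking table (kcal/mol) over the nicked inter-domain junctions of
y- versus x-slats; designs are resampled until stacking is stronger along
y (the direction that crosses over every half turn), matching the design
intent for well-behaved variants. Decorations: poly-T brushes (edge
passivation against blunt-end stacking aggregation; annotated non-binding
and added after screening), 3- or 4-nt sticky ends (one ribbon edge gets
the overhang, the other its reverse complement; with a tightly-coiled
11.0 bp/turn layout closure is annotated constant-diameter, with a
shifted-phase 10.5 layout varying-diameter), and blockers (exact reverse
complements of chosen nuc-y cores). Genome nucleators tile a 190-nt window
of a supplied ssDNA sequence into six near-equal consecutive blocks
(4×32 + 2×31 nt — 190 is not divisible by 6), each slat binding one block
by reverse complement and presenting six v6 handle domains. Coordinates
are 0-based half-open; all strands are written 5′→3′; identical
(config, seed) pairs export byte-identical FASTA and 96-well column-major
plate CSVs.

## Known limitations

* The kTAM comparison is quasi-equilibrium bookkeeping over attachment
  pathways, not a kinetic simulation; attempt frequencies and off-pathway
  aggregation are outside the model.
* The two standard-state offsets (tiles vs slats) are calibrated
  constants, not predictions; only barrier differences *within* a family
  are parameter-free.
* Stalling and termination are phenomenological; the discrete per-slat
  stalling variant is not implemented.
* The self-structure proxy scores stem length only (no loop penalties or
  stacking thermodynamics), and decorated slats are screened as cores —
  poly-T brushes can form weak poly-A stems that the screen intentionally
  ignores.
* Temperature appears only through preset labels and rate values, never
  mechanistically.
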