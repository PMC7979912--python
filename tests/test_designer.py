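"""Slat designer: layouts, crossing map, sequences, screens, exports."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisscross.design import (
    SequenceConstraints,
    assign_sequences,
    build_blueprint,
    decorate,
    design_genome_nucleators,
    export_sequences,
    generate_domain_layout,
    score_self_structure,
    stacking_polarity,
    twist_report,
)
from crisscross.design.blueprint import Domain, SlatRecord
from crisscross.design.screens import STACKING_DG, revcomp
from crisscross.design.sequences import DesignInfeasible


class TestDomainLayout:
    def test_v6_layout(self):
        lay = generate_domain_layout(6, 10.5)
        assert lay.num_domains == 12
        assert lay.total_length == 63
        assert set(lay.four_window_sums()) == {21}

    def test_v8_underwound_layout(self):
        lay = generate_domain_layout(8, 11.0)
        assert lay.domain_lengths == (5, 6) * 8
        assert lay.total_length == 88
        assert set(lay.four_window_sums()) == {22}

    def test_unattainable_twist_rejected(self):
        with pytest.raises(ValueError):
            generate_domain_layout(6, 10.3)

    @given(
        st.integers(2, 10),
        st.sampled_from([10.0, 10.5, 11.0, 11.5, 12.0]),
        st.integers(0, 3),
    )
    @settings(max_examples=40)
    def test_window_sum_invariant(self, n, bp, phase):
        lay = generate_domain_layout(n, bp, phase)
        assert set(lay.four_window_sums()) == {int(round(2 * bp))}
        assert all(d in (5, 6) for d in lay.domain_lengths)

    def test_twist_classes(self):
        assert twist_report(generate_domain_layout(6, 10.5)).coil_class == "flat"
        assert (
            twist_report(generate_domain_layout(8, 10.5, phase=1)).coil_class
            == "loose-coil"
        )
        assert twist_report(generate_domain_layout(8, 11.0)).coil_class == "tight-coil"


class TestBlueprint:
    def test_v6_full_counts(self):
        bp = build_blueprint(generate_domain_layout(6, 10.5), "full")
        assert len(bp.nuc_y_slats) == 12
        assert len(bp.x_slats) == len(bp.y_slats) == 12

    def test_v8_half_n_pairs_repeat(self):
        bp = build_blueprint(generate_domain_layout(8, 10.5), "half_n_pairs")
        assert bp.repeat == 4

    def test_half_n_pairs_needs_even_n(self):
        with pytest.raises(ValueError):
            build_blueprint(generate_domain_layout(3, 10.5), "half_n_pairs")

    @pytest.mark.parametrize("mode", ["full", "n_pairs", "half_n_pairs"])
    def test_crossing_map_bijective(self, mode):
        bp = build_blueprint(generate_domain_layout(6, 10.5), mode)
        seen_x, seen_y = set(), set()
        for cls, a, d, b, dy in bp.crossings():
            assert (a, d) not in seen_x
            assert (b, dy) not in seen_y
            seen_x.add((a, d))
            seen_y.add((b, dy))
        w = bp.layout.num_domains
        assert len(seen_x) == bp.repeat * w
        assert seen_y == {(b, dy) for b in range(bp.repeat) for dy in range(w)}

    def test_crossing_lengths_agree(self):
        bp = build_blueprint(generate_domain_layout(6, 10.5))
        ys = {s.index: s for s in bp.y_slats}
        xs = {s.index: s for s in bp.x_slats}
        for cls, a, d, b, dy in bp.crossings():
            assert xs[a].domains[d].length == ys[b].domains[dy].length

    def test_x_slats_do_not_cross_over(self):
        bp = build_blueprint(generate_domain_layout(6, 10.5))
        assert all(not s.crossover_every_half_turn for s in bp.x_slats)
        assert all(s.crossover_every_half_turn for s in bp.y_slats)


class TestAssignSequences:
    def test_deterministic(self, v6_blueprint):
        again = assign_sequences(
            build_blueprint(generate_domain_layout(6, 10.5), "full"), rng_seed=42
        )
        for a, b in zip(v6_blueprint.all_slats(), again.all_slats()):
            assert a.sequence == b.sequence

    def test_all_crossings_complementary(self, v6_blueprint):
        xs = {s.index: s for s in v6_blueprint.x_slats}
        ys = {s.index: s for s in v6_blueprint.y_slats}
        for cls, a, d, b, dy in v6_blueprint.crossings():
            assert ys[b].domains[dy].sequence == revcomp(xs[a].domains[d].sequence)

    def test_constraints_hold_on_every_slat(self, v6_blueprint):
        c = SequenceConstraints()
        for slat in v6_blueprint.all_slats():
            seq = slat.sequence
            assert all(
                seq[i : i + c.max_homopolymer + 1]
                != seq[i] * (c.max_homopolymer + 1)
                for i in range(len(seq))
            )
            assert score_self_structure(seq) < c.max_self_stem

    def test_orthogonality_floor(self, v6_blueprint):
        by_len = {}
        for cls, a, d, _b, _dy in v6_blueprint.crossings():
            seq = {s.index: s for s in v6_blueprint.x_slats}[a].domains[d].sequence
            by_len.setdefault(len(seq), set()).add(seq)
        for seqs in by_len.values():
            for u, v in itertools.combinations(seqs, 2):
                assert sum(a != b for a, b in zip(u, v)) >= 2

    def test_infeasible_raises_with_diagnostics(self):
        bp = build_blueprint(generate_domain_layout(8, 10.5), "full")
        with pytest.raises(DesignInfeasible):
            assign_sequences(bp, rng_seed=1)  # exceeds 5-nt pool capacity


class TestSelfStructure:
    def test_poly_a_scores_zero(self):
        assert score_self_structure("A" * 20) == 0

    def test_palindrome_scores_half(self):
        assert score_self_structure("ACGTGCACGT") >= 5

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            score_self_structure("ACGN")
        with pytest.raises(ValueError):
            score_self_structure("")

    def test_agrees_with_brute_force(self):
        def brute(seq):
            L, best = len(seq), 0
            for k in range(1, L // 2 + 1):
                for i in range(L - k + 1):
                    for j in range(i + k, L - k + 1):
                        if seq[j : j + k] == revcomp(seq[i : i + k]):
                            best = max(best, k)
            return best

        rng = random.Random(1)
        for _ in range(200):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 30)))
            assert score_self_structure(s) == brute(s)


class TestStacking:
    def _toy(self, xseq, yseq):
        def slat(name, role, seqs):
            return SlatRecord(
                name=name,
                role=role,
                index=0,
                domains=tuple(
                    Domain(length=len(s), kind="binding", sequence=s) for s in seqs
                ),
            )

        bp = build_blueprint(generate_domain_layout(1, 10.5))
        object.__setattr__(bp, "x_slats", (slat("x", "x", xseq),))
        object.__setattr__(bp, "y_slats", (slat("y", "y", yseq),))
        return bp

    def test_symmetric_toy_has_zero_polarity(self):
        bp = self._toy(["AAAAA", "TTTTT"], ["AAAAA", "TTTTT"])
        rep = stacking_polarity(bp)
        assert rep.polarity == 0.0
        assert not rep.y_stronger

    def test_hand_computed_two_junction_sum(self):
        # x: AAAAA|CCCCC junction step AC; GGGGG|TTTTT junction step GT
        bp = self._toy(["AAAAA", "CCCCC", "GGGGG", "TTTTT"], ["AAAAA", "TTTTT"])
        rep = stacking_polarity(bp)
        expected_x = STACKING_DG["AC"] + STACKING_DG["CG"] + STACKING_DG["GT"]
        assert rep.x_total == pytest.approx(expected_x)
        assert rep.y_total == pytest.approx(STACKING_DG["AT"])

    def test_designed_blueprint_passes_polarity(self, v6_blueprint):
        assert stacking_polarity(v6_blueprint).y_stronger

    def test_incomplete_table_rejected(self, v6_blueprint):
        with pytest.raises(ValueError):
            stacking_polarity(v6_blueprint, {"AA": -1.0})


class TestDecorate:
    def test_brush_appended_and_annotated(self, v6_blueprint):
        dec = decorate(v6_blueprint, brush_length=8, brush_end="3")
        for s in dec.x_slats + dec.y_slats:
            assert s.domains[-1].kind == "brush"
            assert s.domains[-1].sequence == "T" * 8
            assert s.core_length == 63
        assert dec.decorations["brush"]["length"] == 8

    def test_zero_brush_is_annotation_only(self, v6_blueprint):
        dec = decorate(v6_blueprint, brush_length=0)
        for a, b in zip(dec.x_slats, v6_blueprint.x_slats):
            assert a.sequence == b.sequence
        assert dec.decorations["brush"] is None

    def test_sticky_ends_pair_across_edge(self):
        lay = generate_domain_layout(8, 11.0)
        bp = assign_sequences(build_blueprint(lay, "n_pairs"), rng_seed=5)
        dec = decorate(bp, sticky_end_length=3, rng_seed=9)
        top = dec.y_slats[0].domains[0]
        bottom = dec.x_slats[0].domains[-1]
        assert top.kind == bottom.kind == "sticky"
        assert bottom.sequence == revcomp(top.sequence)
        assert dec.decorations["sticky_end"]["closure"] == "closed-tube"
        assert dec.decorations["sticky_end"]["diameter"] == "constant"

    def test_loose_coil_closes_with_varying_diameter(self):
        lay = generate_domain_layout(8, 10.5, phase=1)
        bp = assign_sequences(build_blueprint(lay, "n_pairs"), rng_seed=5)
        dec = decorate(bp, sticky_end_length=4, rng_seed=9)
        assert dec.decorations["sticky_end"]["diameter"] == "varying"

    def test_invalid_sticky_length(self, v6_blueprint):
        with pytest.raises(ValueError):
            decorate(v6_blueprint, sticky_end_length=2)

    def test_blocker_is_exact_reverse_complement(self, v6_blueprint):
        dec = decorate(v6_blueprint, blockers=[1])
        blocker = dec.extra_slats[-1]
        target = {s.index: s for s in v6_blueprint.nuc_y_slats}[1]
        assert blocker.sequence == revcomp(target.sequence)


class TestGenomeNucleators:
    GENOME = "".join(
        random.Random(99).choice("ACGT") for _ in range(600)
    )

    def test_tiling_reconstructs_window(self, v6_blueprint):
        slats = design_genome_nucleators(self.GENOME, 37, blueprint=v6_blueprint)
        assert len(slats) == 6
        recon = "".join(revcomp(s.domains[0].sequence) for s in slats)
        assert recon == self.GENOME[37 : 37 + 190]
        # equivalently: reverse-ordered binding domains = revcomp(window)
        cat = "".join(s.domains[0].sequence for s in reversed(slats))
        assert cat == revcomp(self.GENOME[37 : 37 + 190])

    def test_handles_present_v6_y_recruiting_domains(self, v6_blueprint):
        slats = design_genome_nucleators(self.GENOME, 0, blueprint=v6_blueprint)
        for k, s in enumerate(slats):
            handles = [d.sequence for d in s.domains[1:]]
            expect = [
                d.sequence
                for d in v6_blueprint.x_slats[k].domains[6:]
                if d.kind == "binding"
            ]
            assert handles == expect

    def test_window_out_of_range(self):
        with pytest.raises(ValueError):
            design_genome_nucleators(self.GENOME, 500)
        with pytest.raises(ValueError):
            design_genome_nucleators(self.GENOME, -1)

    def test_ambiguous_bases_rejected(self):
        g = self.GENOME[:100] + "N" + self.GENOME[101:]
        with pytest.raises(ValueError):
            design_genome_nucleators(g, 60)


class TestExport:
    def test_fasta_round_trip_and_counts(self, v6_blueprint, tmp_path):
        from Bio import SeqIO

        paths = export_sequences(v6_blueprint, tmp_path)
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(paths["fasta"]), "fasta")}
        assert len(records) == 36  # 12 nuc-y + 12 x + 12 y
        for slat in v6_blueprint.all_slats():
            assert records[slat.name] == slat.sequence

    def test_plate_overflow(self, tmp_path):
        import pandas as pd

        lay = generate_domain_layout(8, 11.0)
        bp = assign_sequences(build_blueprint(lay, "full"), rng_seed=3)
        paths = export_sequences(bp, tmp_path, repeat_units=3)
        df = pd.read_csv(paths["plate"])
        # 16 nuc-y + 3*(16+16) = 112 wells -> 2 plates, column-major order
        assert len(df) == 112
        assert df["plate"].max() == 2
        assert list(df["well"][:3]) == ["A1", "B1", "C1"]
        assert df.groupby("plate").size().max() <= 96

    def test_byte_identical_exports(self, v6_blueprint, tmp_path):
        p1 = export_sequences(v6_blueprint, tmp_path / "a")
        p2 = export_sequences(v6_blueprint, tmp_path / "b")
        assert p1["fasta"].read_bytes() == p2["fasta"].read_bytes()
        assert p1["plate"].read_bytes() == p2["plate"].read_bytes()

    def test_unassigned_sequences_rejected(self, tmp_path):
        bp = build_blueprint(generate_domain_layout(6, 10.5))
        with pytest.raises(ValueError):
            export_sequences(bp, tmp_path)
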