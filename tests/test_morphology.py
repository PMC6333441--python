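"""Morphology: generation invariants, discretization, SWC round trips, queries."""

import math

import numpy as np
import pytest

from piriform.morphology import (
    DendriticLocation,
    GeneratorParams,
    Morphology,
    MorphologyError,
    SWCError,
    Section,
    branch_relation,
    classify_zone,
    discretize,
    generate_synthetic_morphology,
    morphology_summary,
    path_distance,
    read_swc,
    write_swc,
)


def single_cable(length=100.0, diam=1.0, soma_area=829.0) -> Morphology:
    return Morphology(
        (Section(0, -1, length, diam, diam, 0, 0),), soma_area=soma_area
    )


class TestGenerator:
    @pytest.mark.parametrize("seed", range(100))
    def test_invariants_hold_for_any_seed(self, seed):
        """Total length, positivity, extent and acceptance-band compartment
        count hold across 100 generator seeds."""
        m = generate_synthetic_morphology(seed=seed)
        assert 2238.0 - 1e-6 <= m.total_length <= 2516.0 + 1e-6
        assert all(s.length > 0 and s.diam_prox > 0 for s in m.sections)
        assert m.n_primary() >= 2
        extent = max(
            m.section_path_start(t) + m.sections[t].length
            for t in m.terminal_sections()
        )
        assert extent >= 350.0 - 1e-6
        assert 400 <= discretize(m).n_comp <= 650

    def test_fixed_seed_is_deterministic(self):
        a = generate_synthetic_morphology(seed=7)
        b = generate_synthetic_morphology(seed=7)
        assert a == b

    def test_soma_area_matches_parameter(self):
        m = generate_synthetic_morphology(GeneratorParams(soma_area=829.0), seed=1)
        assert m.soma_area == pytest.approx(829.0)
        # the equivalent cylinder with length == diameter has that lateral area
        d = m.soma_diameter
        assert math.pi * d * d == pytest.approx(829.0)

    def test_unsatisfiable_constraints_raise(self):
        with pytest.raises(MorphologyError):
            generate_synthetic_morphology(
                GeneratorParams(total_length_range=(500.0, 600.0)), seed=0
            )
        with pytest.raises(MorphologyError):
            generate_synthetic_morphology(GeneratorParams(n_primary=1), seed=0)


class TestDiscretize:
    @pytest.mark.parametrize(
        "length,max_seg,expected",
        [(19.0, 19.0, 1), (40.0, 19.0, 3), (100.0, 4.6, 22)],
    )
    def test_compartment_count_is_ceiling(self, length, max_seg, expected):
        grid = discretize(single_cable(length=length), max_seg)
        assert grid.section_ncomp[0] == expected

    def test_compartment_lengths_sum_to_section_length(self):
        m = generate_synthetic_morphology(seed=3)
        grid = discretize(m)
        for sec in m.sections:
            tot = sum(
                grid.compartments[grid.section_offset[sec.index] + k].length
                for k in range(grid.section_ncomp[sec.index])
            )
            assert tot == pytest.approx(sec.length)
            assert all(
                grid.compartments[grid.section_offset[sec.index] + k].length
                <= grid.max_seg_len + 1e-9
                for k in range(grid.section_ncomp[sec.index])
            )

    def test_topology_matches_section_tree(self):
        m = generate_synthetic_morphology(seed=3)
        grid = discretize(m)
        for sec in m.sections:
            first = grid.section_offset[sec.index]
            up = grid.parent_comp[first]
            if sec.parent == -1:
                assert up == 0  # attaches to the soma
            else:
                parent_last = (
                    grid.section_offset[sec.parent]
                    + grid.section_ncomp[sec.parent] - 1
                )
                assert up == parent_last

    def test_rediscretization_is_stable(self):
        m = generate_synthetic_morphology(seed=5)
        a = discretize(m, 4.6)
        b = discretize(m, 4.6)
        assert a.section_ncomp == b.section_ncomp

    def test_invalid_seg_len_rejected(self):
        with pytest.raises(ValueError):
            discretize(single_cable(), 0.0)


class TestQueries:
    def test_path_distance_examples(self):
        # parent ends 200 µm out; midpoint of a 60 µm child sits at 230 µm
        m = Morphology(
            (
                Section(0, -1, 200.0, 2.0, 1.0, 0, 0),
                Section(1, 0, 60.0, 1.0, 0.8, 1, 0),
            ),
            soma_area=829.0,
        )
        grid = discretize(m)
        assert path_distance(grid, DendriticLocation(0, 0.0)) == pytest.approx(0.0)
        assert path_distance(grid, DendriticLocation(0, 1.0)) == pytest.approx(200.0)
        assert path_distance(grid, DendriticLocation(1, 0.5)) == pytest.approx(230.0)

    def test_path_distance_monotone_to_tip(self):
        m = generate_synthetic_morphology(seed=2)
        grid = discretize(m)
        t = m.terminal_sections()[0]
        arcs = np.linspace(0, 1, 7)
        d = [path_distance(grid, DendriticLocation(t, a)) for a in arcs]
        assert all(x < y for x, y in zip(d, d[1:]))

    def test_unknown_section_raises(self):
        grid = discretize(single_cable())
        with pytest.raises(KeyError):
            path_distance(grid, DendriticLocation(99, 0.5))

    @pytest.mark.parametrize(
        "dist,zone", [(80.0, "perisomatic"), (160.0, "IC"), (280.0, "LOT")]
    )
    def test_zone_classification(self, dist, zone):
        grid = discretize(single_cable(length=400.0))
        assert classify_zone(grid, DendriticLocation(0, dist / 400.0)) == zone

    def test_zone_bands_are_contiguous(self):
        grid = discretize(single_cable(length=500.0))
        zones = [
            classify_zone(grid, DendriticLocation(0, a))
            for a in np.linspace(0.0, 1.0, 201)
        ]
        # once a zone is left it never recurs: perisomatic -> IC -> LOT
        order = {"perisomatic": 0, "IC": 1, "LOT": 2}
        codes = [order[z] for z in zones]
        assert codes == sorted(codes)


class TestBranchRelation:
    @pytest.fixture()
    def morph(self):
        return generate_synthetic_morphology(seed=4)

    def test_same_on_one_terminal_section(self, morph):
        t = morph.terminal_sections()[0]
        a, b = DendriticLocation(t, 0.3), DendriticLocation(t, 0.8)
        assert branch_relation(morph, a, b) == "same"

    def test_ancestor_path_is_same(self, morph):
        t = morph.terminal_sections()[0]
        parent = morph.sections[t].parent
        assert (
            branch_relation(
                morph, DendriticLocation(parent, 0.5), DendriticLocation(t, 0.5)
            )
            == "same"
        )

    def test_sister_and_different(self, morph):
        by_root = {}
        for t in morph.terminal_sections():
            by_root.setdefault(morph.sections[t].root_id, []).append(t)
        roots = sorted(by_root)
        t1, t2 = by_root[roots[0]][:2]
        d1 = by_root[roots[1]][0]
        assert branch_relation(
            morph, DendriticLocation(t1, 0.5), DendriticLocation(t2, 0.5)
        ) == "sister"
        assert branch_relation(
            morph, DendriticLocation(t1, 0.5), DendriticLocation(d1, 0.5)
        ) == "different"

    def test_symmetry(self, morph):
        locs = [DendriticLocation(t, 0.5) for t in morph.terminal_sections()[:6]]
        for a in locs:
            for b in locs:
                assert branch_relation(morph, a, b) == branch_relation(morph, b, a)


class TestSWC:
    def test_three_point_toy_file(self, tmp_path):
        path = tmp_path / "toy.swc"
        path.write_text(
            "# toy\n"
            "1 1 0 0 0 8.12 -1\n"
            "2 4 50 0 0 0.5 1\n"
            "3 4 100 0 0 0.5 2\n"
        )
        m = read_swc(str(path))
        assert len(m.sections) == 1
        assert m.sections[0].length == pytest.approx(100.0)
        assert m.soma_area == pytest.approx(4 * math.pi * 8.12**2, rel=1e-6)

    def test_round_trip_preserves_geometry(self, tmp_path):
        m = generate_synthetic_morphology(seed=6)
        path = tmp_path / "cell.swc"
        write_swc(m, str(path))
        m2 = read_swc(str(path))
        assert len(m2.sections) == len(m.sections)
        assert m2.total_length == pytest.approx(m.total_length, rel=1e-6)
        assert m2.soma_area == pytest.approx(m.soma_area, rel=1e-6)
        lengths = sorted(s.length for s in m.sections)
        lengths2 = sorted(s.length for s in m2.sections)
        assert np.allclose(lengths, lengths2, rtol=1e-6)

    def test_missing_parent_is_structure_error(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 8 -1\n2 4 10 0 0 0.5 9\n")
        with pytest.raises(SWCError, match="missing parent"):
            read_swc(str(path))

    def test_malformed_record_reports_line(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 8 -1\n2 4 ten 0 0 0.5 1\n")
        with pytest.raises(SWCError, match="line 2"):
            read_swc(str(path))


def test_summary_reports_printed_facts():
    m = generate_synthetic_morphology(seed=1)
    grid = discretize(m)
    s = morphology_summary(grid)
    assert s["soma_area_um2"] == pytest.approx(829.0)
    assert 2238 <= s["total_dendritic_length_um"] <= 2516
    assert s["n_compartments"] == grid.n_comp
    assert set(s["zone_length_um"]) == {"perisomatic", "IC", "LOT"}
    assert sum(s["zone_length_um"].values()) == pytest.approx(
        m.total_length, rel=1e-6
    )
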