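import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetalock.morphology import (
    Compartment,
    Morphology,
    MorphSpec,
    generate_morphology,
    leak_conductance,
    read_swc,
    spine_correction,
    write_swc,
)


class TestSpineCorrection:
    @pytest.mark.parametrize(
        "section,z,thickness,expected",
        [
            ("soma", 0.0, 15.0, 1.0),
            ("basal", 80.0, 0.9, 2.51),
            ("basal", 300.0, 2.0, 2.51),
            # near apical (z <= 350): thresholds closed on the lower bound
            ("apical_trunk", 100.0, 2.0, 1.69),
            ("apical_trunk", 100.0, 1.6, 1.69),
            ("apical_branch", 200.0, 1.0, 1.60),
            ("apical_branch", 200.0, 0.55, 1.60),
            ("apical_branch", 349.0, 0.2, 1.86),
            ("apical_branch", 350.0, 0.2, 1.86),  # boundary goes to near rule
            # far apical (z > 350)
            ("apical_branch", 400.0, 2.0, 2.10),
            ("apical_branch", 400.0, 0.35, 2.10),
            ("apical_branch", 400.0, 0.2, 1.71),
        ],
    )
    def test_decision_table(self, section, z, thickness, expected):
        assert spine_correction(section, z, thickness) == pytest.approx(expected)

    def test_unknown_section_rejected(self):
        with pytest.raises(ValueError, match="unknown section"):
            spine_correction("axon", 10.0, 1.0)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            spine_correction("basal", 10.0, 0.0)


class TestLeakConductance:
    def test_sigmoid_midpoint_closed_form(self):
        expected = 0.001 / (80.0 + (0.4 - 80.0) / 2.0)
        assert leak_conductance(225.0) == pytest.approx(expected, rel=1e-12)

    def test_somatic_value(self):
        expected = 0.001 / (80.0 + (0.4 - 80.0) / (1.0 + math.exp(7.5)))
        assert leak_conductance(0.0) == pytest.approx(expected, rel=1e-12)
        assert leak_conductance(0.0) == pytest.approx(1.2507e-5, rel=1e-3)

    def test_asymptotes(self):
        assert leak_conductance(1e7) == pytest.approx(0.001 / 0.4, rel=1e-9)
        lo = 0.001 / 80.0
        assert leak_conductance(0.0) > lo
        assert leak_conductance(0.0) == pytest.approx(lo, rel=0.01)

    def test_spine_scaling(self):
        assert leak_conductance(100.0, SS=2.51) == pytest.approx(
            2.51 * leak_conductance(100.0)
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1000.0),
           st.floats(min_value=0.01, max_value=1000.0))
    def test_strictly_increasing_and_bounded(self, z, dz):
        g1, g2 = leak_conductance(z), leak_conductance(z + dz)
        assert g2 > g1
        assert 0.001 / 80.0 < g1 < 0.001 / 0.4

    def test_negative_z_rejected(self):
        with pytest.raises(ValueError):
            leak_conductance(-1.0)


class TestGenerateMorphology:
    def test_branch_counts_exact_over_seeds(self):
        spec = MorphSpec(n_basal=5, n_apical=8)
        for seed in range(100):
            m = generate_morphology(spec, seed=seed)
            assert m.n_basal_branches == 5
            assert m.n_apical_branches == 8
            assert m.n_total_branches == 13

    def test_deterministic(self):
        a = generate_morphology(MorphSpec(), seed=7)
        b = generate_morphology(MorphSpec(), seed=7)
        assert [(c.id, c.parent, c.length, c.diameter, c.z) for c in a.compartments] == [
            (c.id, c.parent, c.length, c.diameter, c.z) for c in b.compartments
        ]

    def test_compartment_count_tracks_spec(self):
        # 1 soma + apical trunk/tuft and basal tree of ~40 compartments
        spec = MorphSpec(n_basal=4, n_apical=6, depth=2, mean_seg_length=10.0)
        m = generate_morphology(spec, seed=3)
        # sections: trunk 3 + apical subtree (2*6-1=11) + basal (2*4-1=7) = 21
        expected = 1 + 21 * spec.depth
        assert abs(m.n_compartments - expected) <= 0.2 * expected

    def test_invariants_hold(self, default_morph):
        by_id = {c.id: c for c in default_morph.compartments}
        for c in default_morph.compartments:
            if c.parent != -1:
                assert c.z > by_id[c.parent].z
            assert c.length > 0 and c.diameter > 0

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_morphology(MorphSpec(n_basal=0))
        with pytest.raises(ValueError):
            generate_morphology(MorphSpec(depth=0))


class TestSwc:
    def test_round_trip_topology(self, tmp_path, default_morph):
        p = tmp_path / "cell.swc"
        write_swc(default_morph, p)
        back = read_swc(p)
        assert back.n_compartments == default_morph.n_compartments
        # same parent structure and lengths within float tolerance
        a = sorted(default_morph.compartments, key=lambda c: c.id)
        b = sorted(back.compartments, key=lambda c: c.id)
        for ca, cb in zip(a, b):
            assert ca.parent == cb.parent
            assert cb.length == pytest.approx(ca.length, rel=1e-4, abs=1e-3)
            assert cb.diameter == pytest.approx(ca.diameter, abs=2e-4)
        assert back.n_basal_branches == default_morph.n_basal_branches
        assert back.n_apical_branches == default_morph.n_apical_branches

    def test_minimal_file(self, tmp_path):
        p = tmp_path / "mini.swc"
        p.write_text("1 1 0 0 0 10 -1\n2 3 0 -30 0 1 1\n3 4 0 40 0 1.5 1\n")
        m = read_swc(p)
        assert m.n_compartments == 3
        types = {c.section_type for c in m.compartments}
        assert types == {"soma", "basal", "apical_branch"}

    def test_missing_parent_names_line(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 10 -1\n2 3 0 -30 0 1 9\n")
        with pytest.raises(ValueError, match="parent 9"):
            read_swc(p)

    def test_multiple_roots_rejected(self, tmp_path):
        p = tmp_path / "two_roots.swc"
        p.write_text("1 1 0 0 0 10 -1\n2 1 50 0 0 10 -1\n")
        with pytest.raises(ValueError, match="root"):
            read_swc(p)


class TestMorphologyValidation:
    def test_single_root_required(self):
        soma = Compartment(0, -1, "soma", 20.0, 20.0, 0.0)
        orphan = Compartment(1, 5, "basal", 10.0, 1.0, 10.0)
        with pytest.raises(ValueError, match="missing parent"):
            Morphology([soma, orphan])

    def test_z_must_increase(self):
        comps = [
            Compartment(0, -1, "soma", 20.0, 20.0, 0.0),
            Compartment(1, 0, "basal", 10.0, 1.0, 0.0),
        ]
        with pytest.raises(ValueError, match="z not increasing"):
            Morphology(comps)
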