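"""Structure parsing, measurements and contact classification."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ndpdesign import (ACTIVE_REFERENCE_A, INACTIVE_REFERENCE_A,
                       AtomSelector, ContactRuleSet, activation_metric,
                       angle_xda, atom_distance, classify_activation,
                       contacts_to_tsv, detect_contacts, load_structure,
                       planar_angle, select_atom)
from ndpdesign.synth import (CONTACT_CASES, _random_rigid_motion,
                             random_two_chain_model,
                             synthetic_pair_geometry)

from conftest import make_pdb
from _oracles import contacts_as_set, oracle_contacts


@pytest.fixture()
def two_atom_model(tmp_path):
    text = make_pdb([
        ("CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        ("CA", "ALA", "B", 1, 3.0, 4.0, 0.0, "C"),
    ])
    p = tmp_path / "two.pdb"
    p.write_text(text)
    return load_structure(p)


class TestLoadStructure:
    def test_minimal_fixture(self, two_atom_model):
        assert len(two_atom_model.atoms) == 2
        assert two_atom_model.chains == {"A", "B"}

    def test_multi_model_keeps_first(self, tmp_path):
        text = make_pdb([("CA", "GLY", "A", 1, 1.0, 2.0, 3.0, "C")],
                        multi_model=True)
        p = tmp_path / "mm.pdb"
        p.write_text(text)
        model = load_structure(p)
        assert len(model.atoms) == 1
        assert model.atoms[0].position[0] == pytest.approx(1.0)

    def test_mmcif_round_trip(self, tmp_path):
        import gemmi
        p = tmp_path / "x.pdb"
        p.write_text(make_pdb([("CA", "GLY", "A", 5, 1.0, 2.0, 3.0, "C")]))
        st = gemmi.read_structure(str(p))
        st.setup_entities()
        cif = tmp_path / "x.cif"
        st.make_mmcif_document().write_file(str(cif))
        model = load_structure(cif, format="mmcif")
        assert model.atoms[0].residue_number == "5"

    def test_unreadable_file_errors(self, tmp_path):
        p = tmp_path / "junk.pdb"
        p.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            load_structure(p)

    def test_solvent_filter(self, tmp_path):
        text = make_pdb([
            ("CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
            ("O", "HOH", "A", 2, 5.0, 0.0, 0.0, "O"),
        ])
        p = tmp_path / "wet.pdb"
        p.write_text(text)
        assert len(load_structure(p).atoms) == 2
        assert len(load_structure(p, drop_solvent=True).atoms) == 1

    def test_unknown_format_errors(self, tmp_path):
        with pytest.raises(ValueError):
            load_structure(tmp_path / "x.pdb", format="xyz")


class TestSelectors:
    def test_round_trip(self):
        for text in ("A:ARG131:NH2", "B:GLU106:OE2", "A:ARG131"):
            assert str(AtomSelector.parse(text)) == text

    def test_malformed_selector(self):
        with pytest.raises(ValueError):
            AtomSelector.parse("nonsense")

    def test_select_atom(self, two_atom_model):
        atom = select_atom(two_atom_model, "A:GLY1:CA")
        assert atom.atom_name == "CA"
        assert atom.chain == "A"

    def test_missing_chain_errors(self, two_atom_model):
        with pytest.raises(KeyError):
            select_atom(two_atom_model, "Q:ALA1:CA")

    def test_residue_name_mismatch_guards_numbering(self, two_atom_model):
        with pytest.raises(ValueError, match="not ALA"):
            select_atom(two_atom_model, "A:ALA1:CA")


class TestMeasurements:
    def test_distance_three_four_five(self, two_atom_model):
        d = atom_distance(two_atom_model, "A:GLY1:CA", "B:ALA1:CA")
        assert d == pytest.approx(5.0)

    def test_distance_to_self_is_zero(self, two_atom_model):
        assert atom_distance(two_atom_model, "A:GLY1:CA",
                             "A:GLY1:CA") == 0.0

    def test_distance_symmetry(self, two_atom_model):
        assert atom_distance(two_atom_model, "A:GLY1:CA", "B:ALA1:CA") \
            == atom_distance(two_atom_model, "B:ALA1:CA", "A:GLY1:CA")

    def test_collinear_angle(self, tmp_path):
        p = tmp_path / "lin.pdb"
        p.write_text(make_pdb([
            ("N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
            ("CA", "GLY", "A", 2, 1.0, 0.0, 0.0, "C"),
            ("C", "GLY", "A", 3, 2.0, 0.0, 0.0, "C"),
        ]))
        model = load_structure(p)
        assert angle_xda(model, "A:GLY1:N", "A:GLY2:CA",
                         "A:GLY3:C") == pytest.approx(180.0)

    def test_right_angle(self, tmp_path):
        p = tmp_path / "ra.pdb"
        p.write_text(make_pdb([
            ("N", "GLY", "A", 1, 1.0, 0.0, 0.0, "N"),
            ("CA", "GLY", "A", 2, 0.0, 0.0, 0.0, "C"),
            ("C", "GLY", "A", 3, 0.0, 1.0, 0.0, "C"),
        ]))
        model = load_structure(p)
        assert angle_xda(model, "A:GLY1:N", "A:GLY2:CA",
                         "A:GLY3:C") == pytest.approx(90.0)

    def test_random_triples_match_dot_product_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            p1, p2, p3 = rng.uniform(-5, 5, size=(3, 3))
            v1, v2 = p1 - p2, p3 - p2
            expected = math.degrees(math.acos(np.clip(
                np.dot(v1, v2)
                / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
            assert planar_angle(p1, p2, p3) == pytest.approx(
                expected, abs=1e-9)

    def test_coincident_atoms_error(self):
        with pytest.raises(ValueError):
            planar_angle(np.zeros(3), np.zeros(3), np.ones(3))


class TestActivationMetric:
    def _model(self, tmp_path, separation):
        p = tmp_path / "act.pdb"
        p.write_text(make_pdb([
            ("CA", "TRP", "A", 68, 0.0, 0.0, 0.0, "C"),
            ("CA", "ALA", "A", 271, separation, 0.0, 0.0, "C"),
        ]))
        return load_structure(p)

    def test_active_reference_distance(self, tmp_path):
        model = self._model(tmp_path, ACTIVE_REFERENCE_A)
        d = activation_metric(model, ("A", 68), ("A", 271))
        assert d == pytest.approx(18.084)
        assert classify_activation(d) == "active-like"

    def test_inactive_reference_distance(self, tmp_path):
        model = self._model(tmp_path, INACTIVE_REFERENCE_A)
        d = activation_metric(model, ("A", 68), ("A", 271))
        assert d == pytest.approx(10.766)
        assert classify_activation(d) == "inactive-like"

    def test_same_residue_twice_is_zero(self, tmp_path):
        model = self._model(tmp_path, 12.0)
        assert activation_metric(model, ("A", 68), ("A", 68)) == 0.0

    def test_missing_atom_errors(self, tmp_path):
        model = self._model(tmp_path, 12.0)
        with pytest.raises(KeyError):
            activation_metric(model, ("A", 68), ("A", 271), atom="C")


class TestContactRuleSet:
    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ContactRuleSet(hydrophobic_max=0.0)

    def test_angle_threshold_bounds(self):
        with pytest.raises(ValueError):
            ContactRuleSet(hbond_angle_min=200.0)


EXPECTED_TYPE = {
    "Salt Bridge": "Salt Bridge; Attractive Charge",
    "none": None,
}


class TestDetectContacts:
    @pytest.mark.parametrize("case", CONTACT_CASES)
    def test_synthetic_case_yields_exactly_its_type(self, case):
        rules = ContactRuleSet()
        for seed in range(5):
            model = synthetic_pair_geometry(case, rules, seed)
            types = {r.type for r in detect_contacts(model, "A", "B", rules)}
            expected = EXPECTED_TYPE.get(case, case)
            assert types == ({expected} if expected else set())

    def test_far_alkyl_pair_has_no_contact(self, tmp_path):
        p = tmp_path / "far.pdb"
        p.write_text(make_pdb([
            ("CB", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            ("CB", "ALA", "B", 1, 10.0, 0.0, 0.0, "C"),
        ]))
        model = load_structure(p)
        assert detect_contacts(model, "A", "B", ContactRuleSet()) == []

    def test_unknown_chain_errors(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(make_pdb([("CB", "ALA", "A", 1, 0, 0, 0, "C")]))
        model = load_structure(p)
        with pytest.raises(KeyError):
            detect_contacts(model, "A", "Q", ContactRuleSet())

    def test_chain_swap_symmetry(self):
        rules = ContactRuleSet()
        for seed in range(20):
            model = random_two_chain_model(seed)
            ab = contacts_as_set(detect_contacts(model, "A", "B", rules))
            ba = contacts_as_set(detect_contacts(model, "B", "A", rules))
            # same contacts up to from/to relabeling (roles such as donor
            # or positive fix the direction; symmetric types may flip)
            unordered = lambda s: {(frozenset((f, t)), c, ty, d)
                                   for f, t, c, ty, d in s}
            assert unordered(ab) == unordered(ba)

    def test_rigid_motion_invariance(self):
        rules = ContactRuleSet()
        rng = np.random.default_rng(77)
        for seed in range(20):
            model = random_two_chain_model(seed)
            before = detect_contacts(model, "A", "B", rules)
            Q, t = _random_rigid_motion(rng)
            after = detect_contacts(model.transformed(Q, t), "A", "B", rules)
            assert len(before) == len(after)
            for r1, r2 in zip(before, after):
                assert (r1.from_selector, r1.to_selector, r1.category,
                        r1.type) == (r2.from_selector, r2.to_selector,
                                     r2.category, r2.type)
                assert r1.distance == pytest.approx(r2.distance, abs=1e-9)
                for k in r1.angles:
                    assert r1.angles[k] == pytest.approx(
                        r2.angles[k], abs=1e-7)

    def test_matches_brute_force_oracle(self):
        rules = ContactRuleSet()
        for seed in range(300):
            model = random_two_chain_model(seed)
            impl = contacts_as_set(detect_contacts(model, "A", "B", rules))
            assert impl == oracle_contacts(model, "A", "B", rules), \
                f"disagreement at seed {seed}"

    def test_cutoff_monotonicity(self):
        """Enlarging a cutoff never removes a contact of its type."""
        base = ContactRuleSet()
        grow = {
            "attractive_charge_max": "Attractive Charge",
            "hbond_HA_max": "Conventional Hydrogen Bond",
            "carbon_hbond_HA_max": "Carbon Hydrogen Bond",
            "hydrophobic_max": "Alkyl",
            "pi_max": "Pi-Alkyl",
            "amide_pi_max": "Amide-Pi Stacked",
        }
        for field_name, typ in grow.items():
            bigger = ContactRuleSet(
                **{field_name: getattr(base, field_name) + 1.0})
            for seed in range(30):
                model = random_two_chain_model(seed)
                small = {c for c in contacts_as_set(
                    detect_contacts(model, "A", "B", base)) if c[3] == typ}
                large = {c for c in contacts_as_set(
                    detect_contacts(model, "A", "B", bigger)) if c[3] == typ}
                assert small <= large

    def test_output_ordering(self):
        from ndpdesign.structure import CATEGORY_ORDER
        for seed in range(20):
            model = random_two_chain_model(seed)
            recs = detect_contacts(model, "A", "B", ContactRuleSet())
            keys = [(CATEGORY_ORDER[r.category], r.distance) for r in recs]
            assert keys == sorted(keys)

    def test_tsv_report_shape(self):
        model = synthetic_pair_geometry("Salt Bridge", seed=3)
        recs = detect_contacts(model, "A", "B", ContactRuleSet())
        text = contacts_to_tsv(recs)
        lines = text.strip().splitlines()
        assert lines[0].startswith("Name\tDistance\tCategory\tType")
        assert len(lines) == len(recs) + 1
        assert "Salt Bridge; Attractive Charge" in lines[1]
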