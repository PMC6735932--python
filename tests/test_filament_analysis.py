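"""Groove widths, contacts, pairing detection, bubbles and stacking."""

import numpy as np
import pytest

from filaweaver import (
    MonomerAnnotation,
    RigidTransform,
    StrandModel,
    cross_groove_contacts,
    default_criteria,
    detect_pairs,
    groove_width,
    groove_width_profile,
    interstrand_proximity,
    melting_bubble,
    stacking_partition,
)
from filaweaver.filament_analysis import CriterionConfigError, load_criteria
from filaweaver.filament_builder import Filament
from filaweaver.structure_io import AtomRecord, Structure

from conftest import random_rigid_transform

ANN = MonomerAnnotation()


def _point_monomer(c_dom_xyz, n_dom_xyz):
    """Pseudo-monomer with one C-domain atom and one N-domain atom."""
    atoms = [
        AtomRecord(1, "CA", "GLY", 280, "A", c_dom_xyz, element="C"),
        AtomRecord(2, "CA", "GLY", 10, "A", n_dom_xyz, element="C"),
    ]
    return Structure(atoms)


def _filament_from_monomers(monomers):
    return Filament(
        monomers,
        [RigidTransform.identity() for _ in monomers],
        ["ATP"] * (len(monomers) - 1),
    )


class TestGrooveWidth:
    def test_constructed_distance_exact(self):
        monomers = [
            _point_monomer([float(k), 0.0, 0.0], [float(k), 10.0, 0.0])
            for k in range(8)
        ]
        f = _filament_from_monomers(monomers)
        e = groove_width(f, ANN, 0)
        # C-dom of monomer 0 at (0,0,0); N-doms of partners 5,6,7 at
        # (5,10,0), (6,10,0), (7,10,0): the minimum is sqrt(25+100).
        assert e.width == pytest.approx(np.sqrt(125.0), abs=1e-12)
        assert e.partner == 5
        assert not e.truncated

    def test_truncated_partner_set_flagged(self):
        monomers = [
            _point_monomer([float(k), 0.0, 0.0], [float(k), 10.0, 0.0])
            for k in range(6)
        ]
        f = _filament_from_monomers(monomers)
        e = groove_width(f, ANN, 0)
        assert e.truncated and e.partner == 5

    def test_no_partner_errors(self):
        monomers = [_point_monomer([0, 0, 0], [0, 10, 0]) for _ in range(3)]
        f = _filament_from_monomers(monomers)
        with pytest.raises(ValueError, match="undefined"):
            groove_width(f, ANN, 0)

    def test_rigid_motion_invariance(self, regular_filament):
        fil, _ = regular_filament
        profile = groove_width_profile(fil, ANN)
        g = random_rigid_transform(np.random.default_rng(21))
        moved = Filament(
            [g.apply_structure(m) for m in fil.monomers],
            [g @ p for p in fil.placements],
            list(fil.interfaces),
        )
        profile2 = groove_width_profile(moved, ANN)
        for a, b in zip(profile, profile2):
            assert a.width == pytest.approx(b.width, abs=1e-9)
            assert a.partner == b.partner


class TestCrossGrooveContacts:
    def test_distant_monomers_no_contacts(self):
        m1 = _point_monomer([0, 0, 0], [0, 1, 0])
        m2 = _point_monomer([100, 0, 0], [100, 1, 0])
        f = _filament_from_monomers([m1, m2])
        assert cross_groove_contacts(f, 0, 1) == []

    def test_engineered_contact_found(self):
        m1 = Structure(
            [
                AtomRecord(1, "CA", "GLY", 290, "A", [0.0, 0.0, 0.0], element="C"),
                AtomRecord(2, "CA", "GLY", 291, "A", [50.0, 0.0, 0.0], element="C"),
            ]
        )
        m2 = Structure(
            [AtomRecord(1, "CA", "GLY", 20, "A", [3.0, 0.0, 0.0], element="C")]
        )
        f = _filament_from_monomers([m1, m2])
        contacts = cross_groove_contacts(f, 0, 1, cutoff=4.0)
        assert contacts == [(290, 20, pytest.approx(3.0))]


def _base(letter, center, chain="X", seq=1):
    """Minimal base with the named pairing atoms placed explicitly."""
    from filaweaver.synthetic_data import _base_atoms

    resname = {"A": "DA", "T": "DT"}[letter]
    side = "left" if letter == "A" else "right"
    atoms = []
    for i, (name, pos) in enumerate(_base_atoms(letter, side).items(), start=1):
        atoms.append(AtomRecord(i, name, resname, seq, chain, np.asarray(center) + pos))
    return Structure(atoms)


class TestDetectPairs:
    def test_ideal_duplex_full_wc_recall(self, bdna_duplex):
        a, b = bdna_duplex
        records = detect_pairs(a, b)
        wc = [r for r in records if r.label == "WC_AT"]
        assert len(wc) == a.n_nucleotides
        paired_positions = {r.bases[0][1] for r in wc}
        assert paired_positions == set(range(1, a.n_nucleotides + 1))

    def test_separated_strands_nothing_detected(self, bdna_duplex):
        a, b = bdna_duplex
        moved = StrandModel(
            b.structure.with_coords(b.structure.coords() + np.array([10.0, 0, 0])),
            b.site,
            list(b.placed_by),
            b.sequence,
        )
        assert detect_pairs(a, moved) == []

    def test_constructed_hoogsteen_geometry(self):
        """A/T with N7(A)-N3(T) and N6(A)-O2(T) near 2.9 A satisfies the
        Hoogsteen criterion (heavy-atom fallback) and not Watson-Crick."""
        a = _base("A", [0.0, 0.0, 0.0], chain="X")
        n7 = a.atom(None, 1, "N7").position
        n6 = a.atom(None, 1, "N6").position
        # place a bare T whose N3 and O2 sit 2.9 A from N7 and N6
        direction = np.array([0.0, 0.0, 1.0])
        t_atoms = [
            AtomRecord(1, "N3", "DT", 1, "Y", n7 + 2.9 * direction),
            AtomRecord(2, "O2", "DT", 1, "Y", n6 + 2.9 * direction),
            AtomRecord(3, "C2", "DT", 1, "Y", n6 + 3.5 * direction),
        ]
        t = Structure(t_atoms)
        labels = {r.label for r in detect_pairs(a, t)}
        assert labels == {"HG_AT"}

    def test_triplet_detection(self):
        """Constructed T(incoming):A(complementary):T(outgoing) triplet."""
        b = _base("A", [0.0, 0.0, 0.0], chain="Y")  # complementary adenine
        n6 = b.atom(None, 1, "N6").position
        n1 = b.atom(None, 1, "N1").position
        a_atoms = [
            AtomRecord(1, "O4", "DT", 1, "X", n6 + np.array([0.0, 0.0, 2.9])),
            AtomRecord(2, "N3", "DT", 1, "X", n1 + np.array([0.0, 0.0, 2.9])),
        ]
        o4_incoming = a_atoms[0].position
        c_atoms = [
            AtomRecord(1, "O4", "DT", 1, "Z", n6 + np.array([0.0, 0.0, -2.9])),
            AtomRecord(2, "N3", "DT", 1, "Z", o4_incoming + np.array([3.0, 0.0, 0.0])),
        ]
        records = detect_pairs(
            Structure(a_atoms), b, bases_c=Structure(c_atoms)
        )
        assert {r.label for r in records} == {"R_TRIPLET"}

    def test_unknown_atom_name_is_config_error(self):
        doc = {
            "criteria": [
                {
                    "label": "BAD",
                    "roles": {"a": ["DA"], "b": ["DT"]},
                    "clauses": [[{"i": "a", "atom_i": "Q9", "j": "b", "atom_j": "O4", "max": 3.0}]],
                }
            ]
        }
        with pytest.raises(CriterionConfigError, match="Q9"):
            load_criteria(doc)

    def test_rigid_motion_invariance(self, bdna_duplex):
        a, b = bdna_duplex
        g = random_rigid_transform(np.random.default_rng(31))
        am = StrandModel(g.apply_structure(a.structure), a.site, list(a.placed_by), a.sequence)
        bm = StrandModel(g.apply_structure(b.structure), b.site, list(b.placed_by), b.sequence)
        assert len(detect_pairs(am, bm)) == len(detect_pairs(a, b))


class TestMeltingBubble:
    def test_all_paired_empty(self):
        assert melting_bubble([True] * 20) == []

    def test_six_bp_bubble(self):
        mask = [True] * 36
        for i in range(15, 21):  # positions 16-21, 1-based
            mask[i] = False
        assert melting_bubble(mask) == [(15, 6)]

    def test_alternating_runs_of_one(self):
        mask = [i % 2 == 0 for i in range(10)]
        runs = melting_bubble(mask)
        assert all(length == 1 for _, length in runs) and len(runs) == 5

    def test_conservation_property(self, rng):
        for _ in range(25):
            mask = rng.random(rng.integers(1, 40)) > 0.5
            runs = melting_bubble(mask)
            assert sum(l for _, l in runs) + int(mask.sum()) == len(mask)


class TestStackingPartition:
    def test_bdna_single_run(self, bdna_strand):
        assert stacking_partition(bdna_strand) == [bdna_strand.n_nucleotides]

    def test_every_third_step_disrupted_gives_triplets(self, bdna_strand):
        s = bdna_strand.copy()
        for n in range(3, s.n_nucleotides, 3):
            # push base (not backbone) of every fourth nucleotide away
            for a in s.nucleotide(n + 1):
                if a.atom_name not in ("P", "O3'"):
                    a.position = a.position + np.array([8.0, 0.0, 0.0])
        runs = stacking_partition(s)
        assert runs[0] == 3
        assert sum(runs) == s.n_nucleotides

    def test_zero_cutoff_all_singletons(self, bdna_strand):
        assert stacking_partition(bdna_strand, dist_cutoff=0.0) == [1] * bdna_strand.n_nucleotides

    def test_partition_sums_to_base_count(self, threaded_strand):
        assert sum(stacking_partition(threaded_strand)) == threaded_strand.n_nucleotides

    def test_too_few_ring_atoms_rejected(self):
        atoms = [
            AtomRecord(1, "P", "DT", 1, "X", [0, 0, 0]),
            AtomRecord(2, "N1", "DT", 1, "X", [1, 0, 0]),
        ]
        s = StrandModel(Structure(atoms), "I_incoming", [0], "T")
        with pytest.raises(ValueError, match="ring atoms"):
            stacking_partition(s)


class TestInterstrandProximity:
    def test_identical_strands_zero(self, bdna_strand):
        profile = interstrand_proximity(bdna_strand, bdna_strand)
        np.testing.assert_allclose(profile, 0.0, atol=1e-12)

    def test_offset_strands_constant_profile(self, bdna_strand):
        moved = StrandModel(
            bdna_strand.structure.with_coords(
                bdna_strand.structure.coords() + np.array([10.0, 0.0, 0.0])
            ),
            bdna_strand.site,
            list(bdna_strand.placed_by),
            bdna_strand.sequence,
        )
        profile = interstrand_proximity(bdna_strand, moved)
        assert profile.max() <= 10.0 + 1e-9
        # each nucleotide sees at least its own displaced copy's nearest atom
        assert profile.min() > 0.0
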