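"""Ground-truth synthetic inputs for every pipeline stage.

Every generator here produces structures whose geometric parameters are
programmed exactly, so construction and analysis code can be validated
end-to-end with no external coordinates:

* pseudo-monomer filaments on a programmed screw (optionally kinked),
* idealized DNA strands/duplexes with programmed rise, twist and radius,
* multi-model "trajectories" with programmed inter-atom distance series.

The default screw presets emulate the two RecA filament regimes — an
extended (ATP-like) screw of 58.4 deg / 15.4 A per monomer (pitch 94.9 A,
inside the 85-100 A extended band) and a compressed (ADP-like) screw of
58.3 deg / 13.4 A (pitch 82.7 A, inside the 65-85 A compressed band).
They are synthetic stand-ins for interface geometries that would otherwise
be measured from crystal structures; the numbers are chosen to sit at the
documented centers of the two regimes, not fitted to any structure.

Base geometries are idealized: planar hexagonal rings with 1.38 A bonds,
substituent atoms placed so that the Watson-Crick A:T criterion distances
(N1-N3 and N6-O4 of 2.85 A, H-acceptor 1.85 A) hold exactly in generated
duplexes.  All randomness flows through one seeded NumPy generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dna_threading import StrandModel
from .filament_builder import ADP, ATP, Filament
from .screw_geometry import RigidTransform, ScrewParams, compose, transform_from_screw
from .structure_io import AtomRecord, Structure

__all__ = [
    "SyntheticFilamentSpec",
    "SyntheticDNASpec",
    "EXTENDED_SCREW",
    "COMPRESSED_SCREW",
    "make_filament",
    "make_dna",
    "make_site_template",
    "make_trajectory",
]

_Z = np.array([0.0, 0.0, 1.0])

EXTENDED_SCREW = ScrewParams(_Z, np.zeros(3), 58.4, 15.4)
"""ATP-like (extended-regime) screw: 6.16 monomers/turn, pitch 94.9 A."""

COMPRESSED_SCREW = ScrewParams(_Z, np.zeros(3), 58.3, 13.4)
"""ADP-like (compressed-regime) screw: 6.17 monomers/turn, pitch 82.7 A."""


# ---------------------------------------------------------------------
# pseudo-monomer filaments


@dataclass
class SyntheticFilamentSpec:
    """Programmed filament: ``n`` pseudo-monomers on a screw of
    ``angle_deg``/``translation`` about the z axis, monomer body centered
    at ``radius`` from the axis.  ``kink_after`` (internal 0-based index)
    pre-rotates all downstream placements by ``kink_deg`` about an axis
    perpendicular to the helix axis at the junction, emulating the axis
    kink a compressed interface introduces into an extended filament.

    Pseudo-monomers carry single labelled atoms inside the default
    annotation ranges (N-domain residues 10-12, C-domain 285-287, L1 160,
    L2 200, LexA loop 230) plus a seeded random body cloud (residues 50+),
    giving each monomer a non-degenerate inertia tensor."""

    angle_deg: float = 58.4
    translation: float = 15.4
    n: int = 12
    kink_after: int | None = None
    kink_deg: float = 0.0
    atoms_per_monomer: int = 24
    radius: float = 25.0
    seed: int = 1
    index_offset: int = 0


def _pseudo_monomer(spec: SyntheticFilamentSpec) -> Structure:
    rng = np.random.default_rng(spec.seed)
    center = np.array([spec.radius, 0.0, 0.0])
    labelled = [
        # (residue_seq, local offset): domain marker atoms
        (10, np.array([2.0, -6.0, -6.5])),   # N-domain
        (11, np.array([0.0, -7.0, -5.5])),
        (12, np.array([-2.0, -6.0, -6.0])),
        (160, np.array([-6.0, 0.0, 0.0])),   # L1
        (200, np.array([-5.0, 3.0, 1.0])),   # L2
        (230, np.array([0.0, 6.0, 0.0])),    # LexA-binding loop
        (285, np.array([2.0, 5.5, 6.5])),    # C-domain
        (286, np.array([0.0, 6.5, 6.0])),
        (287, np.array([-2.0, 5.5, 6.0])),
    ]
    n_body = spec.atoms_per_monomer - len(labelled)
    if spec.atoms_per_monomer < 4:
        raise ValueError("need >= 4 atoms per monomer for a non-degenerate body")
    atoms: list[AtomRecord] = []
    serial = 0
    for seq, off in labelled:
        serial += 1
        atoms.append(
            AtomRecord(serial, "CA", "GLY", seq, "A", center + off, element="C")
        )
    for i in range(max(n_body, 0)):
        serial += 1
        # uniform in a ball of radius 8 around the monomer center
        v = rng.normal(size=3)
        v *= 8.0 * rng.random() ** (1 / 3) / np.linalg.norm(v)
        atoms.append(
            AtomRecord(serial, "CA", "GLY", 50 + i, "A", center + v, element="C")
        )
    atoms.sort(key=lambda a: a.residue_seq)
    for serial, a in enumerate(atoms, start=1):
        a.serial = serial
    return Structure(atoms)


def make_filament(
    spec: SyntheticFilamentSpec,
) -> tuple[Filament, ScrewParams, float]:
    """Build the programmed filament; returns (filament, ground-truth
    screw, ground-truth kink in degrees)."""
    screw = ScrewParams(_Z, np.zeros(3), spec.angle_deg, spec.translation)
    t = transform_from_screw(screw)
    monomer = _pseudo_monomer(spec)
    placements = [RigidTransform.identity()]
    for _ in range(spec.n - 1):
        placements.append(compose(placements[-1], t))
    labels = [ATP] * (spec.n - 1)
    kink = 0.0
    if spec.kink_after is not None:
        j = spec.kink_after
        if not 0 <= j < spec.n - 1:
            raise ValueError("kink_after must name an interface (0..n-2)")
        kink = float(spec.kink_deg)
        pivot = np.array([0.0, 0.0, (j + 1) * spec.translation])
        K = transform_from_screw(
            ScrewParams(np.array([1.0, 0.0, 0.0]), pivot, kink, 0.0)
        )
        placements = [p if k <= j else compose(K, p) for k, p in enumerate(placements)]
        labels[j] = ADP
    monomers = [p.apply_structure(monomer) for p in placements]
    f = Filament(monomers, placements, labels, index_offset=spec.index_offset)
    return f, screw, kink


# ---------------------------------------------------------------------
# idealized DNA

_HEX_R = 1.38  # ring bond length -> circumradius of the idealized hexagon
_SUB_R = 2.0 * _HEX_R  # substituents sit radially at twice the ring radius

# half the N1(A)-N3(T) Watson-Crick distance, measured from ring vertices
_WC_NN = 2.85
_PAIR_HALF = (_WC_NN + 2.0 * _HEX_R) / 2.0  # base-center to pair-center offset


def _hexagon(center: np.ndarray, names_at_angles: list[tuple[str, float]]) -> dict[str, np.ndarray]:
    out = {}
    for name, ang in names_at_angles:
        rad = math.radians(ang)
        out[name] = center + np.array([math.cos(rad), math.sin(rad), 0.0]) * _HEX_R
    return out


def _sub(center: np.ndarray, ang: float, radius: float = _SUB_R) -> np.ndarray:
    rad = math.radians(ang)
    return center + np.array([math.cos(rad), math.sin(rad), 0.0]) * radius


def _purine_atoms(center: np.ndarray, letter: str) -> dict[str, np.ndarray]:
    """Idealized purine with N1 facing +x (the pairing direction)."""
    atoms = _hexagon(
        center,
        [("N1", 0.0), ("C6", 60.0), ("C5", 120.0), ("C4", 180.0), ("N3", 240.0), ("C2", 300.0)],
    )
    atoms["N7"] = _sub(center, 130.0, 2.40)
    atoms["C8"] = _sub(center, 160.0, 3.10)
    atoms["N9"] = _sub(center, 190.0, 2.40)
    if letter == "A":
        atoms["N6"] = _sub(center, 60.0)
        atoms["H61"] = atoms["N6"] + np.array([1.0, 0.0, 0.0])
        atoms["H62"] = atoms["N6"] + np.array([0.5, math.sqrt(3) / 2, 0.0])
    else:  # G
        atoms["O6"] = _sub(center, 60.0)
        atoms["N2"] = _sub(center, 300.0)
    return atoms


def _pyrimidine_atoms(center: np.ndarray, letter: str) -> dict[str, np.ndarray]:
    """Idealized pyrimidine with N3 facing -x (toward the paired purine)."""
    atoms = _hexagon(
        center,
        [("C6", 0.0), ("C5", 60.0), ("C4", 120.0), ("N3", 180.0), ("C2", 240.0), ("N1", 300.0)],
    )
    if letter == "T":
        atoms["O4"] = _sub(center, 120.0)
        atoms["O2"] = _sub(center, 240.0)
        atoms["H3"] = atoms["N3"] + np.array([-1.0, 0.0, 0.0])
    else:  # C
        atoms["N4"] = _sub(center, 120.0)
        atoms["O2"] = _sub(center, 240.0)
    return atoms


_RESNAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _base_atoms(letter: str, side: str) -> dict[str, np.ndarray]:
    """Base atoms in the pair frame: ``side='left'`` faces +x from the
    left-hand center, ``'right'`` faces -x from the right-hand center."""
    if side == "left":
        center = np.array([-_PAIR_HALF, 0.0, 0.0])
        if letter in "AG":
            return _purine_atoms(center, letter)
        # left-hand pyrimidine: mirror the template through x -> -x
        atoms = _pyrimidine_atoms(np.zeros(3), letter)
        return {n: center + np.array([-p[0], p[1], p[2]]) for n, p in atoms.items()}
    center = np.array([_PAIR_HALF, 0.0, 0.0])
    if letter in "TC":
        atoms = _pyrimidine_atoms(np.zeros(3), letter)
        return {n: center + p for n, p in atoms.items()}
    atoms = _purine_atoms(np.zeros(3), letter)
    return {n: center + np.array([-p[0], p[1], p[2]]) for n, p in atoms.items()}


@dataclass
class SyntheticDNASpec:
    """Programmed helical strand (or WC duplex) built about the z axis.

    Defaults are the B-form baseline (rise 3.38 A, twist 34.3 deg,
    phosphate radius 8.9 A).  The filament-bound site-I regime corresponds
    to rise 5.07 A and twist 20.6 deg (50% stretched, 40% unwound)."""

    n: int = 36
    rise: float = 3.38
    twist: float = 34.3
    radius: float = 8.9
    sequence: str | None = None  # default: poly-dT (dA for the complement)
    duplex: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0 and abs(self.twist) > 1e-12:
            raise ValueError("zero radius with non-zero twist is degenerate")
        if self.sequence is None:
            self.sequence = "T" * self.n
        if len(self.sequence) != self.n:
            raise ValueError("sequence length must equal n")
        if any(c not in "ACGT" for c in self.sequence):
            raise ValueError("sequence must be over {A,C,G,T}")


def _rotz(angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _strand_from_frames(
    spec: SyntheticDNASpec,
    letters: str,
    side: str,
    phos_angle: float,
    chain: str,
    site: str,
) -> StrandModel:
    """Build one strand: per nucleotide, rotate the pair-frame template by
    n x twist about z and lift by n x rise; P sits at ``spec.radius`` and
    local angle ``phos_angle``; O3' is placed 1.6 A from the (analytic)
    next P, so ideal strands are continuous by construction."""
    atoms: list[AtomRecord] = []
    serial = 0

    def p_at(n: int) -> np.ndarray:
        ang = math.radians(n * spec.twist + phos_angle)
        return np.array(
            [spec.radius * math.cos(ang), spec.radius * math.sin(ang), n * spec.rise]
        )

    for n, letter in enumerate(letters):
        R = _rotz(n * spec.twist)
        lift = np.array([0.0, 0.0, n * spec.rise])
        pos_p = p_at(n)
        nxt = p_at(n + 1)
        direction = pos_p - nxt
        o3 = nxt + 1.6 * direction / np.linalg.norm(direction)
        placed = {"P": pos_p, "O3'": o3}
        for name, p in _base_atoms(letter, side).items():
            placed[name] = R @ p + lift
        for name, p in placed.items():
            serial += 1
            atoms.append(
                AtomRecord(serial, name, _RESNAME[letter], n + 1, chain, p)
            )
    return StrandModel(Structure(atoms), site, list(range(len(letters))), letters)


def make_dna(spec: SyntheticDNASpec) -> StrandModel | tuple[StrandModel, StrandModel]:
    """Generate the programmed strand; with ``duplex=True`` also the
    Watson-Crick-paired complementary strand (pair planes perpendicular to
    the helix axis, WC criterion satisfied at every position)."""
    strand = _strand_from_frames(
        spec, spec.sequence, "left", 160.0, "I", "I_incoming"
    )
    if not spec.duplex:
        return strand
    comp_letters = "".join(_COMPLEMENT[c] for c in spec.sequence)
    comp = _strand_from_frames(
        spec, comp_letters, "right", 20.0, "J", "I_complementary"
    )
    return strand, comp


def make_site_template(
    screw: ScrewParams = EXTENDED_SCREW,
    radius: float = 8.9,
    sequence: str = "TTT",
    phos_angle: float = 160.0,
) -> Structure:
    """Trinucleotide threading template consistent with a filament screw.

    The three nucleotides are placed by the one-third screw (angle/3,
    translation/3), so threading the template along a regular filament
    built from the same screw produces a uniform, backbone-continuous
    helix with per-step rise d/3 and twist theta/3.  This mirrors how
    crystal-derived templates tile a filament in triplets.
    """
    if len(sequence) != 3:
        raise ValueError("template sequence must have exactly 3 bases")
    sub = SyntheticDNASpec(
        n=3,
        rise=screw.translation / 3.0,
        twist=screw.angle_deg / 3.0,
        radius=radius,
        sequence=sequence,
    )
    strand = _strand_from_frames(sub, sequence, "left", phos_angle, "I", "I_incoming")
    return strand.structure


# ---------------------------------------------------------------------
# programmed trajectories


def make_trajectory(
    base: Structure,
    events: list[tuple[tuple[str, int, str], tuple[str, int, str], np.ndarray]],
    n_frames: int,
    seed: int = 1,
    jitter_sigma: float = 0.0,
) -> list[Structure]:
    """Multi-model trajectory with programmed inter-atom distance series.

    Each event is ``(sel_a, sel_b, program)`` with selectors
    ``(chain_id, residue_seq, atom_name)`` and ``program`` the target
    a-b distance per frame.  The program is realized by rigidly
    translating the residue holding ``sel_b`` along the initial a->b
    direction; atom a stays put.  Two events may not move the same
    residue.  Unprogrammed atoms optionally receive Gaussian jitter of
    ``jitter_sigma`` A (seeded, reproducible).
    """
    rng = np.random.default_rng(seed)
    moved: set[tuple[str, int]] = set()
    anchored: set[tuple[str, int]] = set()
    plans = []
    for sel_a, sel_b, program in events:
        program = np.asarray(program, dtype=float)
        if program.shape != (n_frames,):
            raise ValueError("each program must provide one distance per frame")
        if np.any(program <= 0):
            raise ValueError("programmed distances must be positive")
        key = (sel_b[0], sel_b[1])
        if key in moved:
            raise ValueError(f"conflicting programs move residue {key} twice")
        moved.add(key)
        anchored.add((sel_a[0], sel_a[1]))
        a0 = base.atom(*sel_a).position
        b0 = base.atom(*sel_b).position
        sep = b0 - a0
        dist = np.linalg.norm(sep)
        if dist < 1e-9:
            raise ValueError("coincident program atoms: direction undefined")
        plans.append((sel_a[0], sel_a[1], sel_a[2], key, a0, sep / dist, b0, program))

    frames: list[Structure] = []
    idx_by_residue: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(base.atoms):
        idx_by_residue.setdefault((a.chain_id, a.residue_seq), []).append(i)
    base_coords = base.coords()
    # programmed residues and their reference residues stay jitter-free so
    # realized distances equal the program exactly
    frozen = {i for key in moved | anchored for i in idx_by_residue[key]}
    for f_idx in range(n_frames):
        coords = base_coords.copy()
        if jitter_sigma > 0:
            noise = rng.normal(scale=jitter_sigma, size=coords.shape)
            for i in frozen:
                noise[i] = 0.0
            coords = coords + noise
        for _, _, aname, key, a0, direction, b0, program in plans:
            shift = (a0 + direction * program[f_idx]) - b0
            for i in idx_by_residue[key]:
                coords[i] = base_coords[i] + shift
        frame = base.with_coords(coords)
        frame.model_index = f_idx + 1
        frames.append(frame)
    return frames
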