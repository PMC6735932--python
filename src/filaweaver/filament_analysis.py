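"""Structural metrics of distorted nucleofilaments.

The observables here quantify what a single switched (compressed-form)
interface does to an otherwise extended filament and its bound DNA:

* groove-entrance width — the smallest distance between the C-terminal
  domain of monomer k and the N-terminal domains of the three monomers
  across the groove (k+5, k+6, k+7); about 28 A in regular extended
  filaments, collapsing to contact when the kink closes the groove;
* cross-groove residue contacts (which residues realize the closure);
* geometric base-pairing detection — Watson-Crick, Hoogsteen and R-type
  triplet criteria as atom-distance conditions read from a config file;
* melting-bubble extraction (maximal unpaired runs of a duplex mask);
* stacking partition of a strand into maximal stacked runs (regular
  site-I DNA partitions into base triplets; a distorted region into e.g.
  a duplet plus a quadruplet);
* per-nucleotide inter-strand proximity profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .dna_threading import StrandModel
from .filament_builder import Filament, MonomerAnnotation
from .structure_io import AtomRecord, Structure, select

__all__ = [
    "GrooveWidthEntry",
    "PairingCriterion",
    "PairingRecord",
    "CriterionConfigError",
    "load_criteria",
    "default_criteria",
    "groove_width",
    "groove_width_profile",
    "cross_groove_contacts",
    "detect_pairs",
    "melting_bubble",
    "stacking_partition",
    "interstrand_proximity",
]

_NUCLEOTIDE_ATOMS = {
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
    "N1", "C2", "O2", "N2", "N3", "C4", "O4", "N4", "C5", "C7", "C6", "O6",
    "N6", "N7", "C8", "N9",
    "H1", "H2", "H3", "H5", "H6", "H8", "H21", "H22", "H41", "H42", "H61", "H62",
}

_RING_ATOMS = {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"}


# ---------------------------------------------------------------------
# groove geometry


@dataclass(frozen=True)
class GrooveWidthEntry:
    """Groove-entrance width at monomer ``k`` (internal index)."""

    k: int
    width: float
    partner: int
    atoms: tuple[str, str]
    truncated: bool


def _domain_atoms(f: Filament, k: int, rng: tuple[int, int]) -> Structure:
    return select(f.monomers[k], residue_range=rng, heavy_only=True)


def groove_width(f: Filament, ann: MonomerAnnotation, k: int) -> GrooveWidthEntry:
    """Smallest heavy-atom distance between the C-terminal domain of
    monomer ``k`` and the N-terminal domains of monomers k+5, k+6, k+7.
    Near the filament end the partner set is truncated to the monomers
    that exist (flagged); with no partner at all the width is undefined."""
    c_dom = _domain_atoms(f, k, ann.c_domain)
    if c_dom.empty_selection:
        raise ValueError(f"monomer {k} has no heavy atoms in the C-domain range")
    partners = [k + 5, k + 6, k + 7]
    existing = [p for p in partners if p < len(f)]
    if not existing:
        raise ValueError(f"groove width undefined for monomer {k}: no partner monomer")
    best: tuple[float, int, tuple[str, str]] | None = None
    cpos = c_dom.coords()
    for p in existing:
        n_dom = _domain_atoms(f, p, ann.n_domain)
        if n_dom.empty_selection:
            continue
        d = cdist(cpos, n_dom.coords())
        i, j = np.unravel_index(np.argmin(d), d.shape)
        val = float(d[i, j])
        if best is None or val < best[0]:
            names = (
                f"{c_dom.atoms[i].residue_seq}/{c_dom.atoms[i].atom_name}",
                f"{n_dom.atoms[j].residue_seq}/{n_dom.atoms[j].atom_name}",
            )
            best = (val, p, names)
    if best is None:
        raise ValueError(f"no partner of monomer {k} has N-domain atoms")
    return GrooveWidthEntry(
        k=k,
        width=best[0],
        partner=best[1],
        atoms=best[2],
        truncated=len(existing) < len(partners),
    )


def groove_width_profile(f: Filament, ann: MonomerAnnotation) -> list[GrooveWidthEntry]:
    out = []
    for k in range(len(f)):
        if k + 5 >= len(f):
            break
        out.append(groove_width(f, ann, k))
    return out


def cross_groove_contacts(
    f: Filament, i: int, j: int, cutoff: float = 4.0
) -> list[tuple[int, int, float]]:
    """Residue pairs (one residue from monomer ``i``, one from ``j``)
    whose minimum heavy-atom distance is within ``cutoff``, sorted by
    distance.  Returns (residue_seq_i, residue_seq_j, distance)."""
    a = select(f.monomers[i], heavy_only=True)
    b = select(f.monomers[j], heavy_only=True)
    results: list[tuple[int, int, float]] = []
    res_a = a.residues()
    res_b = b.residues()
    for (ka, atoms_a) in res_a:
        pa = np.array([x.position for x in atoms_a])
        for (kb, atoms_b) in res_b:
            pb = np.array([x.position for x in atoms_b])
            d = float(cdist(pa, pb).min())
            if d <= cutoff:
                results.append((ka[1], kb[1], d))
    results.sort(key=lambda r: r[2])
    return results


# ---------------------------------------------------------------------
# base-pairing detection


class CriterionConfigError(ValueError):
    """Malformed pairing-criterion configuration."""


@dataclass(frozen=True)
class PairingCriterion:
    """One geometric pairing rule: residue-name roles plus distance
    clauses (every clause must hold; a clause is an OR over alternative
    atom-pair conditions)."""

    label: str
    roles: dict
    clauses: tuple

    @property
    def n_roles(self) -> int:
        return len(self.roles)


def _validate_condition(cond: dict, roles: dict, label: str) -> None:
    for key in ("i", "j", "atom_i", "atom_j", "max"):
        if key not in cond:
            raise CriterionConfigError(f"{label}: condition missing key {key!r}")
    for role_key in (cond["i"], cond["j"]):
        if role_key not in roles:
            raise CriterionConfigError(f"{label}: unknown role {role_key!r}")
    for atom in (cond["atom_i"], cond["atom_j"]):
        if atom not in _NUCLEOTIDE_ATOMS:
            raise CriterionConfigError(f"{label}: unknown atom name {atom!r}")
    if not (isinstance(cond["max"], (int, float)) and cond["max"] > 0):
        raise CriterionConfigError(f"{label}: max distance must be positive")


def load_criteria(path_or_dict) -> list[PairingCriterion]:
    """Load pairing criteria from a YAML file path or a parsed mapping."""
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        with open(path_or_dict) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "criteria" not in doc:
        raise CriterionConfigError("criteria document must have a 'criteria' list")
    out: list[PairingCriterion] = []
    for entry in doc["criteria"]:
        label = entry.get("label")
        roles = entry.get("roles")
        clauses = entry.get("clauses")
        if not label or not roles or not clauses:
            raise CriterionConfigError("criterion needs label, roles and clauses")
        for clause in clauses:
            if not clause:
                raise CriterionConfigError(f"{label}: empty clause")
            for cond in clause:
                _validate_condition(cond, roles, label)
        out.append(
            PairingCriterion(
                label=label,
                roles={k: tuple(v) for k, v in roles.items()},
                clauses=tuple(tuple(dict(c) for c in clause) for clause in clauses),
            )
        )
    return out


def default_criteria() -> list[PairingCriterion]:
    ref = resources.files("filaweaver").joinpath("data/pairing_criteria.yaml")
    with ref.open() as fh:
        return load_criteria(yaml.safe_load(fh))


@dataclass(frozen=True)
class PairingRecord:
    """A detected pairing: which bases, under which criterion, at which
    realized distances (one per satisfied clause)."""

    frame: int
    bases: tuple
    label: str
    distances: tuple


def _residue_table(strand) -> list[tuple[tuple[str, int, str], dict]]:
    st = strand.structure if isinstance(strand, StrandModel) else strand
    out = []
    for key, atoms in st.residues():
        out.append((key, {a.atom_name: a.position for a in atoms}))
    return out


def _positions_from_frame(frame: Structure) -> dict:
    return {(a.chain_id, a.residue_seq, a.atom_name): a.position for a in frame.atoms}


def _atom_pos(res_key, res_atoms, atom_name, frame_lut):
    if frame_lut is not None:
        return frame_lut.get((res_key[0], res_key[1], atom_name))
    return res_atoms.get(atom_name)


def _eval_criterion(crit: PairingCriterion, assignment: dict, frame_lut) -> tuple | None:
    """Return realized distances (one per clause) or None."""
    realized = []
    for clause in crit.clauses:
        best = None
        for cond in clause:
            key_i, atoms_i = assignment[cond["i"]]
            key_j, atoms_j = assignment[cond["j"]]
            pi = _atom_pos(key_i, atoms_i, cond["atom_i"], frame_lut)
            pj = _atom_pos(key_j, atoms_j, cond["atom_j"], frame_lut)
            if pi is None or pj is None:
                continue
            d = float(np.linalg.norm(pi - pj))
            if d <= cond["max"] and (best is None or d < best):
                best = d
        if best is None:
            return None
        realized.append(best)
    return tuple(realized)


def detect_pairs(
    bases_a,
    bases_b,
    criteria: list[PairingCriterion] | None = None,
    frame: Structure | None = None,
    bases_c=None,
    frame_index: int = 0,
) -> list[PairingRecord]:
    """Detect base pairings (and, when ``bases_c`` is given, triplets)
    between strands under geometric criteria.

    Coordinates come from the strands themselves unless ``frame`` is
    given, in which case atoms are looked up in the frame by (chain,
    residue, atom name) — the standard way to scan trajectory models.
    Two-role criteria are tried in both residue-role assignments.
    """
    if criteria is None:
        criteria = default_criteria()
    frame_lut = _positions_from_frame(frame) if frame is not None else None
    ra = _residue_table(bases_a)
    rb = _residue_table(bases_b)
    rc = _residue_table(bases_c) if bases_c is not None else None
    records: list[PairingRecord] = []
    for crit in criteria:
        role_names = sorted(crit.roles)
        if crit.n_roles == 2 and rc is None:
            r1, r2 = role_names
            for key_a, atoms_a in ra:
                for key_b, atoms_b in rb:
                    for assignment in (
                        {r1: (key_a, atoms_a), r2: (key_b, atoms_b)},
                        {r1: (key_b, atoms_b), r2: (key_a, atoms_a)},
                    ):
                        if not all(
                            assignment[r][0][2] in crit.roles[r] for r in role_names
                        ):
                            continue
                        dists = _eval_criterion(crit, assignment, frame_lut)
                        if dists is not None:
                            records.append(
                                PairingRecord(
                                    frame_index,
                                    (key_a, key_b),
                                    crit.label,
                                    dists,
                                )
                            )
                            break
        elif crit.n_roles == 3 and rc is not None:
            ka, kb, kc = role_names
            for key_a, atoms_a in ra:
                if key_a[2] not in crit.roles[ka]:
                    continue
                for key_b, atoms_b in rb:
                    if key_b[2] not in crit.roles[kb]:
                        continue
                    for key_c, atoms_c in rc:
                        if key_c[2] not in crit.roles[kc]:
                            continue
                        assignment = {
                            ka: (key_a, atoms_a),
                            kb: (key_b, atoms_b),
                            kc: (key_c, atoms_c),
                        }
                        dists = _eval_criterion(crit, assignment, frame_lut)
                        if dists is not None:
                            records.append(
                                PairingRecord(
                                    frame_index,
                                    (key_a, key_b, key_c),
                                    crit.label,
                                    dists,
                                )
                            )
    return records


# ---------------------------------------------------------------------
# duplex masks and stacking


def melting_bubble(paired_mask) -> list[tuple[int, int]]:
    """Maximal runs of consecutive unpaired positions in a duplex mask.

    ``paired_mask[i]`` is truthy when position i is paired.  Returns
    ``(start, length)`` per run, start being the 0-based mask index.  A
    six-position run is the melting-bubble signature of a kinked region.
    """
    runs: list[tuple[int, int]] = []
    start = None
    for i, paired in enumerate(paired_mask):
        if not paired and start is None:
            start = i
        elif paired and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(paired_mask) - start))
    return runs


def _ring_geometry(atoms: list[AtomRecord]) -> tuple[np.ndarray, np.ndarray]:
    ring = np.array(
        [a.position for a in atoms if a.atom_name in _RING_ATOMS and not a.is_hydrogen]
    )
    if len(ring) < 3:
        raise ValueError(
            f"base {atoms[0].chain_id}/{atoms[0].residue_seq} has "
            f"{len(ring)} ring atoms (< 3)"
        )
    centroid = ring.mean(axis=0)
    _, _, vt = np.linalg.svd(ring - centroid)
    return centroid, vt[2]


def stacking_partition(
    s: StrandModel, dist_cutoff: float = 4.5, angle_cutoff: float = 30.0
) -> list[int]:
    """Partition the strand into maximal stacked runs.

    Consecutive bases are stacked when their ring centroids are within
    ``dist_cutoff`` A and their ring planes within ``angle_cutoff``
    degrees.  Regular filament-bound DNA partitions into triplets (one
    per monomer); run lengths always sum to the number of bases.
    """
    geoms = [_ring_geometry(s.nucleotide(n)) for n in range(1, s.n_nucleotides + 1)]
    runs: list[int] = []
    current = 1
    for (c1, n1), (c2, n2) in zip(geoms, geoms[1:]):
        dist = float(np.linalg.norm(c2 - c1))
        cosang = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
        angle = math.degrees(math.acos(cosang))
        if dist <= dist_cutoff and angle <= angle_cutoff:
            current += 1
        else:
            runs.append(current)
            current = 1
    runs.append(current)
    return runs


def interstrand_proximity(
    a: StrandModel, b: StrandModel, frame: Structure | None = None
) -> np.ndarray:
    """Per-nucleotide profile: for each nucleotide of ``a``, the minimum
    heavy-atom distance to any heavy atom of ``b``."""
    lut = _positions_from_frame(frame) if frame is not None else None

    def _coords(strand: StrandModel, n: int | None = None) -> np.ndarray:
        if n is None:
            atoms = [x for x in strand.structure.atoms if not x.is_hydrogen]
        else:
            atoms = [x for x in strand.nucleotide(n) if not x.is_hydrogen]
        pos = []
        for x in atoms:
            p = lut.get((x.chain_id, x.residue_seq, x.atom_name)) if lut else x.position
            if p is not None:
                pos.append(p)
        return np.array(pos)

    b_all = _coords(b)
    out = np.empty(a.n_nucleotides)
    for n in range(1, a.n_nucleotides + 1):
        out[n - 1] = float(cdist(_coords(a, n), b_all).min())
    return out
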