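"""DNA threading into filaments and stretch/unwinding metrics.

Recombinase filaments bind DNA in base triplets: each monomer carries
three nucleotides in a fixed local binding geometry, so a strand is built
by repeating a trinucleotide template with every monomer placement.  The
resulting strand follows the filament helix — with roughly 6 monomers
(18.6 nucleotides) per turn of an extended filament versus 10.5 bp per
turn of B-DNA, it is strongly stretched and unwound.  Deviations of the
filament geometry from regular (a mixed ATP/ADP interface, a kink) show up
as breaks of the strand's O3'-P backbone continuity, which this module
detects and reports (never repairs).

Reference B-form values: rise 3.38 A and twist 34.3 deg per step by
default (36.0 deg selectable); both conventions are in common use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .filament_builder import Filament
from .screw_geometry import RigidTransform
from .structure_io import AtomRecord, Structure

__all__ = [
    "StrandModel",
    "BackboneBreak",
    "SITE_CHAIN_IDS",
    "thread_strand",
    "backbone_breaks",
    "stretch_percent",
    "unwinding_percent",
    "end_to_end",
    "blend_junction",
    "B_DNA_RISE",
    "B_DNA_TWIST",
]

B_DNA_RISE = 3.38  # A per base step
B_DNA_TWIST = 34.3  # deg per base step

SITE_CHAIN_IDS = {"I_incoming": "I", "I_complementary": "J", "II_outgoing": "K"}

_BASE_LETTER = {
    "DA": "A", "DT": "T", "DG": "G", "DC": "C",
    "A": "A", "T": "T", "G": "G", "C": "C",
    "ADE": "A", "THY": "T", "GUA": "G", "CYT": "C",
}


@dataclass
class StrandModel:
    """A threaded DNA strand with per-nucleotide provenance.

    ``placed_by[n]`` is the filament monomer index whose placement
    generated nucleotide n (0-based); ``site`` is one of I_incoming,
    I_complementary, II_outgoing.  Nucleotides are numbered 1..N in 5'->3'
    order of increasing monomer index.
    """

    structure: Structure
    site: str
    placed_by: list[int]
    sequence: str

    def __post_init__(self) -> None:
        if len(self.placed_by) != self.n_nucleotides:
            raise ValueError("placed_by length must equal nucleotide count")

    @property
    def n_nucleotides(self) -> int:
        return len(self.structure.residues())

    def nucleotide(self, n: int) -> list[AtomRecord]:
        """Atoms of 1-based nucleotide n."""
        res = self.structure.residues()
        if not 1 <= n <= len(res):
            raise IndexError(f"nucleotide {n} outside 1..{len(res)}")
        return res[n - 1][1]

    def atom_position(self, n: int, atom_name: str) -> np.ndarray:
        for a in self.nucleotide(n):
            if a.atom_name == atom_name:
                return a.position
        _, seq, name = self.structure.residues()[n - 1][0]
        raise KeyError(f"atom {atom_name!r} missing from nucleotide {n} ({name} {seq})")

    def phosphates(self) -> np.ndarray:
        return np.array([self.atom_position(n, "P") for n in range(1, self.n_nucleotides + 1)])

    def copy(self) -> "StrandModel":
        return StrandModel(self.structure.copy(), self.site, list(self.placed_by), self.sequence)


@dataclass(frozen=True)
class BackboneBreak:
    """O3'(n)-P(n+1) distance exceeding the continuity threshold."""

    between: tuple[int, int]
    o3_p_distance: float


def _template_residues(template: Structure) -> list[tuple[tuple[str, int, str], list[AtomRecord]]]:
    res = template.residues()
    if len(res) != 3:
        raise ValueError(f"template must hold exactly 3 nucleotides, got {len(res)}")
    return res


def thread_strand(
    f: Filament,
    template: Structure,
    site: str,
    monomer_indices: list[int] | None = None,
) -> StrandModel:
    """Thread a strand through the filament by repeating a trinucleotide
    template (given in the reference-monomer frame) with each monomer's
    placement, conserving the template's binding geometry per monomer.
    Nucleotides are renumbered contiguously 1..3n."""
    if site not in SITE_CHAIN_IDS:
        raise ValueError(f"unknown site {site!r}; expected one of {sorted(SITE_CHAIN_IDS)}")
    res = _template_residues(template)
    if monomer_indices is None:
        monomer_indices = list(range(len(f)))
    if any(b - a != 1 for a, b in zip(monomer_indices, monomer_indices[1:])):
        raise ValueError("monomer indices must be contiguous and ascending")
    for k in monomer_indices:
        if not 0 <= k < len(f):
            raise IndexError(f"monomer index {k} outside filament of length {len(f)}")
    chain = SITE_CHAIN_IDS[site]
    atoms: list[AtomRecord] = []
    placed_by: list[int] = []
    seq_letters: list[str] = []
    serial = 0
    nt = 0
    for k in monomer_indices:
        placement = f.placements[k]
        for (_, _, resname), res_atoms in res:
            nt += 1
            placed_by.append(k)
            seq_letters.append(_BASE_LETTER.get(resname, "N"))
            for a in res_atoms:
                serial += 1
                atoms.append(
                    replace(
                        a,
                        serial=serial,
                        chain_id=chain,
                        residue_seq=nt,
                        position=placement.apply(a.position),
                    )
                )
    return StrandModel(Structure(atoms), site, placed_by, "".join(seq_letters))


def backbone_breaks(s: StrandModel, threshold: float = 2.0) -> list[BackboneBreak]:
    """Consecutive-nucleotide pairs whose O3'(n)-P(n+1) distance exceeds
    ``threshold`` (default 2.0 A; the covalent bond is about 1.6 A)."""
    breaks: list[BackboneBreak] = []
    for n in range(1, s.n_nucleotides):
        o3 = s.atom_position(n, "O3'")
        p = s.atom_position(n + 1, "P")
        d = float(np.linalg.norm(p - o3))
        if d > threshold:
            breaks.append(BackboneBreak((n, n + 1), d))
    return breaks


def _unit(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float).reshape(3)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("zero axis vector")
    return axis / n


def stretch_percent(
    s: StrandModel, axis: np.ndarray, reference_rise: float = B_DNA_RISE
) -> float:
    """Stretch of the strand relative to B-DNA, in percent.

    The per-step rise is the projection of each P(n)->P(n+1) step on the
    filament axis (which should point 5'->3'); the return value is
    100 x (mean_rise / reference_rise - 1), so +50 means stretched by 50%.
    """
    if s.n_nucleotides < 2:
        raise ValueError("need >= 2 nucleotides")
    u = _unit(axis)
    steps = np.diff(s.phosphates(), axis=0)
    mean_rise = float(np.mean(steps @ u))
    return 100.0 * (mean_rise / reference_rise - 1.0)


def unwinding_percent(
    s: StrandModel,
    axis: np.ndarray,
    reference_twist: float = B_DNA_TWIST,
    axis_point: np.ndarray = (0.0, 0.0, 0.0),
) -> float:
    """Unwinding relative to B-DNA, in percent.

    The per-step twist is the angle between successive phosphate positions
    projected onto the plane perpendicular to the filament axis, measured
    about that axis; the return value is 100 x (1 - mean_twist /
    reference_twist), so +40 means unwound by 40%.  Steps whose phosphate
    projects onto the axis are skipped with a warning.
    """
    if s.n_nucleotides < 2:
        raise ValueError("need >= 2 nucleotides")
    u = _unit(axis)
    p0 = np.asarray(axis_point, dtype=float).reshape(3)
    rel = s.phosphates() - p0
    radial = rel - np.outer(rel @ u, u)
    twists: list[float] = []
    for a, b in zip(radial, radial[1:]):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-9 or nb < 1e-9:
            warnings.warn("phosphate projects onto the filament axis; step skipped", stacklevel=2)
            continue
        c = float(np.clip(np.dot(a / na, b / nb), -1.0, 1.0))
        twists.append(math.degrees(math.acos(c)))
    if not twists:
        raise ValueError("no usable steps for twist computation")
    return 100.0 * (1.0 - float(np.mean(twists)) / reference_twist)


def end_to_end(s: StrandModel, frm: int, to: int) -> float:
    """Distance (A) between the P atoms of nucleotides ``frm`` and ``to``
    (1-based, frm < to)."""
    if frm >= to:
        raise ValueError(f"need frm < to, got {frm} >= {to}")
    return float(np.linalg.norm(s.atom_position(to, "P") - s.atom_position(frm, "P")))


def blend_junction(
    s: StrandModel,
    f: Filament,
    template: Structure,
    junction: int,
) -> StrandModel:
    """Naive geometric closure of the backbone at a perturbed interface.

    Re-places the triplet of nucleotides carried by monomer ``junction+1``
    using placements interpolated between the two flanking monomer
    placements (rotation slerp, translation lerp, fractions 1/4, 2/4,
    3/4 beyond monomer ``junction``).  This is a cosmetic geometric blend,
    not a physical repair of the strand: use it only to produce visually
    continuous models.
    """
    from scipy.spatial.transform import Rotation, Slerp

    if not 0 <= junction < len(f) - 1:
        raise IndexError("junction must name an interface (0..n-2)")
    res = _template_residues(template)
    pa, pb = f.placements[junction], f.placements[junction + 1]
    rots = Rotation.from_matrix(np.stack([pa.rotation, pb.rotation]))
    slerp = Slerp([0.0, 1.0], rots)
    out = s.copy()
    target = junction + 1
    # map: nucleotide index -> its position within the monomer triplet
    for n0, k in enumerate(out.placed_by):
        if k != target:
            continue
        frac = ((n0 % 3) + 1) / 4.0
        R = slerp([frac]).as_matrix()[0]
        t = (1 - frac) * pa.translation + frac * pb.translation
        placement = RigidTransform(R, t)
        tmpl_atoms = res[n0 % 3][1]
        by_name = {a.atom_name: a.position for a in tmpl_atoms}
        for a in out.nucleotide(n0 + 1):
            if a.atom_name in by_name:
                a.position = placement.apply(by_name[a.atom_name])
    return out
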