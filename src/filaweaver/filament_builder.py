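"""Filament construction from a monomer template and interface transforms.

A filament is a chain of placed monomer copies.  Each interface carries a
binding-geometry label — ATP (extended-form geometry) or ADP
(compressed-form geometry) — and the transform of that label is applied
*in the frame of the upstream monomer*: placement(k+1) = placement(k) o
t_label.  This convention guarantees that the local screw across interface
k equals the labelled binding geometry, which is exactly what "monomer (i)
switched to an ADP-binding interface with (i+1)" means.  Inserting a
single ADP interface in an otherwise extended filament kinks the helical
axis; the kink angle between the two flanking segments is the headline
geometric observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .screw_geometry import (
    RigidTransform,
    ScrewParams,
    angle_between_axes,
    compose,
    screw_from_transform,
    superpose,
)
from .structure_io import AtomRecord, Structure, select

__all__ = [
    "Filament",
    "MonomerAnnotation",
    "interface_transform",
    "build_regular",
    "build_mixed",
    "graft_region",
    "kink_angle",
]

ATP = "ATP"
ADP = "ADP"


@dataclass
class MonomerAnnotation:
    """Author-numbered residue ranges of the RecA monomer regions used in
    groove and grafting analyses.  Defaults follow the crystal-structure
    conventions: N-terminal domain 1-37, flexible loops L1 157-164 and
    L2 194-210, LexA-binding loop 225-245.  The C-terminal domain has no
    canonical numeric definition; 270-328 is used (the cross-groove contact
    residues 287-297 fall inside it) and is configurable."""

    n_domain: tuple[int, int] = (1, 37)
    c_domain: tuple[int, int] = (270, 328)
    loop_L1: tuple[int, int] = (157, 164)
    loop_L2: tuple[int, int] = (194, 210)
    lexa_loop: tuple[int, int] = (225, 245)

    def __post_init__(self) -> None:
        for name in ("n_domain", "c_domain", "loop_L1", "loop_L2", "lexa_loop"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range [{lo},{hi}] has lo > hi")
        a, b = self.loop_L1, self.loop_L2
        if not (a[1] < b[0] or b[1] < a[0]):
            raise ValueError("loops L1 and L2 overlap")

    def core_exclusions(self) -> list[tuple[int, int]]:
        """Ranges excluded from conserved-core superpositions: the mobile
        N-terminal domain and the flexible loops."""
        return [self.n_domain, self.loop_L1, self.loop_L2]


@dataclass
class Filament:
    """Ordered monomer copies with their placement transforms.

    ``placements[k]`` maps the reference-monomer frame onto monomer k's
    frame; ``monomers[k]`` already has it applied.  ``index_offset`` shifts
    display indices so a dodecamer can be reported as (i-5)...(i+6) with
    i-5 at offset -5.
    """

    monomers: list[Structure]
    placements: list[RigidTransform]
    interfaces: list[str]
    index_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.placements) != len(self.monomers):
            raise ValueError("one placement per monomer required")
        if len(self.interfaces) != max(len(self.monomers) - 1, 0):
            raise ValueError("need n-1 interface labels for n monomers")

    def __len__(self) -> int:
        return len(self.monomers)

    def display_index(self, k: int) -> int:
        return k + self.index_offset

    def interface_screw(self, k: int, frame: str = "local") -> ScrewParams:
        """Screw of interface k (between monomers k and k+1).

        ``frame="local"`` expresses it in the upstream monomer's frame,
        where it equals the labelled binding geometry; ``"global"`` gives
        the transform that moves placed monomer k onto placed monomer k+1
        in laboratory coordinates (its axis is the local helix axis).
        """
        g = compose(self.placements[k + 1], self.placements[k].inverse())
        if frame == "global":
            return screw_from_transform(g)
        pk = self.placements[k]
        local = compose(pk.inverse(), compose(g, pk))
        return screw_from_transform(local)

    def to_structure(self, chain_ids: list[str] | None = None) -> Structure:
        """Merge monomers into one model, one chain per monomer."""
        if chain_ids is None:
            alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
            chain_ids = [alphabet[k % len(alphabet)] for k in range(len(self))]
        atoms: list[AtomRecord] = []
        serial = 0
        for k, mono in enumerate(self.monomers):
            for a in mono.atoms:
                serial += 1
                atoms.append(
                    replace(a, serial=serial, chain_id=chain_ids[k], position=a.position.copy())
                )
        return Structure(atoms)


def interface_transform(
    s: Structure,
    chain_a: str,
    chain_b: str,
    ann: MonomerAnnotation | None = None,
    match_atoms: str | set[str] = "CA",
) -> RigidTransform:
    """Binding geometry between two chains of one structure: the transform
    superposing chain_a onto chain_b over the conserved core (flexible
    loops and the N-terminal domain excluded when an annotation is given).
    Applied repeatedly to a monomer it regenerates the filament."""
    a = select(s, chain=chain_a)
    b = select(s, chain=chain_b)
    if a.empty_selection or b.empty_selection:
        missing = chain_a if a.empty_selection else chain_b
        raise ValueError(f"chain {missing!r} not present")
    exclude = ann.core_exclusions() if ann is not None else None
    t, _ = superpose(a, b, match_atoms=match_atoms, exclude_ranges=exclude)
    return t


def build_regular(monomer: Structure, t: RigidTransform, n: int, label: str = ATP) -> Filament:
    """Regular filament: monomer k placed by t composed k times."""
    if n < 1:
        raise ValueError("need n >= 1 monomers")
    placements = [RigidTransform.identity()]
    for _ in range(n - 1):
        placements.append(compose(placements[-1], t))
    monomers = [p.apply_structure(monomer) for p in placements]
    return Filament(monomers, placements, [label] * (n - 1))


def build_mixed(
    monomer: Structure,
    t_atp: RigidTransform,
    t_adp: RigidTransform,
    pattern: list[str],
    index_offset: int = 0,
) -> Filament:
    """Mixed-interface filament from an interface-label pattern.

    Each label's transform is applied in the frame of the upstream monomer:
    placement(k+1) = placement(k) o t_label.  The reference construction is
    five ATP interfaces, one ADP interface, five ATP interfaces — a
    dodecamer whose single ADP interface sits between monomers (i) and
    (i+1) when ``index_offset=-5``.
    """
    lut = {ATP: t_atp, ADP: t_adp}
    for lab in pattern:
        if lab not in lut:
            raise ValueError(f"unknown interface label {lab!r}")
    placements = [RigidTransform.identity()]
    for lab in pattern:
        placements.append(compose(placements[-1], lut[lab]))
    monomers = [p.apply_structure(monomer) for p in placements]
    return Filament(monomers, placements, list(pattern), index_offset=index_offset)


MIXED_DODECAMER_PATTERN = [ATP] * 5 + [ADP] + [ATP] * 5
"""Reference mixed pattern: 12 monomers, single ADP interface at the center
(monomers (i-5)..(i+6) with the switched interface between (i) and (i+1))."""


def graft_region(
    target: Structure,
    source: Structure,
    region: tuple[int, int],
    anchor: tuple[int, int],
    match_atoms: str | set[str] = "CA",
) -> Structure:
    """Replace ``target``'s residues in ``region`` by the corresponding
    residues of ``source``, after superposing ``source`` onto ``target``
    over the ``anchor`` residue range.

    This is how a conformer-specific region (e.g. the compressed-form
    N-terminal domain, residues 1-37) is transplanted onto a monomer of the
    other conformation, and how disordered loops are assigned the geometry
    of the ordered conformer.
    """
    for name, st, rng in (("region", source, region), ("anchor", source, anchor), ("anchor", target, anchor)):
        present = {a.residue_seq for a in st.atoms}
        missing = [r for r in range(rng[0], rng[1] + 1) if r not in present]
        if missing:
            raise ValueError(f"{name} residues absent from structure: {missing}")
    t, _ = superpose(source, target, match_atoms=match_atoms, residue_ranges=[anchor])
    moved = t.apply_structure(source)
    lo, hi = region
    grafted = select(moved, residue_range=(lo, hi))
    out: list[AtomRecord] = []
    inserted = False
    for a in target.atoms:
        if lo <= a.residue_seq <= hi:
            if not inserted:
                out.extend(x.copy() for x in grafted.atoms)
                inserted = True
            continue
        out.append(a.copy())
    if not inserted:  # region absent from target: append in order
        out.extend(x.copy() for x in grafted.atoms)
    result = Structure(out, target.model_index)
    for serial, a in enumerate(result.atoms, start=1):
        a.serial = serial
    return result


def _segment_axis(f: Filament, indices: list[int]) -> np.ndarray:
    """Mean global-frame screw-axis direction over a segment's interfaces."""
    axes = []
    for k in indices:
        s = f.interface_screw(k, frame="global").canonical()
        axes.append(s.axis_direction)
    axes = np.array(axes)
    ref = axes[0]
    for i in range(1, len(axes)):  # align hemispheres before averaging
        if np.dot(axes[i], ref) < 0:
            axes[i] = -axes[i]
    mean = axes.mean(axis=0)
    n = np.linalg.norm(mean)
    if n < 1e-9:
        raise ValueError("segment axis direction is ill-defined")
    return mean / n


def kink_angle(f: Filament, split_after: int) -> float:
    """Angle (degrees) between the helical-axis directions of the two
    filament segments obtained by splitting after monomer ``split_after``
    (0-based internal index).  Each segment needs at least two monomers."""
    n = len(f)
    up = list(range(0, split_after))            # interfaces 0..split_after-1
    down = list(range(split_after + 1, n - 1))  # interfaces after the split
    if not up or not down:
        raise ValueError("each segment needs >= 2 monomers (>= 1 interface)")
    return angle_between_axes(_segment_axis(f, up), _segment_axis(f, down))
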