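"""Atomic-structure container and PDB input/output.

The package manipulates filament models as flat, ordered atom tables in
author (1-based) residue numbering — the numbering every RecA region of
interest (N-terminal domain 1-37, loops L1 157-164 and L2 194-210, the
LexA-binding loop 225-245, C-terminal contact residues 287-297) is quoted
in.  Parsing and serialisation of the PDB format are delegated to gemmi;
this module only adapts between gemmi's hierarchy and the flat table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "PDBError",
    "read_structure",
    "write_structure",
    "select",
]

_MAX_PDB_ATOMS = 99_999


class PDBError(ValueError):
    """Raised for malformed, unsupported or unwritable PDB content."""


@dataclass
class AtomRecord:
    """One atom of a model, in author numbering.

    ``position`` is a length-3 float array in Angstrom.  ``element`` is
    inferred from PDB columns 77-78 when present, else from the atom-name
    convention; it is never empty.
    """

    serial: int
    atom_name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    element: str = ""
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise PDBError(
                f"non-finite coordinates for atom {self.atom_name} "
                f"{self.chain_id}/{self.residue_seq}"
            )
        if not self.element:
            self.element = _element_from_name(self.atom_name)
        self.is_hydrogen = self.element in ("H", "D")

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())


def _element_from_name(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise PDBError("empty atom name")
    # PDB convention: digits may prefix hydrogens (e.g. 1HB2); the element
    # is the first alphabetic character for standard residues.
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise PDBError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class Structure:
    """Ordered atom table for one model.

    Invariants: ``(chain_id, residue_seq, atom_name)`` is unique within a
    model; residue order within a chain is non-decreasing.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    model_index: int = 1
    empty_selection: bool = False  # warning flag set by `select`

    # -- basic views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, self.model_index)

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], self.model_index)

    def residues(self) -> list[tuple[tuple[str, int, str], list[AtomRecord]]]:
        """Group atoms by (chain_id, residue_seq, residue_name), in order."""
        out: list[tuple[tuple[str, int, str], list[AtomRecord]]] = []
        key = None
        for a in self.atoms:
            k = (a.chain_id, a.residue_seq, a.residue_name)
            if k != key:
                out.append((k, []))
                key = k
            out[-1][1].append(a)
        return out

    def atom(self, chain_id: str | None, residue_seq: int, atom_name: str) -> AtomRecord:
        for a in self.atoms:
            if (
                a.residue_seq == residue_seq
                and a.atom_name == atom_name
                and (chain_id is None or a.chain_id == chain_id)
            ):
                return a
        raise KeyError(f"atom {chain_id}/{residue_seq}/{atom_name} not found")

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        last: dict[str, int] = {}
        for a in self.atoms:
            k = (a.chain_id, a.residue_seq, a.atom_name)
            if k in seen:
                raise PDBError(f"duplicate atom {k}")
            seen.add(k)
            prev = last.get(a.chain_id)
            if prev is not None and a.residue_seq < prev:
                raise PDBError(
                    f"residue order decreases in chain {a.chain_id} at {a.residue_seq}"
                )
            last[a.chain_id] = a.residue_seq


# -- reading ---------------------------------------------------------


def _prescan(path: str) -> None:
    """Light validation pass giving line-numbered errors for broken records."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBError(f"{path}:{lineno}: truncated {rec.strip()} record")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBError(
                        f"{path}:{lineno}: unparseable coordinate field "
                        f"{line[lo:hi]!r}"
                    ) from None
            icode = line[26]
            if icode not in (" ", ""):
                raise PDBError(
                    f"{path}:{lineno}: insertion code {icode!r} not supported"
                )


def read_structure(path: str, model: int | str = "all") -> list[Structure]:
    """Read a (possibly multi-model) PDB file.

    Returns one :class:`Structure` per MODEL record (a single one when the
    file has no MODEL framing).  ``model`` may be a 1-based model number or
    ``"all"``.  Alternate locations: blank or 'A' kept, others dropped.
    """
    _prescan(str(path))
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    models: list[Structure] = []
    dropped_altloc = 0
    for midx, gmodel in enumerate(st, start=1):
        atoms: list[AtomRecord] = []
        serial = 0
        for chain in gmodel:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("\0", "", "A"):
                        dropped_altloc += 1
                        continue
                    serial += 1
                    el = atom.element.name if atom.element else ""
                    atoms.append(
                        AtomRecord(
                            serial=serial,
                            atom_name=atom.name,
                            residue_name=res.name,
                            residue_seq=res.seqid.num,
                            chain_id=chain.name,
                            position=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                            element=el,
                        )
                    )
        s = Structure(atoms, model_index=midx)
        s.validate()
        models.append(s)
    if dropped_altloc:
        import warnings

        warnings.warn(f"dropped {dropped_altloc} non-'A' altloc atoms", stacklevel=2)
    if model == "all":
        return models
    midx = int(model)
    for s in models:
        if s.model_index == midx:
            return [s]
    raise PDBError(f"model {midx} not found in {path} ({len(models)} models)")


# -- writing ---------------------------------------------------------


def write_structure(
    models: list[Structure] | Structure,
    path: str,
    force_model_records: bool = False,
) -> None:
    """Write one or more models as a PDB file.

    MODEL/ENDMDL framing is emitted when more than one model is given (or
    when ``force_model_records`` is set).  Raises on an empty model list or
    on more atoms than plain PDB serial numbers can hold.
    """
    if isinstance(models, Structure):
        models = [models]
    if not models:
        raise PDBError("no models to write")
    for s in models:
        if len(s) > _MAX_PDB_ATOMS:
            raise PDBError(
                f"{len(s)} atoms exceed PDB serial capacity ({_MAX_PDB_ATOMS})"
            )
        for a in s.atoms:
            if not np.all(np.isfinite(a.position)):
                raise PDBError("non-finite coordinates")

    st = gemmi.Structure()
    st.name = "filaweaver"
    for s in models:
        gmodel = gemmi.Model(str(s.model_index))
        cur_chain = None
        cur_res = None
        cur_key: tuple[str, int, str] | None = None
        for a in s.atoms:
            if cur_chain is None or cur_chain.name != a.chain_id:
                cur_chain = gemmi.Chain(a.chain_id)
                gmodel.add_chain(cur_chain)
                cur_chain = gmodel[len(gmodel) - 1]
                cur_key = None
            key = (a.chain_id, a.residue_seq, a.residue_name)
            if key != cur_key:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_seq, " ")
                cur_chain.add_residue(res)
                cur_res = cur_chain[len(cur_chain) - 1]
                cur_key = key
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.pos = gemmi.Position(*a.position)
            atom.element = gemmi.Element(a.element)
            atom.occ = 1.0
            cur_res.add_atom(atom)
        st.add_model(gmodel)
    st.setup_entities()
    opts = gemmi.PdbWriteOptions()
    opts.minimal_file = True
    if len(models) == 1 and not force_model_records:
        st.write_minimal_pdb(str(path))
        return
    doc = st.make_pdb_string(opts)
    with open(path, "w") as fh:
        fh.write(doc)


# -- selection -------------------------------------------------------


def select(
    s: Structure,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    atom_names: set[str] | None = None,
    heavy_only: bool = False,
) -> Structure:
    """Subset a structure by chain, inclusive residue range and atom names.

    Order is preserved; an empty result is returned (not raised) with the
    ``empty_selection`` flag set.
    """
    if residue_range is not None:
        lo, hi = residue_range
        if lo > hi:
            raise ValueError(f"residue range [{lo},{hi}] has lo > hi")
    out: list[AtomRecord] = []
    for a in s.atoms:
        if chain is not None and a.chain_id != chain:
            continue
        if residue_range is not None and not (lo <= a.residue_seq <= hi):
            continue
        if atom_names is not None and a.atom_name not in atom_names:
            continue
        if heavy_only and a.is_hydrogen:
            continue
        out.append(a.copy())
    result = Structure(out, s.model_index)
    result.empty_selection = not out
    return result
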