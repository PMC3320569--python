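"""Role-tagged atomic snapshots and their PDB/XYZ serialization.

The trajectory analyses only need a handful of atom roles — water oxygens,
backbone-carbonyl oxygens of named filter residues, sidechain oxygens, and
the permeating ions — so frames carry an explicit role per atom rather than
a force-field topology.  PDB I/O goes through biotite with a documented
residue/atom-name mapping; XYZ files carry the roles verbatim in the
comment line, so they round-trip exactly.

Role kinds and tags:

===================== ==============================================
kind                  tag
===================== ==============================================
``water-O``           (empty)
``backbone-carbonyl-O`` residue, e.g. ``"THR175"``
``sidechain-O``       residue, e.g. ``"GLU177"``
``ion``               species: ``"Na"``, ``"K"`` or ``"Cl"``
===================== ==============================================

PDB mapping: water-O → HETATM ``O``/``HOH``; backbone carbonyl O → atom
``O`` of the named residue; sidechain O → the residue's canonical oxygen
atom name (``OE1`` for Glu, ``OG`` for Ser, ``OG1`` for Thr, ``OD1`` for
Asp, ``OH`` for Tyr); ions → HETATM with the element as residue and atom
name.  PDB coordinates are written at the format's 3-decimal precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRole",
    "Frame",
    "generate_structure_fixture",
    "water_oxygen",
    "backbone_oxygen",
    "sidechain_oxygen",
    "ion",
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "read_pdb",
]

ROLE_KINDS = ("water-O", "backbone-carbonyl-O", "sidechain-O", "ion")
ION_SPECIES = ("Na", "K", "Cl")

_SIDECHAIN_O_NAME = {"GLU": "OE1", "SER": "OG", "THR": "OG1", "ASP": "OD1", "TYR": "OH"}


@dataclass(frozen=True)
class AtomRole:
    kind: str
    tag: str = ""

    def __post_init__(self):
        if self.kind not in ROLE_KINDS:
            raise ValueError(f"unknown role kind {self.kind!r}")
        if self.kind == "ion" and self.tag not in ION_SPECIES:
            raise ValueError(f"unknown ion species {self.tag!r}")
        if self.kind in ("backbone-carbonyl-O", "sidechain-O") and not self.tag:
            raise ValueError(f"{self.kind} role needs a residue tag")

    def token(self) -> str:
        return f"{self.kind}:{self.tag}" if self.tag else self.kind

    @classmethod
    def from_token(cls, token: str) -> "AtomRole":
        kind, _, tag = token.partition(":")
        return cls(kind, tag)


def water_oxygen() -> AtomRole:
    return AtomRole("water-O")


def backbone_oxygen(residue: str) -> AtomRole:
    return AtomRole("backbone-carbonyl-O", residue.upper())


def sidechain_oxygen(residue: str) -> AtomRole:
    return AtomRole("sidechain-O", residue.upper())


def ion(species: str) -> AtomRole:
    return AtomRole("ion", species.capitalize())


@dataclass
class Frame:
    """A snapshot: unique atom identifiers, roles, coordinates (Å), time (ps)."""

    ids: list
    roles: list
    coords: np.ndarray  # (n, 3)
    time: float = 0.0
    _index: dict = field(default=None, repr=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        if not (len(self.ids) == len(self.roles) == coords.shape[0]):
            raise ValueError("ids, roles and coords must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate atom identifiers: {dupes}")
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, atom_id) -> int:
        return self._index[atom_id]

    def select(self, kind: str, tag: str = None) -> np.ndarray:
        """Indices of atoms with the given role kind (and tag, if given)."""
        return np.array(
            [
                i
                for i, r in enumerate(self.roles)
                if r.kind == kind and (tag is None or r.tag == tag)
            ],
            dtype=int,
        )


def generate_structure_fixture(spec, time: float = 0.0) -> Frame:
    """Build a Frame from (id, role, (x, y, z)) placements.

    Roles may be :class:`AtomRole` instances or role tokens such as
    ``"water-O"`` or ``"sidechain-O:GLU177"``.  Duplicate identifiers are
    rejected.
    """
    ids, roles, coords = [], [], []
    for atom_id, role, xyz in spec:
        ids.append(atom_id)
        roles.append(role if isinstance(role, AtomRole) else AtomRole.from_token(role))
        coords.append(tuple(float(v) for v in xyz))
    return Frame(
        ids=ids,
        roles=roles,
        coords=np.array(coords, dtype=float).reshape(-1, 3),
        time=time,
    )


# -- XYZ (roles kept verbatim in the comment line) -------------------------


def _element_of(role: AtomRole) -> str:
    return role.tag if role.kind == "ion" else "O"


def write_xyz(frame: Frame, path):
    lines = [str(len(frame))]
    tokens = ",".join(r.token() for r in frame.roles)
    comment = f"t={frame.time:g} roles={tokens}"
    ids = [str(i) for i in frame.ids]
    if all("," not in i and " " not in i for i in ids):
        comment += f" ids={','.join(ids)}"
    lines.append(comment)
    for role, xyz in zip(frame.roles, frame.coords):
        lines.append(
            f"{_element_of(role):<2s} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> Frame:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0])
    time = 0.0
    tokens = []
    ids = None
    for fieldstr in lines[1].split():
        key, _, val = fieldstr.partition("=")
        if key == "t":
            time = float(val)
        elif key == "roles":
            tokens = val.split(",") if val else []
        elif key == "ids":
            ids = val.split(",") if val else []
    if len(tokens) != n:
        raise ValueError(f"{path}: comment line lists {len(tokens)} roles for {n} atoms")
    roles = [AtomRole.from_token(t) for t in tokens]
    coords = []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        coords.append([float(v) for v in parts[1:4]])
    if ids is None or len(ids) != n:
        ids = [f"{r.token()}#{i}" for i, r in enumerate(roles)]
    return Frame(ids=ids, roles=roles, coords=np.array(coords), time=time)


# -- PDB via biotite --------------------------------------------------------


def _pdb_fields(role: AtomRole):
    """(res_name, res_id, atom_name, element, hetero) for a role."""
    if role.kind == "water-O":
        return "HOH", 0, "O", "O", True
    if role.kind == "ion":
        name = role.tag.upper()
        return name, 0, name, name, True
    res_name = role.tag[:3].upper()
    res_id = int(role.tag[3:])
    if role.kind == "backbone-carbonyl-O":
        return res_name, res_id, "O", "O", False
    return res_name, res_id, _SIDECHAIN_O_NAME.get(res_name, "OX1"), "O", False


def write_pdb(frame: Frame, path):
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(frame)
    atoms = struc.AtomArray(n)
    atoms.coord = frame.coords.astype(np.float32)
    for i, role in enumerate(frame.roles):
        res_name, res_id, atom_name, element, hetero = _pdb_fields(role)
        atoms.res_name[i] = res_name
        atoms.res_id[i] = res_id if res_id else i + 1
        atoms.atom_name[i] = atom_name
        atoms.element[i] = element
        atoms.hetero[i] = hetero
        atoms.chain_id[i] = "A"
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)


def _role_from_pdb(res_name, atom_name, res_id) -> AtomRole:
    res_name = res_name.strip().upper()
    atom_name = atom_name.strip().upper()
    if res_name == "HOH":
        return water_oxygen()
    if res_name in ("NA", "K", "CL"):
        return ion(res_name.capitalize())
    if atom_name == "O":
        return backbone_oxygen(f"{res_name}{res_id}")
    return sidechain_oxygen(f"{res_name}{res_id}")


def read_pdb(path, time: float = 0.0) -> Frame:
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(path).get_structure(model=1)
    ids, roles, coords = [], [], []
    for i in range(atoms.array_length()):
        role = _role_from_pdb(atoms.res_name[i], atoms.atom_name[i], atoms.res_id[i])
        roles.append(role)
        ids.append(f"{role.token()}#{i}")
        coords.append(atoms.coord[i])
    return Frame(ids=ids, roles=roles, coords=np.array(coords, dtype=float), time=time)
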