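"""Structures, trajectories, atom selection, and least-squares superposition.

This module is the substrate of every analysis stage: it reads fixed-column
PDB structures, CHARMM/NAMD DCD (via MDAnalysis' low-level reader), XYZ and
multi-model PDB trajectories, resolves a small selection language
("chain A and name CA"), and performs Kabsch superposition / trajectory
alignment onto a first-frame or iteratively refined average reference.

Internal indexing is 0-based throughout; the file-facing residue number
(``residue_seq``) is preserved verbatim so round-trips are lossless.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from ._elements import ELEMENT_MASS, ELEMENT_VDW, infer_element


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; names the offending line."""


class SelectionError(ValueError):
    """Raised for an unparsable or unresolvable selection descriptor."""


@dataclass
class Atom:
    """One atom with the per-atom parameters the analyses need.

    ``charge`` (e), ``vdw_radius`` (Å) and ``lj_epsilon`` (kcal/mol) back the
    SASA and molecular-mechanics terms; they default to the element table /
    zero and can be overridden from a delimited parameter table.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    residue_seq: int
    chain_id: str
    mass: float = 0.0
    charge: float = 0.0
    vdw_radius: float = 0.0
    lj_epsilon: float = 0.0


@dataclass
class Structure:
    """An ordered list of atoms plus one coordinate set (Å)."""

    atoms: list[Atom]
    coordinates: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {self.coordinates.shape} does not "
                f"match atom count {len(self.atoms)}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])


@dataclass
class Trajectory:
    """F frames of N×3 coordinates over a fixed topology."""

    structure: Structure
    frames: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.structure.n_atoms, 3):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.structure.n_atoms} atoms"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms


@dataclass
class AtomSelection:
    """Ordered, strictly increasing 0-based atom indices with provenance."""

    indices: np.ndarray
    descriptor: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class SuperpositionResult:
    """Rigid transform (proper rotation + translation) and the residual RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int, residue_tracker: dict) -> tuple[Atom, np.ndarray]:
    record = line[:6].strip()
    try:
        serial = int(line[6:11])
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed serial field {line[6:11]!r}")
    name = line[12:16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21:22].strip() or " "
    try:
        res_seq = int(line[22:26])
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed residue number {line[22:26]!r}")
    try:
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed coordinate columns {line[30:54]!r}")

    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name, record)
    if element not in ELEMENT_MASS:
        raise PDBParseError(
            f"line {lineno}: unknown element {element!r} for atom serial {serial}"
        )

    key = (chain_id, res_seq, res_name)
    if key not in residue_tracker:
        residue_tracker[key] = len(residue_tracker)
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        residue_index=residue_tracker[key],
        residue_name=res_name,
        residue_seq=res_seq,
        chain_id=chain_id,
        mass=ELEMENT_MASS[element],
        vdw_radius=ELEMENT_VDW[element],
    )
    return atom, xyz


def read_pdb(path) -> Structure:
    """Read a PDB v3 fixed-column file into a :class:`Structure`.

    One :class:`Atom` per ATOM/HETATM record; a MODEL-less file (or the first
    MODEL of a multi-model file) yields the structure. Element symbols missing
    from columns 77–78 are inferred from the atom name; masses and vdW radii
    come from the built-in element table.
    """
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    tracker: dict = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            n_lines += 1
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                atom, xyz = _parse_atom_line(line, lineno, tracker)
                atoms.append(atom)
                coords.append(xyz)
            elif rec == "ENDMDL":
                break
    if n_lines == 0:
        raise PDBParseError(f"{path}: empty file")
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms=atoms, coordinates=np.array(coords))


def _format_atom_line(atom: Atom, xyz: np.ndarray) -> str:
    name = atom.name
    # PDB convention: 1–3 character names start in column 14.
    fname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {atom.serial:>5d} {fname} {atom.residue_name:<3s} "
        f"{atom.chain_id:1s}{atom.residue_seq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}\n"
    )


def write_pdb(structure: Structure, path, frames: np.ndarray | None = None) -> None:
    """Write a structure (or a multi-model trajectory) as fixed-column PDB."""
    frame_list = [structure.coordinates] if frames is None else list(frames)
    multi = len(frame_list) > 1
    with open(path, "w") as fh:
        for m, coords in enumerate(frame_list, start=1):
            if multi:
                fh.write(f"MODEL     {m:>4d}\n")
            prev_chain = None
            for atom, xyz in zip(structure.atoms, coords):
                if prev_chain is not None and atom.chain_id != prev_chain:
                    fh.write("TER\n")
                fh.write(_format_atom_line(atom, xyz))
                prev_chain = atom.chain_id
            fh.write("TER\n")
            fh.write("ENDMDL\n" if multi else "END\n")


# ---------------------------------------------------------------------------
# Trajectory reading / writing
# ---------------------------------------------------------------------------

def _read_xyz_frames(path, n_atoms: int) -> np.ndarray:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].split()[0])
        except ValueError:
            raise ValueError(f"{path}: expected atom count at line {i + 1}")
        if count != n_atoms:
            raise ValueError(
                f"{path}: frame {frame_idx} has {count} atoms, topology has {n_atoms}"
            )
        block = lines[i + 2 : i + 2 + count]
        if len(block) < count:
            raise ValueError(f"{path}: truncated final frame {frame_idx}")
        frame = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(frame)
        i += 2 + count
        frame_idx += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return np.array(frames)


def _read_dcd_frames(path, n_atoms: int) -> np.ndarray:
    from MDAnalysis.lib.formats.libdcd import DCDFile

    frames = []
    with DCDFile(str(path)) as dcd:
        if dcd.header["natoms"] != n_atoms:
            raise ValueError(
                f"{path}: DCD has {dcd.header['natoms']} atoms, "
                f"topology has {n_atoms}"
            )
        for fr in dcd:
            frames.append(np.array(fr.xyz, dtype=float))
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return np.array(frames)


def _read_multimodel_pdb_frames(path, n_atoms: int) -> np.ndarray:
    frames = []
    current: list[np.ndarray] = []
    frame_idx = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                try:
                    current.append(
                        np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
                    )
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed coordinate columns"
                    )
            elif rec == "ENDMDL":
                if len(current) != n_atoms:
                    raise ValueError(
                        f"{path}: frame {frame_idx} has {len(current)} atoms, "
                        f"topology has {n_atoms}"
                    )
                frames.append(np.array(current))
                current = []
                frame_idx += 1
    if current:
        if len(current) != n_atoms:
            raise ValueError(
                f"{path}: truncated final frame {frame_idx} "
                f"({len(current)} of {n_atoms} atoms)"
            )
        frames.append(np.array(current))
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return np.array(frames)


_FORMAT_READERS = {
    "dcd": _read_dcd_frames,
    "xyz": _read_xyz_frames,
    "pdb-multimodel": _read_multimodel_pdb_frames,
}


def read_trajectory(topology: Structure, path, format: str | None = None) -> Trajectory:
    """Read frames from DCD / XYZ / multi-model PDB onto an existing topology."""
    if format is None:
        suffix = str(path).rsplit(".", 1)[-1].lower()
        format = {"dcd": "dcd", "xyz": "xyz", "pdb": "pdb-multimodel"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer trajectory format from {path!r}")
    if format not in _FORMAT_READERS:
        raise ValueError(f"unknown trajectory format {format!r}")
    frames = _FORMAT_READERS[format](path, topology.n_atoms)
    return Trajectory(structure=topology, frames=frames)


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as DCD (float32), XYZ, or multi-model PDB."""
    if format is None:
        suffix = str(path).rsplit(".", 1)[-1].lower()
        format = {"dcd": "dcd", "xyz": "xyz", "pdb": "pdb-multimodel"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer trajectory format from {path!r}")
    if format == "dcd":
        from MDAnalysis.lib.formats.libdcd import DCDFile

        with DCDFile(str(path), "w") as dcd:
            dcd.write_header(
                remarks="allodyn trajectory",
                natoms=traj.n_atoms,
                istart=0,
                nsavc=1,
                delta=1.0,
                is_periodic=0,
            )
            for frame in traj.frames:
                dcd.write(np.asarray(frame, dtype=np.float32))
    elif format == "xyz":
        with open(path, "w") as fh:
            for f, frame in enumerate(traj.frames):
                fh.write(f"{traj.n_atoms}\nframe {f}\n")
                for atom, xyz in zip(traj.structure.atoms, frame):
                    fh.write(
                        f"{atom.element:<2s} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n"
                    )
    elif format == "pdb-multimodel":
        write_pdb(traj.structure, path, frames=traj.frames)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------
#
# Grammar (case-insensitive keywords, names/ids case-sensitive):
#   expr     := or_expr
#   or_expr  := and_expr ("or" and_expr)*
#   and_expr := not_expr ("and" not_expr)*
#   not_expr := "not" not_expr | primary
#   primary  := "(" expr ")" | "all" | "chain" ID+ | "name" ID+
#             | "resid" RANGE+       (RANGE := INT | INT:INT | INT "to" INT)
#
# Multiple ids after a keyword are OR-ed: "name CA CB" == atoms named CA or CB.

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelParser:
    def __init__(self, descriptor: str, structure: Structure):
        self.tokens = _TOKEN_RE.findall(descriptor)
        self.pos = 0
        self.structure = structure
        self.descriptor = descriptor

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection descriptor")
        mask = self.parse_or()
        if self.peek() is not None:
            raise SelectionError(
                f"unexpected token {self.peek()!r} in selection {self.descriptor!r}"
            )
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        if self.peek() is not None and self.peek().lower() == "not":
            self.next()
            return ~self.parse_not()
        return self.parse_primary()

    def _collect_args(self) -> list[str]:
        args = []
        stop = {"and", "or", "not", ")", "("}
        while self.peek() is not None and self.peek().lower() not in stop:
            args.append(self.next())
        if not args:
            raise SelectionError(f"keyword missing arguments in {self.descriptor!r}")
        return args

    def parse_primary(self) -> np.ndarray:
        tok = self.next()
        if tok is None:
            raise SelectionError(f"unexpected end of selection {self.descriptor!r}")
        low = tok.lower()
        atoms = self.structure.atoms
        n = len(atoms)
        if tok == "(":
            mask = self.parse_or()
            if self.next() != ")":
                raise SelectionError(f"unbalanced parentheses in {self.descriptor!r}")
            return mask
        if low == "all":
            return np.ones(n, dtype=bool)
        if low == "chain":
            ids = set(self._collect_args())
            return np.array([a.chain_id in ids for a in atoms])
        if low == "name":
            names = set(self._collect_args())
            return np.array([a.name in names for a in atoms])
        if low == "resid":
            args = self._collect_args()
            wanted: set[int] = set()
            i = 0
            while i < len(args):
                arg = args[i]
                if i + 2 < len(args) and args[i + 1].lower() == "to":
                    lo, hi = int(arg), int(args[i + 2])
                    wanted.update(range(lo, hi + 1))
                    i += 3
                elif ":" in arg:
                    lo, hi = (int(v) for v in arg.split(":"))
                    wanted.update(range(lo, hi + 1))
                    i += 1
                else:
                    wanted.add(int(arg))
                    i += 1
            return np.array([a.residue_seq in wanted for a in atoms])
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select(structure: Structure, descriptor: str) -> AtomSelection:
    """Resolve a selection descriptor against a structure.

    Raises :class:`SelectionError` (echoing the descriptor) if the grammar is
    violated or no atom matches.
    """
    try:
        mask = _SelParser(descriptor, structure).parse()
    except (ValueError, SelectionError) as exc:
        raise SelectionError(f"cannot parse selection {descriptor!r}: {exc}") from None
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise SelectionError(f"selection {descriptor!r} matches no atoms")
    return AtomSelection(indices=indices, descriptor=descriptor)


# ---------------------------------------------------------------------------
# Superposition / alignment
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: AtomSelection | np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Kabsch least-squares fit of ``mobile`` onto ``reference``.

    The returned proper rotation and translation minimize the RMSD over the
    selected atoms; no mass weighting unless ``weights`` is given. A selection
    of fewer than 3 atoms, or a collinear one, leaves the rotation
    underdetermined and raises ``ValueError``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        idx = np.arange(mobile.shape[0])
    elif isinstance(selection, AtomSelection):
        idx = selection.indices
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size < 3:
        raise ValueError(f"superposition needs >= 3 atoms, got {idx.size}")

    x = mobile[idx]
    y = reference[idx]
    if weights is None:
        w = np.ones(idx.size)
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    xc = (w[:, None] * x).sum(axis=0)
    yc = (w[:, None] * y).sum(axis=0)
    x0 = x - xc
    y0 = y - yc

    # Collinearity check: a degenerate second principal extent in either
    # point set leaves rotation about that axis free.
    for pts in (x0, y0):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise ValueError("selection is collinear; rotation underdetermined")

    h = (w[:, None] * x0).T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc

    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt((w * ((fitted - y) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd(a: np.ndarray, b: np.ndarray, selection=None) -> float:
    """Plain (unfitted) coordinate RMSD over an optional selection."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if selection is not None:
        idx = selection.indices if isinstance(selection, AtomSelection) else np.asarray(selection)
        a, b = a[idx], b[idx]
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def align_trajectory(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    reference: str = "average-iterative",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> Trajectory:
    """Superpose every frame onto a common reference.

    ``reference="first-frame"`` fits each frame to frame 0 once.
    ``reference="average-iterative"`` refits all frames to the running mean
    structure until no frame moves by more than ``tol`` Å RMSD in a round
    (at most ``max_iter`` rounds) — the fluctuation/covariance reference used
    throughout the package. The iteration starts from the mean of the input
    frames (falling back to a first-frame prefit if that mean is
    degenerate), so an already-aligned trajectory is an exact fixed point
    and alignment is idempotent.
    """
    if selection is None:
        selection = AtomSelection(indices=np.arange(traj.n_atoms), descriptor="all")
    if reference not in ("first-frame", "average-iterative"):
        raise ValueError(f"unknown alignment reference {reference!r}")

    frames = np.array(traj.frames, dtype=float, copy=True)

    def fit_all(target) -> None:
        for f in range(frames.shape[0]):
            frames[f] = superpose(frames[f], target, selection).apply(frames[f])

    if reference == "first-frame":
        fit_all(frames[0].copy())
        return Trajectory(
            structure=traj.structure, frames=frames, frame_times=traj.frame_times
        )

    try:
        fit_all(frames.mean(axis=0))
    except ValueError:
        # raw mean degenerate (e.g. frames in wildly different orientations
        # averaging to a collapsed shape): seed from the first frame instead
        fit_all(frames[0].copy())
        fit_all(frames.mean(axis=0))
    for _ in range(max_iter):
        prev = frames.copy()
        fit_all(frames.mean(axis=0))
        sel = selection.indices
        change = np.sqrt(
            ((frames[:, sel] - prev[:, sel]) ** 2).sum(axis=2).mean(axis=1)
        ).max()
        if change < tol:
            break
    return Trajectory(structure=traj.structure, frames=frames, frame_times=traj.frame_times)


def load_atom_parameters(structure: Structure, path) -> Structure:
    """Override per-atom charge / vdW radius / LJ epsilon / mass from a table.

    The table is whitespace-delimited with a header line; recognized columns:
    ``serial charge radius epsilon mass`` (any subset beyond ``serial``).
    Returns a new Structure; atoms not listed keep their current values.
    """
    import pandas as pd

    table = pd.read_csv(path, sep=r"\s+")
    if "serial" not in table.columns:
        raise ValueError(f"{path}: parameter table needs a 'serial' column")
    by_serial = {int(r["serial"]): r for _, r in table.iterrows()}
    new_atoms = []
    for atom in structure.atoms:
        row = by_serial.get(atom.serial)
        if row is None:
            new_atoms.append(atom)
            continue
        kwargs = {}
        if "charge" in table.columns:
            kwargs["charge"] = float(row["charge"])
        if "radius" in table.columns:
            kwargs["vdw_radius"] = float(row["radius"])
        if "epsilon" in table.columns:
            kwargs["lj_epsilon"] = float(row["epsilon"])
        if "mass" in table.columns:
            kwargs["mass"] = float(row["mass"])
        new_atoms.append(replace(atom, **kwargs))
    return Structure(atoms=new_atoms, coordinates=structure.coordinates.copy())
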