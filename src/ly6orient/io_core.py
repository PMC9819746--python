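"""Topology/trajectory containers and file I/O.

File parsing is delegated to MDAnalysis (PDB, GRO topologies; XTC, DCD
trajectories); this module converts everything into plain numpy containers
with **nanometre** coordinates and picosecond times, classifies atoms into
moiety classes, and resolves named atom selections deterministically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .moieties import classify_residues

logger = logging.getLogger("ly6orient")

# MDAnalysis works in Angstrom; everything here is nm.
A_PER_NM = 10.0

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
    "MG": 24.305, "ZN": 65.38, "F": 18.998,
}


@dataclass
class Topology:
    """Static description of the system: one row per atom.

    Atom indices are implicit (0..n_atoms-1, contiguous).  ``moieties`` holds
    one moiety class per atom (see :mod:`ly6orient.moieties`).
    """

    names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray
    chains: np.ndarray
    moieties: np.ndarray
    bonds: np.ndarray | None = None
    source: Path | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "masses", "resnames", "resnums", "chains", "moieties"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length != number of atoms ({n})")
        if np.any(np.asarray(self.masses) <= 0):
            bad = np.flatnonzero(np.asarray(self.masses) <= 0)
            raise ValueError(f"non-positive masses for atom indices {bad.tolist()[:10]}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def indices_where(self, mask: np.ndarray) -> np.ndarray:
        return np.flatnonzero(mask)

    def residue_atoms(self, resnum: int) -> np.ndarray:
        return np.flatnonzero(self.resnums == resnum)

    def moiety_count(self, moiety: str, per_residue: bool = False) -> int:
        mask = self.moieties == moiety
        if not per_residue:
            return int(mask.sum())
        return len(np.unique(self.resnums[mask]))


@dataclass
class Trajectory:
    """Frames of a loaded (or generated) trajectory, coordinates in nm."""

    topology: Topology
    times: np.ndarray          # ps, strictly increasing
    boxes: np.ndarray          # (n_frames, 3) orthorhombic box lengths, nm
    coords: np.ndarray         # (n_frames, n_atoms, 3) nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate rows per frame ({self.coords.shape[1]}) != "
                f"topology atom count ({self.topology.n_atoms})"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length != number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class SelectionSpec:
    """Declarative atom selection; fields are AND-combined.

    ``None`` fields are ignored.  Resolution is deterministic: the result is
    always the ascending list of matching atom indices.
    """

    names: list[str] | None = None
    resnames: list[str] | None = None
    resnums: list[int] | None = None
    moieties: list[str] | None = None
    elements: list[str] | None = None
    allow_empty: bool = False


def select_atoms(topology: Topology, spec: SelectionSpec) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to an ascending atom-index array."""
    mask = np.ones(topology.n_atoms, dtype=bool)
    if spec.names is not None:
        mask &= np.isin(topology.names, list(spec.names))
    if spec.resnames is not None:
        mask &= np.isin(topology.resnames, list(spec.resnames))
    if spec.resnums is not None:
        mask &= np.isin(topology.resnums, list(spec.resnums))
    if spec.moieties is not None:
        mask &= np.isin(topology.moieties, list(spec.moieties))
    if spec.elements is not None:
        mask &= np.isin(topology.elements, list(spec.elements))
    idx = np.flatnonzero(mask)
    if len(idx) == 0 and not spec.allow_empty:
        raise ValueError(f"selection matched no atoms: {spec}")
    return idx


@dataclass
class ResidueGroupsConfig:
    """Named residue-number groups defining the orientation reference vectors.

    ``head`` and the three ``loop*_tip`` groups anchor the A and B vectors;
    ``backbone`` feeds the PCA; ``protein_all`` is the COM group (amino-acid
    residues only).  Residue numbering follows the source file verbatim.
    """

    label: str
    head: list[int]
    loop1_tip: list[int]
    loop2_tip: list[int]
    loop3_tip: list[int]
    backbone: list[int] = field(default_factory=list)
    protein_all: list[int] = field(default_factory=list)
    #: how the disambiguation vector F is built: "sheet_normal" (unit(A x B)),
    #: "a" (F = A), or "custom_groups" with f_from/f_to residue groups.
    f_mode: str = "sheet_normal"
    f_from: list[int] = field(default_factory=list)
    f_to: list[int] = field(default_factory=list)

    def validate(self, topology: Topology) -> None:
        groups = {
            "head": self.head, "loop1_tip": self.loop1_tip,
            "loop2_tip": self.loop2_tip, "loop3_tip": self.loop3_tip,
        }
        for name, resnums in groups.items():
            if not resnums:
                raise ValueError(f"residue group {name!r} is empty")
            missing = set(resnums) - set(topology.resnums.tolist())
            if missing:
                raise ValueError(
                    f"residue group {name!r} names residue number(s) "
                    f"{sorted(missing)} absent from the topology"
                )
        tips = [set(self.loop1_tip), set(self.loop2_tip), set(self.loop3_tip)]
        for i in range(3):
            for j in range(i + 1, 3):
                if tips[i] & tips[j]:
                    raise ValueError(
                        f"loop tip groups {i+1} and {j+1} overlap: {sorted(tips[i] & tips[j])}"
                    )
        if self.f_mode not in ("sheet_normal", "a", "custom_groups"):
            raise ValueError(f"unknown f_mode {self.f_mode!r}")
        if self.f_mode == "custom_groups" and not (self.f_from and self.f_to):
            raise ValueError("f_mode=custom_groups requires f_from and f_to groups")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ResidueGroupsConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "label": self.label, "head": list(self.head),
            "loop1_tip": list(self.loop1_tip), "loop2_tip": list(self.loop2_tip),
            "loop3_tip": list(self.loop3_tip), "backbone": list(self.backbone),
            "protein_all": list(self.protein_all), "f_mode": self.f_mode,
            "f_from": list(self.f_from), "f_to": list(self.f_to),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# file loading
# ---------------------------------------------------------------------------

def _guess_elements(universe) -> np.ndarray:
    atoms = universe.atoms
    if hasattr(atoms, "elements") and all(e for e in atoms.elements):
        return np.array([e.upper() for e in atoms.elements], dtype=object)
    from MDAnalysis.topology.guessers import guess_types

    return np.array([e.upper() for e in guess_types(atoms.names)], dtype=object)


def load_topology(path: str | Path, moiety_rules: dict[str, str] | None = None) -> Topology:
    """Read a PDB or GRO file into a :class:`Topology`.

    Every atom is classified into a moiety class from its residue name; an
    unclassifiable residue name is an error naming the offenders.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    elements = _guess_elements(u)
    try:
        masses = np.asarray(atoms.masses, dtype=float)
    except Exception:  # pragma: no cover - mda always guesses
        masses = np.zeros(len(atoms))
    bad = masses <= 0
    if np.any(bad):
        masses = masses.copy()
        masses[bad] = [_ELEMENT_MASSES.get(e, 12.011) for e in elements[bad]]
    resnames = np.array(atoms.resnames, dtype=object)
    moieties = np.array(classify_residues(resnames, moiety_rules), dtype=object)
    try:
        chains = np.array(atoms.chainIDs, dtype=object)
    except Exception:
        chains = np.array([""] * len(atoms), dtype=object)
    top = Topology(
        names=np.array(atoms.names, dtype=object),
        elements=elements,
        masses=masses,
        resnames=resnames,
        resnums=np.asarray(atoms.resids, dtype=int),
        chains=chains,
        moieties=moieties,
        source=path,
    )
    logger.info(
        "loaded topology %s: %d atoms, %d amino-acid residues, %d lipids",
        path.name, top.n_atoms,
        top.moiety_count("amino-acid", per_residue=True),
        top.moiety_count("lipid", per_residue=True),
    )
    return top


def load_trajectory(
    topology: Topology,
    path: str | Path,
    stride: int = 1,
    top_path: str | Path | None = None,
) -> Trajectory:
    """Read every ``stride``-th frame of an XTC/DCD file, coordinates in nm.

    ``top_path`` defaults to the file the topology was loaded from.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    top_path = Path(top_path) if top_path is not None else topology.source
    if top_path is None:
        raise ValueError("topology has no source file; pass top_path explicitly")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(top_path), str(path))
    if len(u.atoms) != topology.n_atoms:
        raise ValueError(
            f"trajectory atom count ({len(u.atoms)}) != topology atom count "
            f"({topology.n_atoms})"
        )
    coords, times, boxes = [], [], []
    for ts in u.trajectory[::stride]:
        coords.append(ts.positions.astype(float) / A_PER_NM)
        times.append(float(ts.time))
        boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / A_PER_NM)
    return Trajectory(
        topology=topology,
        times=np.asarray(times),
        boxes=np.asarray(boxes),
        coords=np.asarray(coords),
    )


def _make_universe(topology: Topology, coords_nm: np.ndarray, box_nm: np.ndarray):
    import MDAnalysis as mda

    n = topology.n_atoms
    resnums = topology.resnums
    # consecutive (resnum, resname) runs become residues
    boundaries = np.flatnonzero(np.diff(resnums) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    n_res = len(starts)
    residx = np.zeros(n, dtype=int)
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < n_res else n
        residx[s:e] = i
    u = mda.Universe.empty(
        n_atoms=n, n_residues=n_res, atom_resindex=residx,
        n_segments=1, trajectory=True,
    )
    u.add_TopologyAttr("names", topology.names.astype(str))
    u.add_TopologyAttr("elements", topology.elements.astype(str))
    u.add_TopologyAttr("masses", topology.masses)
    u.add_TopologyAttr("resnames", topology.resnames.astype(str)[starts])
    u.add_TopologyAttr("resids", resnums[starts])
    u.atoms.positions = coords_nm * A_PER_NM
    u.dimensions = [box_nm[0] * A_PER_NM, box_nm[1] * A_PER_NM, box_nm[2] * A_PER_NM,
                    90.0, 90.0, 90.0]
    return u


def write_topology_pdb(topology: Topology, coords_nm: np.ndarray,
                       box_nm: np.ndarray, path: str | Path) -> None:
    """Write a single-frame PDB (coordinates given in nm)."""
    u = _make_universe(topology, coords_nm, box_nm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory_xtc(traj: Trajectory, path: str | Path) -> None:
    """Write all frames to XTC (lossy: coordinates quantised to 1e-3 nm)."""
    import MDAnalysis as mda

    u = _make_universe(traj.topology, traj.coords[0], traj.boxes[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i] * A_PER_NM
                u.dimensions = [traj.boxes[i][0] * A_PER_NM,
                                traj.boxes[i][1] * A_PER_NM,
                                traj.boxes[i][2] * A_PER_NM, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = traj.times[i]
                u.trajectory.ts.frame = i
                w.write(u.atoms)


def unwrap_group(coords: np.ndarray, box: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Return coordinates with the given atom group made whole across PBC.

    Each atom of the group is shifted by whole box vectors so it lies within
    half a box of the group's first atom.  Adequate for one compact molecule;
    membrane atoms are left wrapped by the callers.
    """
    out = coords.copy()
    ref = coords[indices[0]]
    sub = out[indices]
    delta = sub - ref
    shift = np.round(delta / box) * box
    out[indices] = sub - shift
    return out
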