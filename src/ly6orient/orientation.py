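"""Membrane-referenced position and orientation of an anchored protein.

The state of a GPI-anchored three-finger protein above a planar bilayer is
described per frame by the triad (Z, alpha, beta):

* ``Z`` — height of the mass-weighted centre of mass of the amino-acid atoms
  above the mean z of the upper-leaflet phosphorus atoms (nm; "rise");
* ``alpha`` — tilt of the head-to-central-loop vector A:
  ``alpha = 90 - angle(A, normal)`` in degrees, positive when the head dips
  toward the membrane, negative when the fingers do ("pitch");
* ``beta`` — rotation about A built from the loop-III-to-loop-I vector B and
  a disambiguation vector F ("roll"):

  ====================  =======================
  condition             beta
  ====================  =======================
  F_z >= 0              90 - angle(B, normal)
  B_z >= 0 and F_z < 0  90 + angle(B, normal)
  B_z <  0 and F_z < 0  -270 + angle(B, normal)
  ====================  =======================

  beta ~ -90: loop I down; +90: loop III down; 0: ventral side down;
  +-180: dorsal side down.

With the default ``F = unit(A x B)`` (the beta-sheet normal) the mapping from
orientation (mod rotation about the membrane normal) to (alpha, beta) is
injective, which is what makes the generator's pose <-> measure round trip
exact.  Because A and B are rigidly perpendicular, B can never incline to the
normal by less than |alpha|; the (alpha, beta) pairs inside the wedges of
half-width |alpha| around beta = +-90 are therefore geometrically unreachable
(see :func:`feasible_beta`).

The membrane normal is the box +z axis; leaflets are assigned once from the
first frame and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import ResidueGroupsConfig, Topology, Trajectory, unwrap_group

__all__ = [
    "LeafletAssignment", "ReferenceVectors", "OrientationSeries",
    "assign_leaflets", "com_height", "reference_vectors",
    "tilt_angle", "rotation_angle", "orientation_series",
    "wrap_angle", "feasible_beta", "nearest_feasible_beta",
]


def wrap_angle(deg):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return a


@dataclass
class LeafletAssignment:
    """Frozen split of phosphorus-bearing lipids into upper/lower leaflets."""

    upper_p_atoms: np.ndarray       # atom indices of upper-leaflet P atoms
    lower_p_atoms: np.ndarray
    upper_residues: np.ndarray      # residue numbers
    lower_residues: np.ndarray
    midplane_z: float               # nm, at the assignment frame


@dataclass
class ReferenceVectors:
    """The A, B, F reference vectors of one frame (nm, box frame)."""

    A: np.ndarray
    B: np.ndarray
    F: np.ndarray
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))


@dataclass
class OrientationSeries:
    """Per-frame (time, Z, alpha, beta) records for one protein."""

    label: str
    times: np.ndarray    # ps
    Z: np.ndarray        # nm
    alpha: np.ndarray    # deg, |alpha| <= 90
    beta: np.ndarray     # deg, (-180, 180]

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.Z) == len(self.alpha) == len(self.beta) == n):
            raise ValueError("series arrays must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def summary(self) -> dict:
        return {
            "label": self.label,
            "n_frames": self.n_frames,
            "Z_nm": {"min": float(self.Z.min()), "max": float(self.Z.max()),
                     "mean": float(self.Z.mean())},
            "alpha_deg": {"min": float(self.alpha.min()), "max": float(self.alpha.max()),
                          "mean": float(self.alpha.mean())},
            "beta_deg": {"min": float(self.beta.min()), "max": float(self.beta.max())},
        }


# ---------------------------------------------------------------------------
# membrane reference
# ---------------------------------------------------------------------------

def assign_leaflets(topology: Topology, first_frame: np.ndarray) -> LeafletAssignment:
    """Split phosphorus-bearing lipids into leaflets from the first frame.

    A lipid is *upper* iff its P atom sits above the midplane (the mean z of
    all lipid phosphorus atoms).  Lipids without phosphorus (cholesterol) are
    excluded.  The assignment is frozen for the whole trajectory.
    """
    p_mask = (topology.moieties == "lipid") & (topology.elements == "P")
    p_idx = np.flatnonzero(p_mask)
    if len(p_idx) < 2:
        raise ValueError("need at least 2 phosphorus-bearing lipids to assign leaflets")
    z = first_frame[p_idx, 2]
    midplane = float(z.mean())
    if np.allclose(z, z[0]):
        raise ValueError("degenerate bilayer: all phosphorus atoms at identical z")
    upper = z > midplane
    return LeafletAssignment(
        upper_p_atoms=p_idx[upper],
        lower_p_atoms=p_idx[~upper],
        upper_residues=np.unique(topology.resnums[p_idx[upper]]),
        lower_residues=np.unique(topology.resnums[p_idx[~upper]]),
        midplane_z=midplane,
    )


def com_height(frame: np.ndarray, protein_sel: np.ndarray, masses: np.ndarray,
               leaflet: LeafletAssignment) -> float:
    """Mass-weighted COM height of the protein above the upper phosphate plane.

    ``Z = z(COM of protein_sel) - mean z(upper-leaflet P atoms, this frame)``.
    Negative values (protein below the surface) are returned unclamped.
    """
    if len(protein_sel) == 0:
        raise ValueError("empty protein selection")
    m = masses[protein_sel]
    com_z = float(np.average(frame[protein_sel, 2], weights=m))
    surf_z = float(frame[leaflet.upper_p_atoms, 2].mean())
    return com_z - surf_z


# ---------------------------------------------------------------------------
# reference vectors and angles
# ---------------------------------------------------------------------------

def _group_com(frame: np.ndarray, topology: Topology, resnums: list[int],
               name: str) -> np.ndarray:
    mask = np.isin(topology.resnums, list(resnums)) & (topology.moieties == "amino-acid")
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"residue group {name!r} resolves to no amino-acid atoms")
    return np.average(frame[idx], axis=0, weights=topology.masses[idx])


def reference_vectors(frame: np.ndarray, topology: Topology,
                      groups: ResidueGroupsConfig) -> ReferenceVectors:
    """Compute A (head -> loop II), B (loop III -> loop I) and F for one frame.

    F depends on ``groups.f_mode``: the beta-sheet normal ``unit(A x B)``
    (default), ``A`` itself, or a custom group-to-group vector.
    """
    head = _group_com(frame, topology, groups.head, "head")
    l1 = _group_com(frame, topology, groups.loop1_tip, "loop1_tip")
    l2 = _group_com(frame, topology, groups.loop2_tip, "loop2_tip")
    l3 = _group_com(frame, topology, groups.loop3_tip, "loop3_tip")
    A = l2 - head
    B = l1 - l3
    if groups.f_mode == "sheet_normal":
        F = np.cross(A, B)
        n = np.linalg.norm(F)
        if n == 0:
            raise ValueError("A and B are parallel; sheet normal undefined")
        F = F / n
    elif groups.f_mode == "a":
        F = A.copy()
    else:  # custom_groups
        F = (_group_com(frame, topology, groups.f_to, "f_to")
             - _group_com(frame, topology, groups.f_from, "f_from"))
    return ReferenceVectors(A=A, B=B, F=F)


def _angle_to_normal(v: np.ndarray, normal: np.ndarray) -> float:
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("zero-length reference vector")
    c = float(np.dot(v, normal) / nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def tilt_angle(v: ReferenceVectors) -> float:
    """Tilt alpha = 90 - angle(A, normal), degrees in [-90, 90]."""
    return 90.0 - _angle_to_normal(v.A, v.normal)


def rotation_angle(v: ReferenceVectors) -> float:
    """Rotation beta from the three-branch formula, degrees in (-180, 180].

    beta = 90 - angle(B, Z) if F_z >= 0; 90 + angle(B, Z) if B_z >= 0 and
    F_z < 0; -270 + angle(B, Z) if B_z < 0 and F_z < 0.  Ties B_z = 0 take
    the middle branch, exactly as the inequalities are written.
    """
    if np.linalg.norm(v.F) == 0:
        raise ValueError("zero-length disambiguation vector F")
    ang = _angle_to_normal(v.B, v.normal)
    f_z = float(np.dot(v.F, v.normal))
    b_z = float(np.dot(v.B, v.normal))
    if f_z >= 0:
        beta = 90.0 - ang
    elif b_z >= 0:
        beta = 90.0 + ang
    else:
        beta = -270.0 + ang
    return float(wrap_angle(beta))


# ---------------------------------------------------------------------------
# feasibility of (alpha, beta) under F = unit(A x B)
# ---------------------------------------------------------------------------

def feasible_beta(alpha: float, beta: float, tol: float = 0.0) -> bool:
    """Whether (alpha, beta) is geometrically reachable (sheet-normal F).

    Reachable betas given tilt alpha are
    ``[|alpha| - 90, 90 - |alpha|] + (90 + |alpha|, 180] + (-180, -90 - |alpha|]``:
    B, being perpendicular to A, cannot make an angle of less than |alpha|
    with the vertical, which excises wedges of half-width |alpha| around
    beta = +-90.
    """
    a = abs(float(alpha))
    b = float(wrap_angle(beta))
    if -(90.0 - a) - tol <= b <= (90.0 - a) + tol:
        return True
    if b > 90.0 + a - tol or b <= -(90.0 + a) + tol:
        return True
    return False


def nearest_feasible_beta(alpha: float, beta: float, margin: float = 1e-3) -> float:
    """Project beta onto the feasible set for the given tilt (with a margin).

    Used by the synthetic generator, whose independent stochastic processes
    for alpha and beta can propose unreachable pairs.
    """
    a = abs(float(alpha))
    b = float(wrap_angle(beta))
    if feasible_beta(alpha, b, tol=-margin):
        return b
    if b > 0:
        lo, hi = 90.0 - a, 90.0 + a      # infeasible wedge around +90
        return lo - margin if (b - lo) <= (hi - b) else hi + margin
    lo, hi = -90.0 - a, -90.0 + a        # wedge around -90
    return lo - margin if (b - lo) <= (hi - b) else hi + margin


# ---------------------------------------------------------------------------
# per-trajectory series
# ---------------------------------------------------------------------------

def orientation_series(traj: Trajectory, groups: ResidueGroupsConfig,
                       leaflet: LeafletAssignment | None = None,
                       unwrap: bool = True) -> OrientationSeries:
    """Compute the (Z, alpha, beta) triad for every frame of a trajectory.

    Protein coordinates are unwrapped (made whole across periodic boundaries)
    before any COM or vector computation; membrane atoms stay wrapped.
    """
    top = traj.topology
    if leaflet is None:
        leaflet = assign_leaflets(top, traj.coords[0])
    protein_sel = np.flatnonzero(top.moieties == "amino-acid")
    if groups.protein_all:
        protein_sel = protein_sel[np.isin(top.resnums[protein_sel], groups.protein_all)]
    groups.validate(top)
    n = traj.n_frames
    Z = np.empty(n)
    alpha = np.empty(n)
    beta = np.empty(n)
    for i in range(n):
        frame = traj.coords[i]
        if unwrap:
            frame = unwrap_group(frame, traj.boxes[i], protein_sel)
        Z[i] = com_height(frame, protein_sel, top.masses, leaflet)
        vecs = reference_vectors(frame, top, groups)
        alpha[i] = tilt_angle(vecs)
        beta[i] = rotation_angle(vecs)
    return OrientationSeries(label=groups.label, times=traj.times.copy(),
                             Z=Z, alpha=alpha, beta=beta)
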