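"""Synthetic trajectories with exact ground truth.

The generator builds a planar pseudo-lipid patch (two leaflets of five-bead
lipids: phosphate P, choline N, ester oxygen O2 and two tail carbons) and a
rigid mock three-finger protein whose marker residues define the head and the
three loop tips.  Per frame the protein is *posed* at a prescribed
(Z, alpha, beta) triple drawn from mode-switching Ornstein-Uhlenbeck
processes, so the orientation pipeline can be tested against exact ground
truth: ``measure(pose(Z, alpha, beta)) == (Z, alpha, beta)`` to floating
point.

The mock protein also carries protruding contact residues (Lys NZ, Tyr OH/HH,
a Phe ring, Leu methyls) so that residue-lipid contacts of each type can be
planted at prescribed time fractions: a reserved lipid is moved up to the
posed residue in exactly ``ceil(fraction * n_frames)`` frames and parked on
its lattice site otherwise, while a second far-away lipid mirrors the z
displacement so the mean upper-leaflet phosphorus height -- and hence the Z
ground truth -- is untouched.

No physics is simulated: lipids are static apart from a small headgroup z
jitter, and the protein is a rigid body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import (
    Topology, Trajectory, write_topology_pdb, write_trajectory_xtc,
)
from .moieties import classify_residues
from .orientation import nearest_feasible_beta, wrap_angle

__all__ = [
    "ProteinTemplate", "three_finger_template", "ObservableProcess",
    "SyntheticSpec", "GroundTruth", "PlantedContact",
    "pose_protein", "generate_trajectory", "plant_contacts",
    "sample_feasible_triple", "default_groups_config",
]

_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "H": 1.008, "P": 30.974}

ALPHA_CLAMP = 89.9   # generator never emits |alpha| above this (gimbal guard)


# ---------------------------------------------------------------------------
# rigid mock protein
# ---------------------------------------------------------------------------

@dataclass
class ProteinTemplate:
    """Rigid mock protein in its canonical frame (COM at origin, A // +x, B // +y)."""

    names: list[str]
    elements: list[str]
    resnames: list[str]
    resnums: list[int]
    coords: np.ndarray            # (n, 3) nm, canonical frame
    head: list[int]               # marker residue numbers
    loop1_tip: list[int]
    loop2_tip: list[int]
    loop3_tip: list[int]

    @property
    def masses(self) -> np.ndarray:
        return np.array([_MASS[e] for e in self.elements])

    def _group_idx(self, resnums: list[int]) -> np.ndarray:
        return np.flatnonzero(np.isin(self.resnums, resnums))

    def marker_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Canonical A (head -> loop II) and B (loop III -> loop I) vectors."""
        m = self.masses
        com = lambda idx: np.average(self.coords[idx], axis=0, weights=m[idx])
        A = com(self._group_idx(self.loop2_tip)) - com(self._group_idx(self.head))
        B = com(self._group_idx(self.loop1_tip)) - com(self._group_idx(self.loop3_tip))
        return A, B

    def atom_index(self, resnum: int, name: str) -> int:
        for i, (rn, nm) in enumerate(zip(self.resnums, self.names)):
            if rn == resnum and nm == name:
                return i
        raise KeyError(f"no atom {name!r} in residue {resnum}")


def three_finger_template() -> ProteinTemplate:
    """The shipped eleven-residue rigid mock of the three-finger fold.

    Residues 1-2 form the 'head', residues 3/4/5 are the loop I/II/III tips
    (A = head->loop II exactly +x, B = loop III->loop I exactly +y in the
    canonical frame).  Residues 7-11 carry protruding side chains for contact
    planting: Lys7/Lys11 NZ (cations), Tyr8 OH/HH (H-bond donor), Phe9 ring
    (aromatic), Leu10 CD1/CD2 (aliphatic).
    """
    rows: list[tuple[int, str, str, str, tuple[float, float, float]]] = [
        (1, "GLY", "CA", "C", (-0.50, 0.12, 0.05)),
        (2, "GLY", "CA", "C", (-0.50, -0.12, -0.05)),
        (3, "GLY", "CA", "C", (0.10, 0.55, 0.00)),
        (4, "GLY", "CA", "C", (0.55, 0.00, 0.00)),
        (5, "GLY", "CA", "C", (0.10, -0.55, 0.00)),
        (6, "GLY", "CA", "C", (-0.15, 0.00, 0.22)),
        (7, "LYS", "CA", "C", (0.20, 0.20, -0.12)),
        (7, "LYS", "NZ", "N", (0.28, 0.28, -0.78)),
        (8, "TYR", "CA", "C", (-0.20, 0.20, -0.12)),
        (8, "TYR", "OH", "O", (-0.28, 0.28, -0.78)),
        (9, "PHE", "CA", "C", (0.00, -0.28, -0.12)),
        (10, "LEU", "CA", "C", (0.15, -0.10, 0.20)),
        (10, "LEU", "CD1", "C", (0.22, -0.15, 0.80)),
        (10, "LEU", "CD2", "C", (0.10, -0.05, 0.85)),
        (11, "LYS", "CA", "C", (-0.55, 0.00, -0.20)),
        (11, "LYS", "NZ", "N", (-0.98, 0.00, -0.42)),
    ]
    # Tyr hydroxyl hydrogen along the CA->OH direction, 0.098 nm from OH
    oh = np.array([-0.28, 0.28, -0.78])
    ca = np.array([-0.20, 0.20, -0.12])
    hh = oh + 0.098 * (oh - ca) / np.linalg.norm(oh - ca)
    rows.append((8, "TYR", "HH", "H", tuple(hh)))
    # Phe ring: hexagon of radius 0.14 nm, centre below CA, normal tilted outward
    centre = np.array([0.00, -0.38, -0.72])
    normal = np.array([0.0, -0.35, -0.90])
    normal = normal / np.linalg.norm(normal)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(normal, e1)
    ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    for k, nm in enumerate(ring_names):
        ang = math.radians(60.0 * k)
        pos = centre + 0.14 * (math.cos(ang) * e1 + math.sin(ang) * e2)
        rows.append((9, "PHE", nm, "C", tuple(pos)))
    rows.sort(key=lambda r: r[0])
    resnums = [r[0] for r in rows]
    resnames = [r[1] for r in rows]
    names = [r[2] for r in rows]
    elements = [r[3] for r in rows]
    coords = np.array([r[4] for r in rows], dtype=float)
    masses = np.array([_MASS[e] for e in elements])
    coords -= np.average(coords, axis=0, weights=masses)   # COM to origin
    return ProteinTemplate(
        names=names, elements=elements, resnames=resnames, resnums=resnums,
        coords=coords, head=[1, 2], loop1_tip=[3], loop2_tip=[4], loop3_tip=[5],
    )


def default_groups_config(label: str = "mock"):
    """Residue-groups config matching :func:`three_finger_template`."""
    from .io_core import ResidueGroupsConfig

    return ResidueGroupsConfig(
        label=label, head=[1, 2], loop1_tip=[3], loop2_tip=[4], loop3_tip=[5],
        backbone=list(range(1, 12)), protein_all=list(range(1, 12)),
    )


# ---------------------------------------------------------------------------
# posing
# ---------------------------------------------------------------------------

def _pose_rotation(alpha: float, beta: float, azimuth: float) -> np.ndarray:
    """Rotation matrix taking the canonical (x, y, z) triad to the lab triad
    realising tilt ``alpha`` and rotation ``beta`` (sheet-normal convention),
    with free azimuth about the membrane normal.

    Inverts the three-branch beta formula: writing b_hat on the circle of
    unit vectors perpendicular to a_hat as cos(theta) u + sin(theta) v (u the
    steepest-ascent direction, v horizontal), the measured quantities are
    cos(angle(B, z)) = cos(theta) cos(alpha) and F_z = -sin(theta) cos(alpha),
    so each feasible beta corresponds to exactly one theta.
    """
    if abs(alpha) > 90.0:
        raise ValueError(f"|alpha| must be <= 90, got {alpha}")
    ca = math.cos(math.radians(alpha))
    if ca < 1e-8:
        raise ValueError("alpha at the pole: beta undefined (gimbal)")
    a_abs = abs(alpha)
    b = float(wrap_angle(beta))
    if -(90.0 - a_abs) <= b <= (90.0 - a_abs):
        ang = 90.0 - b                       # branch 1: F_z >= 0
        theta = -math.acos(np.clip(math.cos(math.radians(ang)) / ca, -1.0, 1.0))
    elif b > 90.0 + a_abs:
        ang = b - 90.0                       # branch 2: B_z >= 0, F_z < 0
        theta = math.acos(np.clip(math.cos(math.radians(ang)) / ca, -1.0, 1.0))
    elif b <= -(90.0 + a_abs):
        ang = b + 270.0                      # branch 3: B_z < 0, F_z < 0
        theta = math.acos(np.clip(math.cos(math.radians(ang)) / ca, -1.0, 1.0))
    else:
        raise ValueError(
            f"(alpha={alpha:.3f}, beta={b:.3f}) is geometrically unreachable: "
            f"beta within {a_abs:.3f} deg of +-90 requires |alpha| smaller"
        )
    sa = math.sin(math.radians(alpha))
    cp, sp = math.cos(azimuth), math.sin(azimuth)
    a_hat = np.array([ca * cp, ca * sp, sa])
    u = np.array([-sa * cp, -sa * sp, ca])
    v = np.array([sp, -cp, 0.0])
    b_hat = math.cos(theta) * u + math.sin(theta) * v
    c_hat = np.cross(a_hat, b_hat)
    return np.column_stack([a_hat, b_hat, c_hat])


def pose_protein(template: ProteinTemplate, Z: float, alpha: float, beta: float,
                 surface_z: float = 0.0, center_xy: tuple[float, float] = (0.0, 0.0),
                 azimuth: float | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Rigidly pose the template so that measurement returns (Z, alpha, beta).

    ``surface_z`` is the mean upper-leaflet phosphorus height the COM height
    is referenced to.  The free rotation about the membrane normal is drawn
    from ``rng`` unless ``azimuth`` (radians) is given.  Raises ``ValueError``
    for |alpha| > 90, poses at the gimbal pole, unreachable (alpha, beta)
    pairs, and degenerate templates (A // B or zero length).
    """
    A0, B0 = template.marker_vectors()
    na, nb = np.linalg.norm(A0), np.linalg.norm(B0)
    if na == 0 or nb == 0:
        raise ValueError("degenerate template: zero-length marker vector")
    if abs(np.dot(A0, B0)) / (na * nb) > 1e-9:
        raise ValueError("degenerate template: A and B markers not perpendicular")
    if azimuth is None:
        rng = np.random.default_rng() if rng is None else rng
        azimuth = float(rng.uniform(0.0, 2.0 * math.pi))
    R_lab = _pose_rotation(alpha, beta, azimuth)
    ta = A0 / na
    tb = B0 / nb
    tc = np.cross(ta, tb)
    T = np.column_stack([ta, tb, tc])
    R = R_lab @ T.T
    centre = np.array([center_xy[0], center_xy[1], surface_z + Z])
    return template.coords @ R.T + centre


def sample_feasible_triple(rng: np.random.Generator,
                           z_range: tuple[float, float] = (1.0, 3.0),
                           alpha_max: float = 89.0,
                           margin: float = 1e-3) -> tuple[float, float, float]:
    """Draw a uniform (Z, alpha, beta) from the legal pose domain.

    Alpha is uniform on [-alpha_max, alpha_max]; beta uniform on the feasible
    set for that alpha (the circle minus the two wedges around +-90).
    """
    Z = float(rng.uniform(*z_range))
    alpha = float(rng.uniform(-alpha_max, alpha_max))
    a = abs(alpha)
    # feasible beta measure: 360 - 4a; sample uniformly then skip the wedges
    span = 360.0 - 4.0 * (a + margin)
    x = rng.uniform(0.0, span)
    beta = -(90.0 - (a + margin)) + x          # start just past the -90 wedge
    if beta > 90.0 - (a + margin):             # jump over the +90 wedge
        beta += 2.0 * (a + margin)
    return Z, alpha, float(wrap_angle(beta))


# ---------------------------------------------------------------------------
# stochastic orientation processes
# ---------------------------------------------------------------------------

@dataclass
class ObservableProcess:
    """Mode-switching OU process targeting a mixture of Gaussians.

    The state relaxes toward the current mode mean with timescale ``tau_ps``
    and stationary SD equal to the mode SD; the mode index is resampled from
    the mixture weights with probability ``switch_prob`` per frame, so long
    dwells in each well produce the autocorrelated, multimodal series seen in
    anchored-protein trajectories.
    """

    means: list[float]
    sds: list[float]
    weights: list[float] | None = None
    tau_ps: float = 2000.0
    switch_prob: float = 0.01
    circular: bool = False

    def __post_init__(self) -> None:
        k = len(self.means)
        if len(self.sds) != k:
            raise ValueError("means and sds must have equal length")
        if any(s <= 0 for s in self.sds):
            raise ValueError("SDs must be positive")
        if self.weights is None:
            self.weights = [1.0 / k] * k
        if len(self.weights) != k or abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.tau_ps <= 0:
            raise ValueError("tau_ps must be positive")

    def sample(self, n: int, dt_ps: float, rng: np.random.Generator) -> np.ndarray:
        phi = math.exp(-dt_ps / self.tau_ps)
        noise_scale = math.sqrt(max(0.0, 1.0 - phi * phi))
        w = np.asarray(self.weights)
        mode = int(rng.choice(len(w), p=w))
        x = float(rng.normal(self.means[mode], self.sds[mode]))
        out = np.empty(n)
        out[0] = wrap_angle(x) if self.circular else x
        for t in range(1, n):
            if rng.random() < self.switch_prob:
                mode = int(rng.choice(len(w), p=w))
            mu, sd = self.means[mode], self.sds[mode]
            delta = out[t - 1] - mu
            if self.circular:
                delta = float(wrap_angle(delta))
            x = mu + phi * delta + sd * noise_scale * float(rng.standard_normal())
            out[t] = wrap_angle(x) if self.circular else x
        return out


# ---------------------------------------------------------------------------
# spec / ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic trajectory.

    Default orientation processes follow the reported Lynx1 behaviour (tilt
    -31.5 +- 8.7 deg, rotation -47.9 +- 7.2 deg); the COM height rides at
    2.0 +- 0.10 nm so the mock's protruding side chains stay clear of the
    headgroup region unless a contact is deliberately planted.
    """

    nx: int = 6
    ny: int = 6
    spacing: float = 0.8          # nm between lipid lattice sites
    leaflet_sep: float = 4.0      # nm between the two phosphate planes
    headgroup_jitter_sd: float = 0.05   # nm, per-lipid per-frame z jitter
    z_process: ObservableProcess = field(
        default_factory=lambda: ObservableProcess(means=[2.0], sds=[0.10]))
    alpha_process: ObservableProcess = field(
        default_factory=lambda: ObservableProcess(means=[-31.5], sds=[8.7]))
    beta_process: ObservableProcess = field(
        default_factory=lambda: ObservableProcess(means=[-47.9], sds=[7.2],
                                                  circular=True))
    n_frames: int = 2000
    dt_ps: float = 1000.0
    seed: int = 0
    azimuth_walk_sd: float = 0.1  # rad, per-frame random walk about the normal

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("patch must be at least 2 x 2 lipids")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        self.beta_process.circular = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("z_process", "alpha_process", "beta_process"):
            if key in data and isinstance(data[key], dict):
                data[key] = ObservableProcess(**data[key])
        return cls(**data)


@dataclass
class PlantedContact:
    """One planted residue-lipid contact: which frames, and how many pairs."""

    resnum: int
    resname: str
    lipid_resnum: int
    lipid_class: str
    ctype: str
    frames: np.ndarray
    count_per_frame: int
    fraction: float


@dataclass
class GroundTruth:
    """Exact per-frame pose values and the planted-contact table."""

    times: np.ndarray
    Z: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    contacts: list[PlantedContact] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({
            "time_ps": self.times, "Z_nm": self.Z,
            "alpha_deg": self.alpha, "beta_deg": self.beta,
        }).to_csv(path, sep="\t", index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

_LIPID_BEADS = [  # name, element, z offset from the phosphate plane (upper leaflet)
    ("P", "P", 0.00),
    ("N", "N", 0.20),
    ("O2", "O", -0.15),
    ("C21", "C", -0.60),
    ("C31", "C", -1.00),
]
_BEADS_PER_LIPID = len(_LIPID_BEADS)
_PROTEIN_FIRST_RESNUM = 1
_LIPID_FIRST_RESNUM = 101


def _build_topology(template: ProteinTemplate, nx: int, ny: int) -> Topology:
    names = list(template.names)
    elements = list(template.elements)
    resnames = list(template.resnames)
    resnums = list(template.resnums)
    resnum = _LIPID_FIRST_RESNUM
    for _leaflet in range(2):
        for _ in range(nx * ny):
            for nm, el, _dz in _LIPID_BEADS:
                names.append(nm)
                elements.append(el)
                resnames.append("POPC")
                resnums.append(resnum)
            resnum += 1
    masses = np.array([_MASS[e] for e in elements])
    moieties = np.array(classify_residues(resnames), dtype=object)
    return Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        masses=masses,
        resnames=np.array(resnames, dtype=object),
        resnums=np.array(resnums, dtype=int),
        chains=np.array([""] * len(names), dtype=object),
        moieties=moieties,
    )


def _lattice_sites(spec: SyntheticSpec) -> np.ndarray:
    xs = (np.arange(spec.nx) + 0.5) * spec.spacing
    ys = (np.arange(spec.ny) + 0.5) * spec.spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _membrane_coords(spec: SyntheticSpec, midplane_z: float,
                     jitter_upper: np.ndarray, jitter_lower: np.ndarray) -> np.ndarray:
    """Static lipid coordinates for one frame (shape: n_lipid_atoms x 3)."""
    sites = _lattice_sites(spec)
    half = spec.leaflet_sep / 2.0
    out = np.empty((2 * len(sites) * _BEADS_PER_LIPID, 3))
    row = 0
    for sign, jit in ((1.0, jitter_upper), (-1.0, jitter_lower)):
        for i, (x, y) in enumerate(sites):
            pz = midplane_z + sign * half + jit[i]
            for _nm, _el, dz in _LIPID_BEADS:
                out[row] = (x, y, pz + sign * dz)
                row += 1
    return out


def generate_trajectory(spec: SyntheticSpec,
                        template: ProteinTemplate | None = None
                        ) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory whose per-frame (Z, alpha, beta) are known exactly.

    Beta draws that are geometrically unreachable for the frame's alpha are
    projected to the nearest feasible boundary; GroundTruth records the values
    actually posed.  Identical spec + seed give bit-identical output.
    """
    template = template or three_finger_template()
    rng = np.random.default_rng(spec.seed)
    top = _build_topology(template, spec.nx, spec.ny)
    n = spec.n_frames
    Z = spec.z_process.sample(n, spec.dt_ps, rng)
    alpha = np.clip(spec.alpha_process.sample(n, spec.dt_ps, rng),
                    -ALPHA_CLAMP, ALPHA_CLAMP)
    beta_raw = spec.beta_process.sample(n, spec.dt_ps, rng)
    beta = np.array([nearest_feasible_beta(a, b) for a, b in zip(alpha, beta_raw)])
    azimuth = np.cumsum(np.concatenate([
        [rng.uniform(0, 2 * math.pi)],
        rng.normal(0.0, spec.azimuth_walk_sd, n - 1)]))

    box = np.array([spec.nx * spec.spacing, spec.ny * spec.spacing, 10.0])
    midplane_z = box[2] / 2.0 - 1.0
    centre_xy = (box[0] / 2.0, box[1] / 2.0)
    n_sites = spec.nx * spec.ny
    n_prot = len(template.names)

    coords = np.empty((n, top.n_atoms, 3))
    times = np.arange(n, dtype=float) * spec.dt_ps
    p_stride = _BEADS_PER_LIPID
    for i in range(n):
        jit_u = rng.normal(0.0, spec.headgroup_jitter_sd, n_sites)
        jit_l = rng.normal(0.0, spec.headgroup_jitter_sd, n_sites)
        membrane = _membrane_coords(spec, midplane_z, jit_u, jit_l)
        # the reference is the mean z of the upper P beads of THIS frame
        surface_z = float(membrane[0:n_sites * p_stride:p_stride, 2].mean())
        coords[i, :n_prot] = pose_protein(
            template, Z[i], alpha[i], beta[i],
            surface_z=surface_z, center_xy=centre_xy, azimuth=float(azimuth[i]),
        )
        coords[i, n_prot:] = membrane
    traj = Trajectory(topology=top, times=times,
                      boxes=np.tile(box, (n, 1)), coords=coords)
    truth = GroundTruth(times=times.copy(), Z=Z, alpha=alpha, beta=beta)
    return traj, truth


# ---------------------------------------------------------------------------
# contact planting
# ---------------------------------------------------------------------------

#: per contact type: the residue atoms involved and the placement recipe
_PLANT_ATOMS = {
    "ionic": {"LYS": "NZ"},
    "ion_dipole": {"LYS": "NZ"},
    "hbond": {"TYR": ("OH", "HH")},
    "pication": {"PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "hydrophobic": {"LEU": ("CD1", "CD2")},
}

_CLEARANCE = 0.65   # nm: planted lipid beads stay this far from non-partner atoms


def _placement(ctype: str, frame_coords: np.ndarray, prot_idx: np.ndarray,
               atom_idx: dict[str, int], com: np.ndarray,
               cutoffs: dict[str, float]) -> tuple[np.ndarray, int]:
    """Lab-frame positions for the 5 beads of the planted lipid + pair count."""
    def outward(p):
        u = p - com
        return u / np.linalg.norm(u)

    if ctype in ("ionic", "ion_dipole"):
        a = frame_coords[atom_idx["key"]]
        u = outward(a)
        d0 = 0.30 if ctype == "ionic" else 0.32
        p = a + d0 * u
        beads = [p, p + 0.50 * u, p + 0.25 * u, p + 0.80 * u, p + 1.10 * u]
        return np.array(beads), 1
    if ctype == "hbond":
        oh = frame_coords[atom_idx["OH"]]
        hh = frame_coords[atom_idx["HH"]]
        w = (hh - oh) / np.linalg.norm(hh - oh)
        o2 = oh + 0.30 * w           # acceptor along the O-H direction: angle 0
        u = outward(o2)
        p = o2 + 0.32 * u
        beads = [p, p + 0.25 * u, o2, p + 0.60 * u, p + 0.90 * u]
        return np.array(beads), 1
    if ctype == "pication":
        ring = frame_coords[[atom_idx[nm] for nm in
                             ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]]
        c = ring.mean(axis=0)
        nvec = np.cross(ring[1] - ring[0], ring[2] - ring[0])
        nvec = nvec / np.linalg.norm(nvec)
        if np.dot(nvec, c - com) < 0:
            nvec = -nvec
        npos = c + 0.45 * nvec       # cation on the ring axis: angle 0
        u = outward(npos)
        p = npos + 0.70 * u
        beads = [p, npos, p + 0.25 * u, p + 0.55 * u, p + 0.85 * u]
        return np.array(beads), 1
    if ctype == "hydrophobic":
        cd1 = frame_coords[atom_idx["CD1"]]
        cd2 = frame_coords[atom_idx["CD2"]]
        u = outward(cd1)
        t1 = cd1 + 0.30 * u
        t2 = t1 + 0.35 * u
        beads = [t2 + 0.90 * u, t2 + 1.10 * u, t2 + 0.70 * u, t1, t2]
        pos = np.array(beads)
        # realised pair count from the constructed geometry
        cut = cutoffs["hydrophobic"]
        prot_c = frame_coords[prot_idx["carbon"]]
        count = int((np.linalg.norm(prot_c[None, :, :] - pos[3:5, None, :], axis=2)
                     <= cut).sum())
        return pos, count
    raise ValueError(f"unknown contact type {ctype!r}")


def plant_contacts(traj: Trajectory, truth: GroundTruth,
                   plan: list[tuple[int, str, float]],
                   template: ProteinTemplate | None = None,
                   cutoffs: dict[str, float] | None = None,
                   seed: int = 0) -> GroundTruth:
    """Plant residue-lipid contacts at prescribed time fractions, in place.

    ``plan`` is a list of ``(residue number, contact type, fraction)``.  Each
    entry reserves one upper-leaflet lipid that is moved next to the posed
    residue in exactly ``ceil(fraction * n_frames)`` frames (chosen at random
    from ``seed``) and parked on its lattice site otherwise; a second
    reserved lipid mirrors the z displacement so the mean upper-leaflet P
    height is preserved exactly.  Raises ``ValueError`` on geometric
    infeasibility (placed beads would come within 0.65 nm of non-partner
    protein atoms, or the resting protein would touch the membrane).
    """
    template = template or three_finger_template()
    cutoffs = cutoffs or {"ionic": 0.45, "ion_dipole": 0.40, "hbond": 0.35,
                          "pication": 0.60, "hydrophobic": 0.45}
    rng = np.random.default_rng(seed)
    top = traj.topology
    n = traj.n_frames
    n_prot = len(template.names)
    prot_resnums = np.asarray(template.resnums)
    prot_names = np.asarray(template.names)
    prot_elements = np.asarray(template.elements)
    masses = template.masses
    prot_carbon = np.flatnonzero(prot_elements == "C")

    # reserved lipids: upper-leaflet residues ordered by distance from the
    # patch centre, farthest first (planted lipid, then its z-compensator)
    lipid_resnums = np.unique(top.resnums[top.moieties == "lipid"])
    sites_xy = {}
    for rn in lipid_resnums:
        idx = top.residue_atoms(rn)
        if traj.coords[0, idx[0], 2] > traj.boxes[0][2] / 2.0 - 1.0:  # upper
            sites_xy[rn] = traj.coords[0, idx[0], :2]
    centre = np.array([traj.boxes[0][0] / 2.0, traj.boxes[0][1] / 2.0])
    order = sorted(sites_xy, key=lambda rn: -np.linalg.norm(sites_xy[rn] - centre))
    if len(order) < 2 * len(plan):
        raise ValueError("not enough upper-leaflet lipids to plant the plan")

    # the resting (pre-planting) membrane must be clear of the protein in
    # every frame, otherwise absence of contact cannot be guaranteed
    lip_atoms = np.flatnonzero(top.moieties == "lipid")
    for i in range(n):
        fc = traj.coords[i]
        d = np.linalg.norm(fc[:n_prot][:, None, :] - fc[lip_atoms][None, :, :],
                           axis=2).min()
        if d < _CLEARANCE - 1e-9:
            raise ValueError(
                "geometric infeasibility: resting protein comes within "
                f"{d:.3f} nm of the membrane in frame {i}; raise the Z process")

    planted: list[PlantedContact] = []
    for k, (resnum, ctype, fraction) in enumerate(plan):
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {fraction}")
        if ctype not in _PLANT_ATOMS:
            raise ValueError(f"unknown contact type {ctype!r}")
        sel = np.flatnonzero(prot_resnums == resnum)
        if len(sel) == 0:
            raise ValueError(f"residue {resnum} not in the protein template")
        resname = template.resnames[sel[0]]
        recipe = _PLANT_ATOMS[ctype].get(resname)
        if recipe is None:
            raise ValueError(
                f"residue {resnum} ({resname}) has no atoms for {ctype} planting")
        if isinstance(recipe, str):
            atom_idx = {"key": template.atom_index(resnum, recipe)}
        else:
            atom_idx = {nm: template.atom_index(resnum, nm) for nm in recipe}

        # ceil of the exact product; guard against float artefacts like
        # 0.55 * 100 -> 55.000000000000006
        n_contact = math.ceil(round(fraction * n, 9))
        frames = np.sort(rng.choice(n, size=n_contact, replace=False)) \
            if n_contact else np.array([], dtype=int)
        lip_rn = order[2 * k]
        comp_rn = order[2 * k + 1]
        lip_idx = top.residue_atoms(lip_rn)
        comp_idx = top.residue_atoms(comp_rn)

        count = 0
        frameset = set(int(f) for f in frames)
        for i in range(n):
            if i not in frameset:
                continue
            fc = traj.coords[i]
            com = np.average(fc[:n_prot], axis=0, weights=masses)
            beads, cnt = _placement(ctype, fc, {"carbon": prot_carbon},
                                    atom_idx, com, cutoffs)
            count = cnt
            # isolation: beads clear of every non-partner protein atom
            partner = set(atom_idx.values())
            others = np.array([j for j in range(n_prot) if j not in partner])
            dmin = np.linalg.norm(fc[others][None, :, :] - beads[:, None, :],
                                  axis=2).min()
            if dmin < _CLEARANCE - 1e-9:
                raise ValueError(
                    f"geometric infeasibility: planted lipid for residue {resnum} "
                    f"({ctype}) comes within {dmin:.3f} nm of another protein atom")
            # z-compensation keeps the upper-leaflet P mean exact: mirror the
            # displacement of THIS frame's (jittered) phosphate height
            dz = beads[0, 2] - traj.coords[i, lip_idx[0], 2]
            traj.coords[i, lip_idx] = beads
            traj.coords[i, comp_idx, 2] = traj.coords[i, comp_idx, 2] - dz
        planted.append(PlantedContact(
            resnum=resnum, resname=resname, lipid_resnum=int(lip_rn),
            lipid_class="phosphatidylcholine", ctype=ctype,
            frames=frames, count_per_frame=count if n_contact else 0,
            fraction=fraction))
    truth.contacts.extend(planted)
    return truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fixture(traj: Trajectory, truth: GroundTruth, out_dir: str | Path,
                  prefix: str = "synthetic") -> dict[str, Path]:
    """Write PDB topology, XTC trajectory and ground-truth TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb = out_dir / f"{prefix}.pdb"
    xtc = out_dir / f"{prefix}.xtc"
    tsv = out_dir / f"{prefix}_truth.tsv"
    write_topology_pdb(traj.topology, traj.coords[0], traj.boxes[0], pdb)
    write_trajectory_xtc(traj, xtc)
    truth.to_tsv(tsv)
    if truth.contacts:
        import pandas as pd

        rows = [{
            "resnum": c.resnum, "resname": c.resname, "lipid_resnum": c.lipid_resnum,
            "lipid_class": c.lipid_class, "type": c.ctype,
            "n_frames_present": len(c.frames), "count_per_frame": c.count_per_frame,
            "fraction": c.fraction,
        } for c in truth.contacts]
        pd.DataFrame(rows).to_csv(out_dir / f"{prefix}_contacts.tsv",
                                  sep="\t", index=False)
    return {"pdb": pdb, "xtc": xtc, "truth": tsv}
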