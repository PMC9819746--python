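"""Principal component analysis of backbone motion above the membrane.

Frames are first superposed on a reference in the xy-plane only: the optimal
rotation about the z-axis plus an x/y translation, leaving z untouched.  This
removes the in-plane diffusion and spin that are symmetries of a planar
membrane while keeping the membrane-normal motion (the interesting part) in
the data.  The covariance of the remaining 3N backbone coordinates is then
eigendecomposed; for an anchored, internally rigid protein the top components
recover the rise/pitch/roll motions.  Covariance is unweighted (plain
coordinates, no masses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import Trajectory

__all__ = ["PcaResult", "fit_xy", "pca_backbone", "extreme_projections",
           "pca_trajectory"]


@dataclass
class PcaResult:
    mean: np.ndarray           # (n_sel, 3) nm
    eigenvalues: np.ndarray    # nm^2, descending
    eigenvectors: np.ndarray   # (3N, n_components), orthonormal columns
    projections: np.ndarray    # (n_frames, n_components) nm

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


def fit_xy(frames: np.ndarray, reference: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Superpose each frame on the reference in the xy-plane only.

    The rotation about z and the x/y translation minimising the in-plane
    least-squares deviation of the selected atoms are found from the 2x2
    cross-covariance SVD (planar Procrustes) and applied to all atoms;
    z-coordinates pass through unchanged.
    """
    sel = np.asarray(sel)
    if len(sel) < 3:
        raise ValueError("need at least 3 atoms for xy superposition")
    ref_xy = reference[sel, :2]
    ref_c = ref_xy.mean(axis=0)
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        mob_xy = frame[sel, :2]
        mob_c = mob_xy.mean(axis=0)
        H = (mob_xy - mob_c).T @ (ref_xy - ref_c)
        U, _s, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(U @ Vt))
        R = (U @ np.diag([1.0, d]) @ Vt).T          # proper 2D rotation
        xy = (frame[:, :2] - mob_c) @ R.T + ref_c
        out[i, :, :2] = xy
        out[i, :, 2] = frame[:, 2]
    return out


def pca_backbone(aligned: np.ndarray, sel: np.ndarray) -> PcaResult:
    """PCA of the selected atoms' 3N coordinate vector over frames.

    Covariance is taken about the time mean; eigenvalues are returned in
    descending order with orthonormal eigenvectors, and each frame is
    projected on each component.
    """
    sel = np.asarray(sel)
    n_frames = aligned.shape[0]
    if n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    X = aligned[:, sel, :].reshape(n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = Xc @ evecs
    return PcaResult(mean=mean.reshape(len(sel), 3), eigenvalues=evals,
                     eigenvectors=evecs, projections=projections)


def extreme_projections(result: PcaResult, component: int) -> tuple[int, int]:
    """Frame indices with minimal and maximal projection on a component.

    Ties are broken toward the lowest frame index.
    """
    if not 0 <= component < result.n_components:
        raise IndexError(f"component {component} out of range "
                         f"(0..{result.n_components - 1})")
    p = result.projections[:, component]
    return int(np.argmin(p)), int(np.argmax(p))


def pca_trajectory(traj: Trajectory, backbone_resnums: list[int] | None = None,
                   atom_names: tuple[str, ...] = ("CA", "C", "N")) -> PcaResult:
    """Convenience pipeline: xy-fit to the first frame, then backbone PCA."""
    top = traj.topology
    mask = (top.moieties == "amino-acid") & np.isin(top.names, list(atom_names))
    if backbone_resnums:
        mask &= np.isin(top.resnums, list(backbone_resnums))
    sel = np.flatnonzero(mask)
    if len(sel) < 3:
        raise ValueError("backbone selection resolves to fewer than 3 atoms")
    aligned = fit_xy(traj.coords, traj.coords[0], sel)
    return pca_backbone(aligned, sel)
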