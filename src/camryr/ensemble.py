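"""Coordinate-ensemble analytics for simulated CaM-peptide complexes.

Implements the essential-dynamics toolchain used to judge whether
independent trajectory replicas sampled the same conformational space:
least-squares superposition onto an iteratively refined average
structure, per-particle RMSF (Cα and bound Ca²⁺ ions), PCA of the
Cα-coordinate covariance matrix, projections onto principal
components, the RMSIP subspace-overlap metric, and an LDA-based
replica-consistency report.

Coordinates are in Å, arrays shaped (frames, particles, 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


@dataclass(frozen=True)
class ParticleLabel:
    """(chain, residue number, atom name) identifier for one particle."""

    chain: str
    resnum: int
    atom: str = "CA"


@dataclass(frozen=True)
class Ensemble:
    """Labelled particles × frames × 3D coordinates."""

    particle_labels: tuple[ParticleLabel, ...]
    frames: np.ndarray
    superposed: bool = False
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", coords)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("frames must have shape (F, P, 3)")
        if coords.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if coords.shape[1] != len(self.particle_labels):
            raise ValueError("label count does not match particle count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_particles(self) -> int:
        return self.frames.shape[1]

    def select(self, selection) -> np.ndarray:
        """Indices of particles picked by a predicate, index list, or tag.

        ``selection`` may be ``"calpha"``, ``"calcium_ion"``, a callable
        on :class:`ParticleLabel`, or an explicit index sequence.
        """
        if selection is None or selection == "all":
            return np.arange(self.n_particles)
        if selection == "calpha":
            return np.array([i for i, p in enumerate(self.particle_labels)
                             if p.atom == "CA"], dtype=int)
        if selection == "calcium_ion":
            return np.array([i for i, p in enumerate(self.particle_labels)
                             if p.atom.upper() in ("CA2+", "CAL", "ION")], dtype=int)
        if callable(selection):
            return np.array([i for i, p in enumerate(self.particle_labels)
                             if selection(p)], dtype=int)
        return np.asarray(selection, dtype=int)


@dataclass(frozen=True)
class EssentialSubspace:
    """Ordered orthonormal PCA eigenvectors with their Å² variances."""

    eigenvectors: np.ndarray  # (3P, S), columns orthonormal
    eigenvalues: np.ndarray   # (S,), descending, Å²
    mean: np.ndarray          # (3P,), the centring used for projections

    def __post_init__(self) -> None:
        vec = np.asarray(self.eigenvectors, dtype=float)
        val = np.asarray(self.eigenvalues, dtype=float)
        object.__setattr__(self, "eigenvectors", vec)
        object.__setattr__(self, "eigenvalues", val)
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        gram = vec.T @ vec
        if not np.allclose(gram, np.eye(vec.shape[1]), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal")
        if np.any(np.diff(val) > 1e-12) or np.any(val < -1e-12):
            raise ValueError("eigenvalues must be non-negative and non-increasing")

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass(frozen=True)
class FlexProfile:
    """Per-particle RMSF (Å) over a selection."""

    rmsf: np.ndarray
    labels: tuple[ParticleLabel, ...]
    selection_tag: str = "calpha"

    def __post_init__(self) -> None:
        r = np.asarray(self.rmsf, dtype=float)
        object.__setattr__(self, "rmsf", r)
        if np.any(r < 0):
            raise ValueError("RMSF must be non-negative")


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t mapping mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, tc - rot @ mc


def superpose(ensemble: Ensemble, selection="calpha", n_rounds: int = 2) -> Ensemble:
    """Rigid-body fit of every frame onto the iteratively refined mean.

    Round 0 fits onto the raw average of the input frames; each
    subsequent round recomputes the average from the fitted frames and
    refits.  Only the ``selection`` particles drive the fit; the full
    frame is transformed.  Rotations are proper (det = +1).
    """
    sel = ensemble.select(selection)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selected particles")
    coords = ensemble.frames.copy()
    reference = coords[:, sel].mean(axis=0)
    for _ in range(n_rounds + 1):
        for f in range(coords.shape[0]):
            rot, trans = _kabsch(coords[f, sel], reference)
            coords[f] = coords[f] @ rot.T + trans
        reference = coords[:, sel].mean(axis=0)
    full_reference = coords.mean(axis=0)
    return replace(ensemble, frames=coords, superposed=True,
                   reference=full_reference)


def rmsf(ensemble: Ensemble, selection="calpha",
         selection_tag: str | None = None) -> FlexProfile:
    """Per-particle root-mean-square fluctuation about the time average.

    RMSF_p = sqrt(⟨|r_p(t) − ⟨r_p⟩|²⟩_t).  Requires a superposed
    ensemble: fluctuations are only meaningful after removing overall
    rotation and translation.
    """
    if not ensemble.superposed:
        raise RuntimeError("ensemble must be superposed before RMSF")
    sel = ensemble.select(selection)
    coords = ensemble.frames[:, sel]
    dev = coords - coords.mean(axis=0)
    vals = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    tag = selection_tag or (selection if isinstance(selection, str) else "custom")
    return FlexProfile(rmsf=vals,
                       labels=tuple(ensemble.particle_labels[i] for i in sel),
                       selection_tag=tag)


def pca(ensemble: Ensemble, selection="calpha") -> EssentialSubspace:
    """Essential dynamics: eigendecomposition of the coordinate covariance.

    Builds the 3P×3P covariance of the flattened, mean-centred selected
    coordinates (no mass weighting) and returns all eigenpairs in
    descending-variance order.  The eigenvalue sum equals the total
    coordinate variance.
    """
    if not ensemble.superposed:
        raise RuntimeError("ensemble must be superposed before PCA")
    sel = ensemble.select(selection)
    flat = ensemble.frames[:, sel].reshape(ensemble.n_frames, -1)
    if ensemble.n_frames <= flat.shape[1]:
        import warnings
        warnings.warn("fewer frames than coordinates: covariance is rank "
                      "deficient; trailing eigenvalues will be zero",
                      RuntimeWarning, stacklevel=2)
    mean = flat.mean(axis=0)
    centred = flat - mean
    cov = centred.T @ centred / flat.shape[0]
    evals, evecs = linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return EssentialSubspace(eigenvectors=evecs, eigenvalues=evals, mean=mean)


def project(ensemble: Ensemble, subspace: EssentialSubspace,
            selection="calpha", k: int = 2) -> np.ndarray:
    """Per-frame scores on the first k principal components (F × k)."""
    sel = ensemble.select(selection)
    flat = ensemble.frames[:, sel].reshape(ensemble.n_frames, -1)
    if flat.shape[1] != subspace.mean.shape[0]:
        raise ValueError("selection dimensionality does not match subspace")
    return (flat - subspace.mean) @ subspace.eigenvectors[:, :k]


def rmsip(sub_a: EssentialSubspace, sub_b: EssentialSubspace, s: int = 20) -> float:
    """Root-mean-square inner product between two essential subspaces.

    RMSIP = sqrt( (1/S) Σ_{n≤S} Σ_{m≤S} (v_n^a · v_m^b)² ), in [0, 1]:
    1 for identical subspaces, 0 for mutually orthogonal ones, and
    ≈ sqrt(S/3P) for random S-dimensional subspaces in 3P dimensions.
    """
    if sub_a.eigenvectors.shape[0] != sub_b.eigenvectors.shape[0]:
        raise ValueError("subspaces live in different dimensionalities")
    if sub_a.n_components < s or sub_b.n_components < s:
        raise ValueError(f"both subspaces need at least {s} components")
    overlap = sub_a.eigenvectors[:, :s].T @ sub_b.eigenvectors[:, :s]
    return float(np.sqrt((overlap ** 2).sum() / s))


def _bhattacharyya_gaussian(mu1, cov1, mu2, cov2) -> float:
    """Bhattacharyya coefficient of two Gaussians (closed form)."""
    cov = (cov1 + cov2) / 2.0
    diff = mu1 - mu2
    db = (diff @ np.linalg.solve(cov, diff)) / 8.0
    db += 0.5 * np.log(np.linalg.det(cov)
                       / np.sqrt(np.linalg.det(cov1) * np.linalg.det(cov2)))
    return float(np.exp(-db))


def replica_consistency(scores: np.ndarray, replica_labels) -> dict:
    """LDA classification report on per-frame PC scores, by replica.

    Fits a linear discriminant on (scores → replica label).  Consistent
    replicas occupy the same region of the essential plane, so the
    classifier stays near chance and the pairwise Gaussian
    Bhattacharyya overlap is high; separated replicas classify cleanly
    and overlap near 0.

    Returns a dict with ``accuracy``, ``chance``, ``confusion``
    (replica × replica counts) and ``overlap`` (pairwise coefficient
    in [0, 1]).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(replica_labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two replicas to compare")
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("need at least two score dimensions")

    lda = LinearDiscriminantAnalysis()
    pred = lda.fit(scores, labels).predict(scores)
    accuracy = float(np.mean(pred == labels))
    confusion = {
        (str(a), str(b)): int(np.sum((labels == a) & (pred == b)))
        for a in uniq for b in uniq
    }

    gaussians = {}
    for lab in uniq:
        pts = scores[labels == lab]
        mu = pts.mean(axis=0)
        cov = np.cov(pts.T)
        if np.allclose(cov, 0.0):
            cov = cov + np.eye(scores.shape[1]) * 1e-12
        gaussians[lab] = (mu, cov)
    overlap = {}
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            bc = _bhattacharyya_gaussian(*gaussians[a], *gaussians[b])
            overlap[(str(a), str(b))] = min(bc, 1.0)

    return {
        "accuracy": accuracy,
        "chance": 1.0 / uniq.size,
        "confusion": confusion,
        "overlap": overlap,
    }
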