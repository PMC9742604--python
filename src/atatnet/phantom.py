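"""Synthetic fMRI phantoms with a known parcellation and planted connectivity.

The simulator emulates the data layer of a resting-state connectivity study:
an AAL-style atlas of N non-overlapping spherical ROIs placed in a 3-D voxel
grid, per-ROI latent time series drawn from a class-dependent covariance
(so that "diagnostic groups" differ in known edges), and voxel intensities
equal to the ROI signal plus independent Gaussian noise.  From the 4-D
volume the "empirical" ROI time series F_e (ROI-mean, standardized) and the
empirical Pearson connectivity A_e are computed; these play the role of the
toolbox-derived truth samples that the adversarial generator is trained to
match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Atlas",
    "PhantomSpec",
    "Subject",
    "make_atlas",
    "normalize_embeddings",
    "simulate_phantom",
    "extract_empirical_series",
    "pearson_fc",
    "block_covariance",
    "hub_covariance",
    "edge_covariance",
    "simulate_cohort",
]

ATLAS_COLUMNS = ["index", "name", "cx", "cy", "cz", "volume"]


class InvalidAtlasError(ValueError):
    pass


class GeometryError(ValueError):
    pass


@dataclass
class Atlas:
    """ROI table (1-based indices, 0-based voxel center coordinates) plus voxel masks."""

    table: pd.DataFrame
    masks: list[np.ndarray]  # one boolean (X,Y,Z) mask per ROI

    @property
    def n_rois(self) -> int:
        return len(self.table)

    def validate(self, grid_shape: tuple[int, int, int]) -> None:
        idx = self.table["index"].to_numpy()
        if len(idx) < 2:
            raise InvalidAtlasError("an atlas needs at least 2 ROIs")
        if not np.array_equal(np.sort(idx), np.arange(1, len(idx) + 1)):
            raise InvalidAtlasError("ROI indices must be unique and contiguous from 1")
        centers = self.table[["cx", "cy", "cz"]].to_numpy()
        if (centers < 0).any() or (centers >= np.array(grid_shape)).any():
            raise InvalidAtlasError("ROI centers outside grid bounds")
        if (self.table["volume"].to_numpy() < 1).any():
            raise InvalidAtlasError("every ROI must contain at least one voxel")
        total = np.zeros(grid_shape, dtype=np.int64)
        for m in self.masks:
            total += m
        if (total > 1).any():
            raise GeometryError("ROI voxel sets overlap")


def _sphere_mask(grid_shape: tuple[int, int, int], center: tuple[int, int, int],
                 radius: float) -> np.ndarray:
    gx, gy, gz = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    cx, cy, cz = center
    return (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= radius ** 2


def make_atlas(grid_shape: tuple[int, int, int], n_rois: int, radius: int) -> Atlas:
    """Place ``n_rois`` non-overlapping spheres on a regular lattice.

    Centers are spaced ``2*radius + 1`` voxels apart so spheres cannot touch;
    raises :class:`GeometryError` when the grid cannot hold them.
    """
    step = 2 * radius + 1
    slots = []
    for x in range(radius, grid_shape[0] - radius, step):
        for y in range(radius, grid_shape[1] - radius, step):
            for z in range(radius, grid_shape[2] - radius, step):
                slots.append((x, y, z))
    if len(slots) < n_rois:
        raise GeometryError(
            f"grid {grid_shape} holds only {len(slots)} spheres of radius {radius}, "
            f"need {n_rois}")
    rows, masks = [], []
    for i, center in enumerate(slots[:n_rois], start=1):
        mask = _sphere_mask(grid_shape, center, radius)
        rows.append({"index": i, "name": f"ROI{i}", "cx": center[0], "cy": center[1],
                     "cz": center[2], "volume": int(mask.sum())})
        masks.append(mask)
    atlas = Atlas(pd.DataFrame(rows, columns=ATLAS_COLUMNS), masks)
    atlas.validate(grid_shape)
    return atlas


def normalize_embeddings(atlas: Atlas | pd.DataFrame) -> np.ndarray:
    """Min-max scale (cx, cy, cz, volume) across ROIs into [0, 1].

    Returns an (N, 4) array of unitless ROI embeddings (ex, ey, ez, ev).
    A component constant across ROIs maps to 0.5 everywhere.
    """
    table = atlas.table if isinstance(atlas, Atlas) else atlas
    if len(table) < 2:
        raise InvalidAtlasError("embedding normalization needs at least 2 ROIs")
    raw = table[["cx", "cy", "cz", "volume"]].to_numpy(dtype=np.float64)
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    emb = np.full_like(raw, 0.5)
    varying = span > 0
    emb[:, varying] = (raw[:, varying] - lo[varying]) / span[varying]
    return emb


@dataclass
class PhantomSpec:
    """Study conditions for one phantom cohort."""

    grid_shape: tuple[int, int, int]
    n_rois: int
    n_timepoints: int
    roi_radius: int
    class_covariances: dict[int, np.ndarray]
    noise_sd: float = 0.5
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr: float = 2.0  # repetition time, seconds

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise standard deviation must be nonnegative")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        for label, cov in self.class_covariances.items():
            cov = np.asarray(cov)
            if cov.shape != (self.n_rois, self.n_rois):
                raise ValueError(f"covariance for class {label} has shape {cov.shape}")
            if not np.allclose(cov, cov.T, atol=1e-12):
                raise ValueError(f"covariance for class {label} is not symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-8:
                raise ValueError(f"covariance for class {label} is not positive semidefinite")
        # raises GeometryError when the spheres do not fit
        make_atlas(self.grid_shape, self.n_rois, self.roi_radius)


@dataclass
class Subject:
    """One simulated scan with its derived empirical features."""

    subject_id: str
    label: int
    volume: np.ndarray          # (X, Y, Z, T)
    atlas: Atlas
    embeddings: np.ndarray      # (N, 4)
    ground_truth: np.ndarray    # (N, T) latent ROI series
    f_e: np.ndarray = field(default=None)  # type: ignore[assignment]
    a_e: np.ndarray = field(default=None)  # type: ignore[assignment]


def simulate_phantom(spec: PhantomSpec, class_label: int, seed: int
                     ) -> tuple[np.ndarray, Atlas, np.ndarray]:
    """Simulate one 4-D volume for a subject of the given class.

    Ground-truth ROI series are drawn i.i.d. over time from a zero-mean
    multivariate normal with the class covariance; every in-ROI voxel carries
    its ROI's series plus independent Gaussian noise, out-of-ROI voxels carry
    pure noise.  Bit-reproducible for identical (spec, class, seed).
    """
    spec.validate()
    if class_label not in spec.class_covariances:
        raise ValueError(f"unknown class label {class_label}")
    rng = np.random.default_rng(seed)
    atlas = make_atlas(spec.grid_shape, spec.n_rois, spec.roi_radius)
    cov = np.asarray(spec.class_covariances[class_label], dtype=np.float64)
    # Cholesky-style sampling via eigendecomposition keeps PSD matrices valid.
    evals, evecs = np.linalg.eigh(cov)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    gt = root @ rng.standard_normal((spec.n_rois, spec.n_timepoints))
    if spec.noise_sd > 0:
        volume = rng.normal(0.0, spec.noise_sd,
                            size=spec.grid_shape + (spec.n_timepoints,))
    else:
        volume = np.zeros(spec.grid_shape + (spec.n_timepoints,))
    for i, mask in enumerate(atlas.masks):
        volume[mask, :] += gt[i]
    return volume, atlas, gt


def extract_empirical_series(volume: np.ndarray, atlas: Atlas) -> np.ndarray:
    """ROI-mean time series, each row standardized to zero mean / unit variance.

    Zero-variance rows are flagged with a warning and replaced by zeros.
    """
    n_t = volume.shape[3]
    series = np.empty((atlas.n_rois, n_t))
    for i, mask in enumerate(atlas.masks):
        if not mask.any():
            raise InvalidAtlasError(f"ROI {i + 1} has an empty voxel set")
        series[i] = volume[mask, :].mean(axis=0)
    mu = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    flat = sd.reshape(-1) == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} ROI(s) have constant signal; rows set to zero",
                      RuntimeWarning, stacklevel=2)
        sd[flat] = 1.0
    out = (series - mu) / sd
    out[flat] = 0.0
    return out


def pearson_fc(series: np.ndarray) -> np.ndarray:
    """Pearson correlation between paired ROI time series.

    Symmetric with unit diagonal; all-zero rows correlate as 0 by convention
    so downstream matrices stay finite.
    """
    series = np.asarray(series, dtype=np.float64)
    n, q = series.shape
    if q < 3:
        raise ValueError("need at least 3 time points for a correlation")
    mu = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    zero = sd.reshape(-1) == 0
    sd[zero] = 1.0
    z = (series - mu) / sd
    corr = z @ z.T / q
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


# --------------------------------------------------------------- covariances

def block_covariance(n_rois: int, blocks: list[list[int]], r_within: float,
                     r_background: float = 0.0) -> np.ndarray:
    """Unit-variance covariance with correlation ``r_within`` inside each block."""
    cov = np.full((n_rois, n_rois), r_background)
    for block in blocks:
        for i in block:
            for j in block:
                if i != j:
                    cov[i, j] = r_within
    np.fill_diagonal(cov, 1.0)
    _check_psd(cov)
    return cov


def hub_covariance(n_rois: int, hub: int, r: float) -> np.ndarray:
    """Unit-variance covariance where one hub ROI correlates ``r`` with all others."""
    cov = np.eye(n_rois)
    cov[hub, :] = r
    cov[:, hub] = r
    cov[hub, hub] = 1.0
    _check_psd(cov)
    return cov


def edge_covariance(n_rois: int, edges: list[tuple[int, int]], r: float,
                    base: np.ndarray | None = None) -> np.ndarray:
    """Set correlation ``r`` on the listed (i, j) pairs of a base covariance."""
    cov = np.eye(n_rois) if base is None else np.array(base, dtype=np.float64)
    for i, j in edges:
        cov[i, j] = cov[j, i] = r
    _check_psd(cov)
    return cov


def _check_psd(cov: np.ndarray) -> None:
    if np.linalg.eigvalsh(cov).min() < -1e-8:
        raise ValueError("requested correlation structure is not positive semidefinite")


def simulate_cohort(spec: PhantomSpec, n_per_class: dict[int, int], seed: int
                    ) -> list[Subject]:
    """Simulate a labelled cohort; one spawned seed per subject."""
    spec.validate()
    n_total = sum(n_per_class.values())
    child_seeds = np.random.SeedSequence(seed).generate_state(n_total) % (2 ** 31)
    subjects: list[Subject] = []
    k = 0
    for label in sorted(n_per_class):
        for j in range(n_per_class[label]):
            vol, atlas, gt = simulate_phantom(spec, label, int(child_seeds[k]))
            emb = normalize_embeddings(atlas)
            f_e = extract_empirical_series(vol, atlas)
            a_e = pearson_fc(f_e)
            subjects.append(Subject(subject_id=f"sub-{k + 1:03d}", label=label,
                                    volume=vol, atlas=atlas, embeddings=emb,
                                    ground_truth=gt, f_e=f_e, a_e=a_e))
            k += 1
    return subjects
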