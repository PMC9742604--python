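"""Readers/writers: NIfTI volumes, TSV tables, flat TOML configs, manifests."""

from __future__ import annotations

import hashlib
import tomllib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import ATLAS_COLUMNS, Atlas, _sphere_mask

__all__ = [
    "save_volume", "load_volume", "save_atlas", "load_atlas",
    "save_matrix", "load_matrix", "save_series", "load_series",
    "load_config", "save_config", "write_manifest", "sha256_of",
]


def save_volume(path, volume: np.ndarray, spacing=(3.0, 3.0, 3.0), tr: float = 2.0) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine)
    img.header.set_zooms((*spacing, tr))
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)


def save_atlas(path, atlas: Atlas) -> None:
    atlas.table[ATLAS_COLUMNS].to_csv(path, sep="\t", index=False)


def load_atlas(path, grid_shape: tuple[int, int, int], radius: int) -> Atlas:
    table = pd.read_csv(path, sep="\t")
    missing = set(ATLAS_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"atlas file lacks columns {sorted(missing)}")
    masks = [_sphere_mask(grid_shape, (r.cx, r.cy, r.cz), radius)
             for r in table.itertuples()]
    atlas = Atlas(table[ATLAS_COLUMNS], masks)
    atlas.validate(grid_shape)
    return atlas


def _roi_labels(n: int) -> list[str]:
    return [f"ROI{i}" for i in range(1, n + 1)]


def save_matrix(path, matrix: np.ndarray) -> None:
    labels = _roi_labels(matrix.shape[0])
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def load_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=np.float64)


def save_series(path, series: np.ndarray) -> None:
    frame = pd.DataFrame(series, index=_roi_labels(series.shape[0]),
                         columns=[f"t{t}" for t in range(series.shape[1])])
    frame.to_csv(path, sep="\t")


def load_series(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=np.float64)


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def save_config(path, config: dict) -> None:
    lines = []
    for key, value in config.items():
        if isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        elif isinstance(value, bool):
            lines.append(f"{key} = {str(value).lower()}")
        elif isinstance(value, (list, tuple)):
            lines.append(f"{key} = [{', '.join(repr(v) for v in value)}]")
        else:
            lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, files: list[Path]) -> Path:
    out_dir = Path(out_dir)
    rows = [{"file": str(f.relative_to(out_dir)), "sha256": sha256_of(f)}
            for f in sorted(files)]
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
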