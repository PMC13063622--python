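"""File-format glue: CSV dialects, image IO, run manifests.

CSV dialect everywhere: comma-separated, UTF-8, mandatory header row,
period decimal separator.  Canonical internal units are mM, g/L, h, px.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imaging import SyntheticImage
from .inference import ARProfile, deviation_report

__all__ = [
    "write_ar_profile",
    "write_trace",
    "read_image",
    "write_image",
    "write_labels",
    "write_manifest",
]


def write_ar_profile(profile: ARProfile, path, rel_tol: float = 0.3) -> Path:
    """Write an AR profile (with deviation flags) as CSV."""
    path = Path(path)
    deviation_report(profile, rel_tol=rel_tol).to_csv(path, index=False)
    return path


def write_trace(trace, path) -> Path:
    """Write a culture trace in tidy long format (time, pH_out, variable, value)."""
    path = Path(path)
    trace.to_tidy().to_csv(path, index=False)
    return path


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG as a float array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse an accidental colour axis
        img = img.mean(axis=-1)
    return img.astype(float)


def write_image(image: np.ndarray, path) -> Path:
    """Write a float image as 16-bit grayscale TIFF or PNG (clipped)."""
    path = Path(path)
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    return path


def write_labels(synthetic: SyntheticImage, stem: Path) -> tuple[Path, Path]:
    """Emit ground truth: labelled-mask TIFF plus true-fraction CSV."""
    import tifffile

    stem = Path(stem)
    mask_path = stem.with_suffix(".labels.tif")
    truth_path = stem.with_suffix(".truth.csv")
    tifffile.imwrite(mask_path, synthetic.labels.astype(np.uint16))
    synthetic.truth.to_csv(truth_path, index=False)
    return mask_path, truth_path


def write_manifest(out_dir, subcommand: str, config: dict, seed: int | None) -> Path:
    """Write the reproducibility manifest beside a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "symporteq",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
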