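"""Reading and writing fields, masks, counts and score tables.

Images go to 8-bit RGB PNG; masks to single-channel PNG holding 0/255 on
disk (mapped to 0/1 in memory). Per-field cohort metadata is a CSV with
header ``sample_id,field_index,race,stage,gleason,true_blue,true_red``.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import SyntheticField

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "save_cohort",
    "load_cohort_metadata",
]

METADATA_COLUMNS = [
    "sample_id",
    "field_index",
    "race",
    "stage",
    "gleason",
    "true_blue",
    "true_red",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB micrograph (PNG/TIFF) as (H, W, 3) uint8."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return np.asarray(img, dtype=np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG (0/255 on disk) as (H, W) uint8 in {0, 1}."""
    m = iio.imread(path)
    if m.ndim == 3:
        m = m[..., 0]
    return (np.asarray(m) > 127).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def save_cohort(
    fields: list[SyntheticField], metadata: pd.DataFrame, out_dir: str | Path
) -> pd.DataFrame:
    """Write fields/masks as PNGs plus the per-field metadata CSV.

    Returns the per-field metadata table that was written.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    sample_meta = metadata.set_index("sample_id")
    rows = []
    for f in fields:
        stem = f"{f.sample_id}_f{f.field_index:02d}"
        write_image(out / "images" / f"{stem}.png", f.image)
        write_mask(out / "masks" / f"{stem}_blue.png", f.blue_mask)
        write_mask(out / "masks" / f"{stem}_red.png", f.red_mask)
        meta = sample_meta.loc[f.sample_id]
        rows.append(
            {
                "sample_id": f.sample_id,
                "field_index": f.field_index,
                "race": meta["race"],
                "stage": meta["stage"],
                "gleason": meta["gleason"],
                "true_blue": f.true_blue_count,
                "true_red": f.true_red_count,
            }
        )
    table = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    table.to_csv(out / "metadata.csv", index=False)
    return table


def load_cohort_metadata(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return table
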