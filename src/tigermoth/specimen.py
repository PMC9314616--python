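"""Multichannel specimen container and on-disk cohort format.

A specimen is a set of four co-registered reflectance rasters (``uv``,
``sw``, ``mw``, ``lw`` — ultraviolet, short-, medium-, long-wavelength
camera channels) together with an integer region-of-interest mask over
forewing (FW), hindwing (HW), thorax (TH) and abdomen (AB).

On disk a cohort is: one multi-page 32-bit float TIFF per specimen
(pages ordered uv, sw, mw, lw), one 8-bit label PNG mask (0=background,
1=FW, 2=HW, 3=TH, 4=AB) and a manifest CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "ROI_LABELS",
    "ROI_NAMES",
    "MultichannelSpecimen",
    "write_cohort",
    "read_cohort",
]

#: Camera channel order used everywhere (and as TIFF page order).
CHANNELS = ("uv", "sw", "mw", "lw")

#: Mask label for each region of interest (0 is background).
ROI_LABELS = {"FW": 1, "HW": 2, "TH": 3, "AB": 4}
ROI_NAMES = tuple(ROI_LABELS)


@dataclass
class MultichannelSpecimen:
    """Four co-registered channel rasters plus an ROI label mask."""

    id: str
    channels: dict[str, np.ndarray]
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"specimen {self.id}: missing channels {missing}")
        shape = self.mask.shape
        for c in CHANNELS:
            arr = np.asarray(self.channels[c], dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"specimen {self.id}: channel {c} shape {arr.shape} != mask {shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"specimen {self.id}: non-finite values in {c}")
            self.channels[c] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def roi_pixels(self, roi: str) -> np.ndarray:
        """Boolean mask of pixels belonging to ``roi`` (FW/HW/TH/AB)."""
        if roi not in ROI_LABELS:
            raise ValueError(f"unknown ROI {roi!r}; expected one of {ROI_NAMES}")
        return self.mask == ROI_LABELS[roi]


def write_cohort(cohort: list[MultichannelSpecimen], outdir: str | Path) -> pd.DataFrame:
    """Write specimens as TIFF + PNG pairs and return the manifest table."""
    import tifffile
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in cohort:
        stack = np.stack([spec.channels[c] for c in CHANNELS]).astype(np.float32)
        tif = outdir / f"{spec.id}.tif"
        png = outdir / f"{spec.id}_mask.png"
        tifffile.imwrite(tif, stack, photometric="minisblack")
        Image.fromarray(spec.mask.astype(np.uint8)).save(png)
        rows.append(
            {
                "id": spec.id,
                "image": tif.name,
                "mask": png.name,
                **{k: v for k, v in spec.meta.items() if np.isscalar(v) or v is None},
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_cohort(indir: str | Path) -> list[MultichannelSpecimen]:
    """Read a cohort written by :func:`write_cohort`."""
    import tifffile
    from PIL import Image

    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    cohort = []
    for row in manifest.to_dict("records"):
        stack = tifffile.imread(indir / row["image"])
        mask = np.asarray(Image.open(indir / row["mask"]), dtype=np.int64)
        channels = {c: stack[i].astype(float) for i, c in enumerate(CHANNELS)}
        meta = {k: v for k, v in row.items() if k not in ("id", "image", "mask")}
        cohort.append(MultichannelSpecimen(str(row["id"]), channels, mask, meta))
    return cohort
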