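"""On-disk dataset layout and image serialization.

A generated dataset directory contains::

    manifest.csv            case_id, slice_position, map_kind, image_path,
                            contour_path, split
    images/<name>.png       16-bit grayscale + <name>.json sidecar with
                            {pixel_spacing_mm, map_kind, slice_position,
                             scale, offset}  (value = png * scale + offset)
    contours/<name>.json    {"epi": [[x, y], ...], "endo": [[x, y], ...]}
    masks/<name>.png        8-bit class labels {0, 1, 2} (predictions)

Images can alternatively be written as single-slice NIfTI (float data, pixel
spacing in the header); readers dispatch on the extension.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .geometry import ContourPointSet, SegmentationMask, contours_from_json, contours_to_json
from .phantom import MapImage, PhantomCase


def save_map_png(path, map_image: MapImage) -> None:
    """16-bit PNG plus JSON sidecar carrying the affine value scaling."""
    path = Path(path)
    data = np.nan_to_num(np.asarray(map_image.data, dtype=float))
    lo, hi = float(data.min()), float(data.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    encoded = np.round((data - lo) / scale).astype(np.uint16)
    Image.fromarray(encoded, mode="I;16").save(path)
    sidecar = {
        "pixel_spacing_mm": list(map_image.pixel_spacing_mm),
        "map_kind": map_image.map_kind,
        "slice_position": map_image.slice_position,
        "scale": scale,
        "offset": lo,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_map_png(path) -> MapImage:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    raw = np.asarray(Image.open(path), dtype=float)
    data = raw * sidecar["scale"] + sidecar["offset"]
    return MapImage(
        data=data,
        pixel_spacing_mm=tuple(sidecar["pixel_spacing_mm"]),
        slice_position=sidecar["slice_position"],
        map_kind=sidecar["map_kind"],
    )


def save_map_nifti(path, map_image: MapImage) -> None:
    affine = np.diag([map_image.pixel_spacing_mm[1], map_image.pixel_spacing_mm[0], 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(map_image.data, dtype=np.float32).T[:, :, None], affine)
    img.header.set_zooms((map_image.pixel_spacing_mm[1], map_image.pixel_spacing_mm[0], 1.0))
    nib.save(img, str(path))


def load_map_nifti(path, map_kind: str = "T1map", slice_position: str = "") -> MapImage:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    data = np.asarray(img.dataobj)[:, :, 0].T
    return MapImage(data=data, pixel_spacing_mm=(float(zooms[1]), float(zooms[0])),
                    slice_position=slice_position, map_kind=map_kind)


def load_map(path) -> MapImage:
    path = Path(path)
    if path.suffix == ".png":
        return load_map_png(path)
    return load_map_nifti(path)


def save_mask_png(path, mask: SegmentationMask) -> None:
    Image.fromarray(mask.labels, mode="L").save(path)


def load_mask_png(path, pixel_spacing_mm=(1.5, 1.5)) -> SegmentationMask:
    return SegmentationMask(np.asarray(Image.open(path), dtype=np.uint8), pixel_spacing_mm)


def write_dataset(
    out_dir,
    cases: list[PhantomCase],
    split_of: dict[str, str] | None = None,
    image_format: str = "png",
) -> pd.DataFrame:
    """Write a phantom cohort as an on-disk dataset; returns the manifest.

    One image file per fitted parametric map (and its sidecar metadata), one
    contour JSON per slice, one manifest row per image.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "contours").mkdir(exist_ok=True)
    rows = []
    for case in cases:
        for sl in case.slices:
            pos = sl.geometry.slice_position
            stem = f"{case.case_id}_{pos}"
            contour_path = out_dir / "contours" / f"{stem}.json"
            contour_path.write_text(contours_to_json(sl.epi_contour, sl.endo_contour))
            for map_image in (sl.fitted_t1, sl.fitted_t2):
                if map_image is None:
                    continue
                name = f"{stem}_{map_image.map_kind}"
                if image_format == "png":
                    image_path = out_dir / "images" / f"{name}.png"
                    save_map_png(image_path, map_image)
                else:
                    image_path = out_dir / "images" / f"{name}.nii.gz"
                    save_map_nifti(image_path, map_image)
                rows.append(
                    {
                        "case_id": case.case_id,
                        "slice_position": pos,
                        "map_kind": map_image.map_kind,
                        "image_path": str(image_path.relative_to(out_dir)),
                        "contour_path": str(contour_path.relative_to(out_dir)),
                        "split": split_of.get(case.case_id, "") if split_of else "",
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(dataset_dir) -> pd.DataFrame:
    return pd.read_csv(Path(dataset_dir) / "manifest.csv").fillna({"split": ""})


def load_contours(dataset_dir, contour_path) -> tuple[ContourPointSet, ContourPointSet]:
    return contours_from_json((Path(dataset_dir) / contour_path).read_text())
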