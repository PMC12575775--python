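"""Readers, writers and dataset manifests.

Supported sample formats: 8/16-bit grayscale PNG, MetaImage (.mhd/.raw,
minimal dialect) and NIfTI (.nii/.nii.gz).  Images are rescaled to [0, 1] on
read; 16-bit PNG is written for images to limit quantization and 8-bit for
masks.  Mask label integers follow the CAMUS dialect {1: LV, 2: MYO, 3: LA};
label 3 is remapped to background on read because the atrium is out of scope.

Spacing precedence: a format header that carries spacing (MetaImage, NIfTI)
wins over the manifest record; a conflict is logged as a warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .errors import InvalidArgumentError, LoadError
from .geometry import SectorGeometry
from .transforms import LabeledSample

logger = logging.getLogger("echoaug")

MANIFEST_VERSION = 1
DEFAULT_REMAP = {3: 0}

__all__ = [
    "read_sample",
    "load_manifest",
    "save_manifest",
    "load_dataset",
    "write_augmented_dataset",
    "validate_nnunet_layout",
]


# ---------------------------------------------------------------------------
# low-level format helpers
# ---------------------------------------------------------------------------

def _read_png(path):
    with Image.open(path) as im:
        arr = np.array(im)
    if arr.ndim != 2:
        raise LoadError(f"{path}: expected single-channel grayscale PNG")
    return arr, None  # PNG carries no spacing


def write_png_image(path, image):
    """16-bit grayscale PNG from a float image in [0, 1]."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    data = np.round(arr * 65535.0).astype(np.uint16)
    Image.fromarray(data).save(path)  # uint16 -> 16-bit grayscale PNG


def write_png_mask(path, mask):
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


_MHD_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}


def read_mhd(path):
    """Minimal MetaImage reader (2-D, local uncompressed raw)."""
    path = Path(path)
    header = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            header[k.strip()] = v.strip()
    try:
        ndims = int(header["NDims"])
        dims = [int(x) for x in header["DimSize"].split()]
        dtype = _MHD_TYPES[header["ElementType"]]
        datafile = header["ElementDataFile"]
    except KeyError as exc:
        raise LoadError(f"{path}: missing MetaImage header key {exc}") from exc
    if ndims != 2:
        raise LoadError(f"{path}: only 2-D MetaImage supported, got NDims={ndims}")
    spacing_xy = [float(x) for x in header.get("ElementSpacing", "1 1").split()]
    raw = (path.parent / datafile).read_bytes()
    arr = np.frombuffer(raw, dtype=dtype).reshape(dims[1], dims[0])  # (rows, cols)
    spacing = (spacing_xy[1], spacing_xy[0])  # header stores (x=col, y=row)
    return arr, spacing


def write_mhd(path, array, spacing=(1.0, 1.0)):
    path = Path(path)
    arr = np.ascontiguousarray(array)
    inv = {v: k for k, v in _MHD_TYPES.items()}
    try:
        etype = inv[arr.dtype.type]
    except KeyError as exc:
        raise InvalidArgumentError(f"unsupported MetaImage dtype {arr.dtype}") from exc
    raw_name = path.with_suffix(".raw").name
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 2",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            f"DimSize = {arr.shape[1]} {arr.shape[0]}",
            f"ElementSpacing = {spacing[1]} {spacing[0]}",
            f"ElementType = {etype}",
            f"ElementDataFile = {raw_name}",
        ]
    )
    path.write_text(header + "\n")
    (path.parent / raw_name).write_bytes(arr.tobytes())


def read_nifti(path):
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise LoadError(f"{path}: expected a 2-D NIfTI volume, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:2]
    return arr, (float(zooms[0]), float(zooms[1]))


def write_nifti(path, array, spacing=(1.0, 1.0)):
    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def _read_any(path):
    suffix = "".join(Path(path).suffixes).lower()
    if suffix.endswith(".png"):
        return _read_png(path)
    if suffix.endswith(".mhd"):
        return read_mhd(path)
    if suffix.endswith(".nii") or suffix.endswith(".nii.gz"):
        return read_nifti(path)
    raise LoadError(f"unsupported sample format: {path}")


def _to_unit_image(arr):
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if arr.dtype == np.int32:  # PIL 'I' mode for 16-bit PNGs
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        raise LoadError("float image values must already lie in [0, 1]")
    return arr


# ---------------------------------------------------------------------------
# samples and manifests
# ---------------------------------------------------------------------------

def geometry_to_dict(geom: SectorGeometry | None):
    if geom is None:
        return None
    return {
        "apex": list(geom.apex),
        "opening_angle": geom.opening_angle,
        "radius": geom.radius,
        "axis_angle": geom.axis_angle,
    }


def geometry_from_dict(d):
    if d is None:
        return None
    return SectorGeometry(
        apex=tuple(d["apex"]),
        opening_angle=d["opening_angle"],
        radius=d["radius"],
        axis_angle=d.get("axis_angle", 0.0),
    )


def read_sample(image_path, mask_path, record=None) -> LabeledSample:
    """Load an image/mask pair into a :class:`LabeledSample`.

    ``record`` is the manifest entry for the sample (spacing, optional
    geometry, view/cycle metadata).
    """
    record = record or {}
    image_raw, img_spacing = _read_any(image_path)
    mask_raw, mask_spacing = _read_any(mask_path)
    image = _to_unit_image(image_raw)
    mask = np.asarray(mask_raw)
    if not np.isin(mask, (0, 1, 2, 3)).all():
        raise LoadError(
            f"{mask_path}: mask labels outside {{0,1,2,3}}: {np.unique(mask)}"
        )
    if image.shape != mask.shape:
        raise LoadError(
            f"image {image.shape} / mask {mask.shape} shape mismatch for {image_path}"
        )
    remap = record.get("label_remap", DEFAULT_REMAP)
    mask = mask.copy()
    for src, dst in remap.items():
        mask[mask == int(src)] = dst

    manifest_spacing = record.get("spacing")
    header_spacing = img_spacing
    if header_spacing is not None and manifest_spacing is not None:
        if not np.allclose(header_spacing, manifest_spacing):
            logger.warning(
                "spacing conflict for %s: header %s vs manifest %s; header wins",
                image_path,
                header_spacing,
                tuple(manifest_spacing),
            )
    spacing = header_spacing or (tuple(manifest_spacing) if manifest_spacing else (1.0, 1.0))
    if spacing[0] <= 0 or spacing[1] <= 0:
        raise LoadError(f"non-positive spacing {spacing} for {image_path}")

    return LabeledSample(
        image=image,
        mask=mask,
        geometry=geometry_from_dict(record.get("geometry")),
        spacing=spacing,
        provenance=list(record.get("provenance", [])),
    )


def save_manifest(path, records):
    payload = {"version": MANIFEST_VERSION, "samples": records}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_manifest(path):
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != MANIFEST_VERSION:
        raise LoadError(f"{path}: unsupported manifest version {payload.get('version')}")
    records = payload["samples"]
    base = Path(path).parent
    for rec in records:
        for key in ("image", "mask"):
            if key in rec and not Path(rec[key]).is_absolute():
                rec[key] = str(base / rec[key])
        for key in ("image", "mask"):
            if key in rec and not Path(rec[key]).exists():
                raise LoadError(f"manifest path does not exist: {rec[key]}")
    return records


def load_dataset(directory):
    """All samples listed in ``<directory>/manifest.json``."""
    records = load_manifest(Path(directory) / "manifest.json")
    return [read_sample(r["image"], r["mask"], r) for r in records]


# ---------------------------------------------------------------------------
# dataset writing
# ---------------------------------------------------------------------------

def _record_for(sample: LabeledSample, image_name, mask_name, extra=None):
    rec = {
        "image": image_name,
        "mask": mask_name,
        "view": "unknown",
        "cycle": None,
        "frame_role": "other",
        "spacing": list(sample.spacing),
        "geometry": geometry_to_dict(sample.geometry),
        "patient_id": None,
    }
    if extra:
        rec.update(extra)
    return rec


def write_augmented_dataset(
    samples, out_dir, layout: str = "native", force: bool = False, name: str = "echoaug"
):
    """Write samples as PNG pairs plus manifest and provenance JSON.

    ``layout='native'`` mirrors the package's own manifest layout;
    ``layout='nnunet'`` emits ``imagesTr``/``labelsTr`` naming with a dataset
    description file.  Returns the manifest path.
    """
    out = Path(out_dir)
    if layout not in ("native", "nnunet"):
        raise InvalidArgumentError(f"unknown layout {layout!r}")
    manifest_path = out / ("dataset.json" if layout == "nnunet" else "manifest.json")
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    records = []
    provenance = {}
    if layout == "native":
        for i, s in enumerate(samples):
            img_name = f"sample_{i:04d}.png"
            msk_name = f"sample_{i:04d}_mask.png"
            write_png_image(out / img_name, s.image)
            write_png_mask(out / msk_name, s.mask)
            records.append(_record_for(s, img_name, msk_name))
            provenance[img_name] = s.provenance
        save_manifest(manifest_path, records)
    else:
        (out / "imagesTr").mkdir(exist_ok=True)
        (out / "labelsTr").mkdir(exist_ok=True)
        for i, s in enumerate(samples):
            img_name = f"imagesTr/{name}_{i:04d}_0000.png"
            msk_name = f"labelsTr/{name}_{i:04d}.png"
            write_png_image(out / img_name, s.image)
            write_png_mask(out / msk_name, s.mask)
            records.append(_record_for(s, img_name, msk_name))
            provenance[img_name] = s.provenance
        dataset = {
            "name": name,
            "channel_names": {"0": "ultrasound"},
            "labels": {"background": 0, "LV": 1, "MYO": 2},
            "numTraining": len(samples),
            "file_ending": ".png",
        }
        manifest_path.write_text(json.dumps(dataset, indent=1, sort_keys=True))
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True, default=_json_default)
    )
    return manifest_path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


_NNUNET_IMG = re.compile(r"^[A-Za-z0-9]+_\d{4}_\d{4}\.png$")
_NNUNET_LBL = re.compile(r"^[A-Za-z0-9]+_\d{4}\.png$")


def validate_nnunet_layout(directory):
    """Check imagesTr/labelsTr naming and pairing; returns the case ids."""
    d = Path(directory)
    images = sorted(p.name for p in (d / "imagesTr").glob("*.png"))
    labels = sorted(p.name for p in (d / "labelsTr").glob("*.png"))
    if not images or not (d / "dataset.json").exists():
        raise InvalidArgumentError(f"{directory} is not an nnU-Net style dataset")
    for name in images:
        if not _NNUNET_IMG.match(name):
            raise InvalidArgumentError(f"bad image name {name}")
    for name in labels:
        if not _NNUNET_LBL.match(name):
            raise InvalidArgumentError(f"bad label name {name}")
    cases_img = {n.rsplit("_", 2)[0] + "_" + n.rsplit("_", 2)[1] for n in images}
    cases_lbl = {n[: -len(".png")] for n in labels}
    if cases_img != cases_lbl:
        raise InvalidArgumentError("imagesTr and labelsTr cases do not match")
    return sorted(cases_lbl)
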