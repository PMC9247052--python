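"""Data model, I/O and preprocessing for medical hyperspectral (HSI) datacubes.

An HSI recording is a 3-D reflectance array (two spatial axes, one spectral
axis of 100 bands from 500 to 995 nm in 5 nm steps, the grid of TIVITA-class
push-broom cameras).  Expert annotations mark one organ region per record.
Preprocessing follows the standard recipe for this class of data:

1. every pixel spectrum is l1-normalized (divided by its band sum) so that
   global illumination scale cancels;
2. one median spectrum per annotation is computed band-wise over the mask.

The median of unit-sum spectra is not itself exactly unit-sum; the extracted
spectrum is re-normalized to sum 1 and the pre-renormalization sum recorded.

Coordinate convention: arrays are indexed ``[y, x, band]`` (row, column,
band); masks are boolean rasters of the same height x width as the cube.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ORGAN_CLASSES",
    "ANGLES",
    "REFERENCE_ORGAN",
    "REFERENCE_ANGLE",
    "WavelengthGrid",
    "Datacube",
    "AnnotationRecord",
    "MedianSpectrum",
    "SpectraTable",
    "make_wavelength_grid",
    "l1_normalize_pixels",
    "extract_median_spectrum",
    "build_spectra_table",
    "read_dataset",
    "write_dataset",
]

#: The 20 porcine organ / tissue classes of the atlas.
ORGAN_CLASSES: tuple[str, ...] = (
    "stomach",
    "jejunum",
    "colon",
    "liver",
    "gallbladder",
    "pancreas",
    "kidney",
    "spleen",
    "bladder",
    "omentum",
    "lung",
    "heart",
    "cartilage",
    "bone",
    "skin",
    "muscle",
    "peritoneum",
    "vena_cava",
    "kidney_with_gerotas_fascia",
    "bile_fluid",
)

#: Camera angles of the standardized acquisition protocol: perpendicular to
#: the tissue surface, and 25 degrees off from either side.
ANGLES: tuple[str, ...] = ("perpendicular", "side_a_25deg", "side_b_25deg")

REFERENCE_ORGAN = "stomach"
REFERENCE_ANGLE = "perpendicular"

#: Metadata columns of a spectra table, in canonical order.
META_COLUMNS = (
    "pig_id",
    "organ",
    "image_id",
    "position_id",
    "angle",
    "repetition",
    "n_pixels",
)


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform spectral sampling grid, in nanometres."""

    start_nm: float = 500.0
    stop_nm: float = 995.0
    step_nm: float = 5.0
    n_bands: int = 100

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        expected = (self.stop_nm - self.start_nm) / self.step_nm + 1
        if abs(expected - self.n_bands) > 1e-9:
            raise ValueError(
                f"inconsistent grid: (stop-start)/step+1 = {expected}, "
                f"n_bands = {self.n_bands}"
            )

    @property
    def values(self) -> np.ndarray:
        """Band-center wavelengths in nm, strictly increasing."""
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    @property
    def band_columns(self) -> list[str]:
        """Column names ``b500 ... b995`` used in CSV spectra tables."""
        return [f"b{int(round(v))}" for v in self.values]


def make_wavelength_grid() -> WavelengthGrid:
    """Return the camera grid: 100 bands, 500 to 995 nm in 5 nm steps."""
    return WavelengthGrid(500.0, 995.0, 5.0, 100)


@dataclass
class Datacube:
    """One HSI recording: reflectance ``[y, x, band]`` in arbitrary units.

    ``invalid_mask`` flags pixels excluded by QC (e.g. all-zero spectra);
    ``qc`` accumulates QC counters such as the number of flagged pixels.
    """

    reflectance: np.ndarray
    grid: WavelengthGrid
    image_id: str
    invalid_mask: np.ndarray | None = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = np.asarray(self.reflectance, dtype=float)
        if ref.ndim != 3:
            raise ValueError("reflectance must be a 3-D array [y, x, band]")
        if ref.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"band dimension {ref.shape[2]} != grid n_bands {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(ref)):
            raise ValueError("reflectance contains non-finite values")
        if np.any(ref < 0):
            raise ValueError("reflectance contains negative values")
        self.reflectance = ref
        if self.invalid_mask is not None:
            inv = np.asarray(self.invalid_mask, dtype=bool)
            if inv.shape != ref.shape[:2]:
                raise ValueError("invalid_mask shape mismatch")
            self.invalid_mask = inv

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (height, width)."""
        return self.reflectance.shape[:2]


@dataclass
class AnnotationRecord:
    """One expert-annotated organ region in one recording.

    ``image_id`` identifies the recorded scene (one organ position viewed
    from one angle); ``repetition`` indexes repeated recordings of that
    identical scene.  ``position_id`` is the organ position on its own.
    """

    pig_id: str
    organ: str
    image_id: str
    position_id: str
    angle: str
    repetition: int
    mask: np.ndarray
    organ_vocabulary: Sequence[str] = ORGAN_CLASSES

    def __post_init__(self) -> None:
        if self.organ not in self.organ_vocabulary:
            raise ValueError(
                f"unknown organ label {self.organ!r}; expected one of "
                f"{sorted(self.organ_vocabulary)}"
            )
        if self.angle not in ANGLES:
            raise ValueError(f"unknown angle {self.angle!r}; expected one of {ANGLES}")
        if not 1 <= int(self.repetition):
            raise ValueError("repetition must be a positive integer")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean raster")
        if not mask.any():
            raise ValueError("annotation mask is empty")
        self.mask = mask

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class MedianSpectrum:
    """Per-annotation band-wise median of l1-normalized pixel spectra.

    ``values`` is re-normalized to sum 1; ``pre_norm_sum`` records the band
    sum of the raw median before that re-normalization (always close to 1).
    """

    values: np.ndarray
    pig_id: str
    organ: str
    image_id: str
    position_id: str
    angle: str
    repetition: int
    n_pixels: int
    pre_norm_sum: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite and non-negative")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"spectrum must sum to 1, got {v.sum()}")
        self.values = v


class SpectraTable:
    """Table of per-annotation median spectra plus their metadata.

    Backed by a :class:`pandas.DataFrame` with the metadata columns
    ``pig_id, organ, image_id, position_id, angle, repetition, n_pixels``
    followed by one column per band (``b500 ... b995``).
    """

    def __init__(self, df: pd.DataFrame, grid: WavelengthGrid):
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        bands = grid.band_columns
        missing_b = [c for c in bands if c not in df.columns]
        if missing_b:
            raise ValueError(f"missing band columns (first few): {missing_b[:5]}")
        self.df = df.reset_index(drop=True)[list(META_COLUMNS) + bands]
        self.grid = grid

    def __len__(self) -> int:
        return len(self.df)

    @property
    def band_matrix(self) -> np.ndarray:
        """Spectra as an (n_rows, n_bands) float array."""
        return self.df[self.grid.band_columns].to_numpy(dtype=float)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    def subset(self, mask) -> "SpectraTable":
        return SpectraTable(self.df.loc[mask].reset_index(drop=True), self.grid)

    @classmethod
    def from_spectra(
        cls, spectra: Iterable[MedianSpectrum], grid: WavelengthGrid
    ) -> "SpectraTable":
        rows = []
        for s in spectra:
            row = {
                "pig_id": s.pig_id,
                "organ": s.organ,
                "image_id": s.image_id,
                "position_id": s.position_id,
                "angle": s.angle,
                "repetition": s.repetition,
                "n_pixels": s.n_pixels,
            }
            row.update(dict(zip(grid.band_columns, s.values)))
            rows.append(row)
        return cls(pd.DataFrame(rows), grid)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        bands = sorted(
            (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if len(bands) < 2:
            raise ValueError("no band columns (b<nm>) found")
        nm = np.array([int(c[1:]) for c in bands], dtype=float)
        step = nm[1] - nm[0]
        grid = WavelengthGrid(nm[0], nm[-1], step, len(nm))
        return cls(df, grid)

    def check_unique_keys(self) -> None:
        """Raise if any (pig, organ, position, angle, repetition) key repeats."""
        keys = self.df[["pig_id", "organ", "position_id", "angle", "repetition"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].to_dict()
            raise ValueError(f"duplicate annotation key: {dup}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def l1_normalize_pixels(cube: Datacube) -> Datacube:
    """l1-normalize every pixel spectrum (divide by its band sum).

    All-zero pixels cannot be normalized; they are flagged in the returned
    cube's ``invalid_mask`` and counted in ``qc["n_zero_pixels"]`` rather
    than silently divided.  Downstream median extraction excludes them.
    """
    ref = cube.reflectance
    sums = ref.sum(axis=2)
    zero = sums <= 0
    safe = np.where(zero, 1.0, sums)
    normalized = ref / safe[:, :, None]
    normalized[zero] = 0.0
    invalid = zero if cube.invalid_mask is None else (zero | cube.invalid_mask)
    qc = dict(cube.qc)
    qc["n_zero_pixels"] = int(zero.sum())
    return Datacube(normalized, cube.grid, cube.image_id, invalid_mask=invalid, qc=qc)


def extract_median_spectrum(cube: Datacube, ann: AnnotationRecord) -> MedianSpectrum:
    """Band-wise median over the annotation mask, re-normalized to sum 1.

    ``cube`` must already be pixel-level l1-normalized.  Pixels flagged in
    the cube's ``invalid_mask`` are excluded from the mask first.
    """
    if ann.mask.shape != cube.shape:
        raise ValueError(
            f"mask shape {ann.mask.shape} does not match cube shape {cube.shape}"
        )
    mask = ann.mask
    if cube.invalid_mask is not None:
        mask = mask & ~cube.invalid_mask
    if not mask.any():
        raise ValueError(
            f"annotation for {ann.organ!r} in image {ann.image_id!r} has no valid "
            "pixels after QC exclusion"
        )
    pixels = cube.reflectance[mask]  # (n_pixels, n_bands)
    med = np.median(pixels, axis=0)
    total = float(med.sum())
    if total <= 0:
        raise ValueError("median spectrum has non-positive mass")
    return MedianSpectrum(
        values=med / total,
        pig_id=ann.pig_id,
        organ=ann.organ,
        image_id=ann.image_id,
        position_id=ann.position_id,
        angle=ann.angle,
        repetition=int(ann.repetition),
        n_pixels=int(mask.sum()),
        pre_norm_sum=total,
    )


def build_spectra_table(
    cubes: Sequence[Datacube], annotations: Sequence[AnnotationRecord]
) -> SpectraTable:
    """Normalize cubes, extract one median spectrum per annotation."""
    if not cubes:
        raise ValueError("no cubes given")
    by_id = {}
    for cube in cubes:
        norm = l1_normalize_pixels(cube)
        by_id[cube.image_id] = norm
    spectra = []
    for ann in annotations:
        if ann.image_id not in by_id:
            raise ValueError(f"annotation references unknown image {ann.image_id!r}")
        spectra.append(extract_median_spectrum(by_id[ann.image_id], ann))
    return SpectraTable.from_spectra(spectra, cubes[0].grid)


# ---------------------------------------------------------------------------
# dataset container I/O
# ---------------------------------------------------------------------------
#
# Layout on disk:
#   <root>/cubes/<image_id>.h5   with datasets /reflectance, /wavelengths_nm
#   <root>/annotations.json      records with metadata + run-length masks
#
# Masks are run-length encoded over the C-order flattened raster as
# [start, length, start, length, ...].


def _encode_mask(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).ravel()
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, stops = edges[0::2], edges[1::2]
    rle = np.column_stack([starts, stops - starts]).ravel().tolist()
    return {"shape": list(mask.shape), "rle": rle}


def _decode_mask(blob: Mapping) -> np.ndarray:
    shape = tuple(blob["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    rle = blob["rle"]
    for start, length in zip(rle[0::2], rle[1::2]):
        flat[start : start + length] = True
    return flat.reshape(shape)


def write_dataset(
    path, cubes: Sequence[Datacube], annotations: Sequence[AnnotationRecord]
) -> None:
    """Write cubes (HDF5) and annotations (JSON sidecar) under ``path``."""
    root = Path(path)
    (root / "cubes").mkdir(parents=True, exist_ok=True)
    for cube in cubes:
        with h5py.File(root / "cubes" / f"{cube.image_id}.h5", "w") as f:
            f.create_dataset("reflectance", data=cube.reflectance)
            f.create_dataset("wavelengths_nm", data=cube.grid.values)
            f.attrs["image_id"] = cube.image_id
    records = []
    for ann in annotations:
        records.append(
            {
                "pig_id": ann.pig_id,
                "organ": ann.organ,
                "image_id": ann.image_id,
                "position_id": ann.position_id,
                "angle": ann.angle,
                "repetition": int(ann.repetition),
                "mask": _encode_mask(ann.mask),
            }
        )
    blob = {"organ_vocabulary": list(ORGAN_CLASSES), "records": records}
    (root / "annotations.json").write_text(json.dumps(blob))


_REQUIRED_FIELDS = ("pig_id", "organ", "image_id", "position_id", "angle", "repetition", "mask")


def read_dataset(
    path, layout_config: Mapping | None = None
) -> tuple[list[Datacube], list[AnnotationRecord]]:
    """Read a dataset directory written by :func:`write_dataset`.

    ``layout_config`` may override ``annotations_file`` (default
    ``annotations.json``) and ``organ_vocabulary``.  Output ordering is
    deterministic: cubes by image_id, annotations by (pig, image, organ).
    """
    root = Path(path)
    cfg = dict(layout_config or {})
    ann_file = root / cfg.get("annotations_file", "annotations.json")
    if not ann_file.exists():
        raise FileNotFoundError(f"annotation file not found: {ann_file}")
    blob = json.loads(ann_file.read_text())
    vocab = tuple(cfg.get("organ_vocabulary", blob.get("organ_vocabulary", ORGAN_CLASSES)))

    cubes = []
    for cube_path in sorted((root / "cubes").glob("*.h5")):
        with h5py.File(cube_path, "r") as f:
            ref = f["reflectance"][...]
            nm = f["wavelengths_nm"][...]
        step = float(nm[1] - nm[0])
        grid = WavelengthGrid(float(nm[0]), float(nm[-1]), step, len(nm))
        if ref.shape[2] != grid.n_bands:
            raise ValueError(f"band-count mismatch in {cube_path.name}")
        cubes.append(Datacube(ref, grid, cube_path.stem))
    cube_shapes = {c.image_id: c.shape for c in cubes}

    annotations = []
    for i, rec in enumerate(blob["records"]):
        missing = [f for f in _REQUIRED_FIELDS if f not in rec]
        if missing:
            raise ValueError(f"annotation record {i} is missing fields {missing}: {rec}")
        mask = _decode_mask(rec["mask"])
        image_id = rec["image_id"]
        if image_id in cube_shapes and mask.shape != cube_shapes[image_id]:
            raise ValueError(
                f"mask shape {mask.shape} does not match cube {image_id} "
                f"shape {cube_shapes[image_id]}"
            )
        annotations.append(
            AnnotationRecord(
                pig_id=rec["pig_id"],
                organ=rec["organ"],
                image_id=image_id,
                position_id=rec["position_id"],
                angle=rec["angle"],
                repetition=int(rec["repetition"]),
                mask=mask,
                organ_vocabulary=vocab,
            )
        )
    annotations.sort(key=lambda a: (a.pig_id, a.image_id, a.organ, a.repetition))
    return cubes, annotations
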