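"""CT windowing and nodule-centred patch extraction.

Raw CT slices carry Hounsfield-unit (HU) values.  The model consumes
windowed, nodule-centred, three-channel patches with pixel values in
[0, 1].  The standard lung window (level -600 HU, width 1500 HU) and the
mediastinal window (level 40 HU, width 300 HU) are provided as constants.

The three channels of a patch are, by default, three copies of the
lung-windowed image; a three-distinct-window variant can be requested by
passing a tuple of windows to :func:`make_patch`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import GeometryError, NumericError, ParameterError

__all__ = [
    "WindowSpec",
    "LUNG_WINDOW",
    "MEDIASTINAL_WINDOW",
    "CtPatch",
    "apply_window",
    "make_patch",
    "load_nifti_volume",
    "load_dicom_series",
    "load_png_patch",
]


@dataclass(frozen=True)
class WindowSpec:
    """A CT display window: ``level`` is the centre, ``width`` the span in HU."""

    level: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ParameterError(f"window width must be > 0, got {self.width}")

    @property
    def floor(self) -> float:
        return self.level - self.width / 2.0

    @property
    def ceil(self) -> float:
        return self.level + self.width / 2.0


LUNG_WINDOW = WindowSpec(level=-600.0, width=1500.0)
MEDIASTINAL_WINDOW = WindowSpec(level=40.0, width=300.0)


@dataclass
class CtPatch:
    """A windowed, nodule-centred patch.

    ``pixels`` is an ``(H, W, 3)`` float array in [0, 1]; ``label`` is 0 for
    granuloma (LGN), 1 for adenocarcinoma (LAC), or ``None`` when unknown.
    """

    pixels: np.ndarray
    label: int | None = None
    patient_id: str = ""
    cohort: str = ""
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ParameterError(f"patch must be (H, W, 3), got {p.shape}")
        if p.shape[0] != p.shape[1]:
            raise ParameterError(f"patch must be square, got {p.shape}")
        if not np.isfinite(p).all():
            raise NumericError("patch contains non-finite values")
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ParameterError("patch values must lie in [0, 1]")

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])


def apply_window(grid: np.ndarray, window: WindowSpec = LUNG_WINDOW) -> np.ndarray:
    """Map HU values linearly onto [0, 1], clamping outside the window.

    ``window.floor`` maps to 0, ``window.ceil`` to 1, the level to 0.5.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if not np.isfinite(grid).all():
        raise NumericError("HU grid contains non-finite values")
    out = (grid - window.floor) / window.width
    return np.clip(out, 0.0, 1.0)


def make_patch(
    grid: np.ndarray,
    center: tuple[float, float],
    crop_size: int,
    window: WindowSpec | tuple[WindowSpec, WindowSpec, WindowSpec] = LUNG_WINDOW,
    out_size: int = 224,
    **patch_kwargs,
) -> CtPatch:
    """Crop ``crop_size`` pixels around ``center`` (row, col), window and resize.

    The crop is the half-open square ``[r0, r0 + crop_size) x [c0, c0 + crop_size)``
    with ``r0 = round(center_row) - crop_size // 2``.  Pixels outside the image
    are padded with the window floor (they window to 0).  A single window
    replicates its channel three times; a 3-tuple of windows produces three
    distinct channels.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2:
        raise ParameterError(f"expected a 2-D HU grid, got shape {grid.shape}")
    if crop_size < 1:
        raise ParameterError("crop_size must be >= 1")
    windows = window if isinstance(window, tuple) else (window, window, window)
    if len(windows) != 3:
        raise ParameterError("window must be a WindowSpec or a 3-tuple of them")

    h, w = grid.shape
    r0 = int(round(center[0])) - crop_size // 2
    c0 = int(round(center[1])) - crop_size // 2
    r1, c1 = r0 + crop_size, c0 + crop_size
    if r1 <= 0 or c1 <= 0 or r0 >= h or c0 >= w:
        raise GeometryError(
            f"crop [{r0}:{r1}, {c0}:{c1}] does not intersect image of shape {grid.shape}"
        )

    pad_value = windows[0].floor
    crop = np.full((crop_size, crop_size), pad_value, dtype=np.float64)
    src_r0, src_c0 = max(r0, 0), max(c0, 0)
    src_r1, src_c1 = min(r1, h), min(c1, w)
    crop[src_r0 - r0 : src_r1 - r0, src_c0 - c0 : src_c1 - c0] = grid[
        src_r0:src_r1, src_c0:src_c1
    ]

    channels = []
    for win in windows:
        ch = apply_window(crop, win)
        if crop_size != out_size:
            ch = _sk_resize(
                ch, (out_size, out_size), order=1, mode="edge",
                anti_aliasing=crop_size > out_size, preserve_range=True,
            )
            ch = np.clip(ch, 0.0, 1.0)
        channels.append(ch)
    pixels = np.stack(channels, axis=-1)
    return CtPatch(pixels=pixels, **patch_kwargs)


# ---------------------------------------------------------------------------
# readers


def load_nifti_volume(path) -> np.ndarray:
    """Load a NIfTI volume as a float HU array (nibabel applies scl slope/inter)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64)


def load_dicom_series(paths) -> np.ndarray:
    """Load a DICOM series (list of file paths) into a (n_slices, H, W) HU volume.

    Slices are sorted by ImagePositionPatient z when present, else by
    InstanceNumber; RescaleSlope/Intercept are applied.
    """
    import pydicom

    datasets = [pydicom.dcmread(str(p)) for p in paths]

    def _key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_key)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    return np.stack(slices, axis=0)


def load_png_patch(path, **patch_kwargs) -> CtPatch:
    """Load an already-windowed 8-bit PNG patch into a CtPatch in [0, 1]."""
    from PIL import Image

    arr = np.asarray(Image.open(str(path)).convert("RGB"), dtype=np.float64) / 255.0
    return CtPatch(pixels=arr, **patch_kwargs)


def save_png_patch(patch: CtPatch, path) -> None:
    """Write a patch as an 8-bit RGB PNG."""
    from PIL import Image

    arr = np.clip(np.round(patch.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(str(path))
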