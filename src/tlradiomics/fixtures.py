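"""Synthetic cohorts and source domains.

The study population this generator emulates is solitary pulmonary solid
nodules (diameter <= 30 mm) resected with a pathological diagnosis of
either lung granulomatous nodule (LGN, label 0) or lung adenocarcinoma
(LAC, label 1).  Real cohorts of this kind are private, so every
downstream stage of the pipeline is exercised on synthetic data drawn
from this module:

* :func:`render_nodule` draws a single nodule on a pseudo-HU grid.
  Lobulation appears as low-frequency undulation of the boundary,
  spiculation as narrow radial spikes — the two dichotomised subjective
  CT findings.
* :func:`generate_target_cohort` samples a full cohort (images plus the
  clinical table: gender, age, nodule size, location, margin, lobulated
  shape, spiculated sign, label).  Default class-conditional parameters
  are the whole-validation summary statistics of the emulated study
  population (e.g. LGN age 53.42 +/- 11.99 y, LAC age 60.13 +/- 10.08 y),
  so synthetic cohorts are statistically comparable to it.
* :func:`generate_source_domain` builds labelled source-domain image sets
  (WSI-like, natural-image-like or CT-nodule-like) whose similarity to
  the target renderer family is controlled by ``target_overlap`` in
  [0, 1]: at 1 every source image comes from the same renderer family as
  the target patches, at 0 from a fully independent generator.

Everything is a pure function of its spec (seed included).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .preprocessing import LUNG_WINDOW, CtPatch, apply_window

__all__ = [
    "NoduleParams",
    "ClassMorphology",
    "SyntheticCohortSpec",
    "SourceDomainSpec",
    "SourceDomain",
    "render_nodule",
    "generate_target_cohort",
    "generate_source_domain",
    "cohort_checksum",
]

LOCATIONS = ("LUL", "LLL", "RUL", "RML", "RLL")

# Whole-validation class-conditional location frequencies (LUL..RLL).
_LOC_P_LGN = np.array([43, 22, 45, 16, 36], dtype=float) / 162.0
_LOC_P_LAC = np.array([103, 67, 133, 43, 65], dtype=float) / 411.0

_FOV_MM = 50.0  # field of view represented by a rendered grid


@dataclass(frozen=True)
class NoduleParams:
    """Morphological parameters of one rendered nodule."""

    diameter_mm: float
    lobulation_count: int = 0
    spicule_count: int = 0
    base_intensity: float = 20.0  # pseudo-HU of the nodule core
    margin_irregular: bool = False
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if not (2.0 < self.diameter_mm <= 30.0):
            raise ParameterError(
                f"diameter_mm must be in (2, 30], got {self.diameter_mm}"
            )
        if self.lobulation_count < 0 or self.spicule_count < 0:
            raise ParameterError("lobulation/spicule counts must be >= 0")


@dataclass(frozen=True)
class ClassMorphology:
    """Class-conditional distributions for the clinical table and renderer.

    ``diam_mean``/``diam_sd`` are in mm (log-normal via moment matching);
    presence probabilities are Bernoulli; given presence, counts are
    ``1 + Poisson(rate)``.
    """

    age_mean: float
    age_sd: float
    diam_mean: float
    diam_sd: float
    p_men: float
    p_lobulated: float
    p_spiculated: float
    p_irregular_margin: float
    lobulation_rate: float = 1.2
    spicule_rate: float = 1.5
    intensity_mean: float = 15.0
    intensity_sd: float = 12.0
    texture_sd: float = 40.0
    location_p: tuple = tuple(_LOC_P_LGN)


# Defaults: whole-validation column of the emulated study population.
LGN_DEFAULT = ClassMorphology(
    age_mean=53.42, age_sd=11.99,
    diam_mean=12.45, diam_sd=6.66,
    p_men=102 / 162, p_lobulated=63 / 162, p_spiculated=29 / 162,
    p_irregular_margin=93 / 162,
    lobulation_rate=0.6, spicule_rate=0.8,
    intensity_mean=5.0, intensity_sd=12.0, texture_sd=35.0,
    location_p=tuple(_LOC_P_LGN),
)
LAC_DEFAULT = ClassMorphology(
    age_mean=60.13, age_sd=10.08,
    diam_mean=18.91, diam_sd=7.65,
    p_men=201 / 411, p_lobulated=351 / 411, p_spiculated=212 / 411,
    p_irregular_margin=372 / 411,
    lobulation_rate=2.2, spicule_rate=2.2,
    intensity_mean=32.0, intensity_sd=12.0, texture_sd=60.0,
    location_p=tuple(_LOC_P_LAC),
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Specification of a synthetic target cohort.

    ``prevalence_lac`` is realised by exact-count allocation
    (``n_lac = round(n * prevalence_lac)``), not by Bernoulli draws.
    """

    n: int = 200
    prevalence_lac: float = 411 / 573
    morphology: dict = field(
        default_factory=lambda: {0: LGN_DEFAULT, 1: LAC_DEFAULT}
    )
    patch_size: int = 224
    cohort: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("n must be >= 2")
        if not (0.0 < self.prevalence_lac < 1.0):
            raise ParameterError("prevalence_lac must be in (0, 1)")
        for cls, m in self.morphology.items():
            if m.age_sd <= 0 or m.diam_sd <= 0:
                raise ParameterError(f"class {cls}: sd must be > 0")
        if self.patch_size < 32:
            raise ParameterError("patch_size must be >= 32")


@dataclass(frozen=True)
class SourceDomainSpec:
    """Specification of a synthetic source domain."""

    kind: str = "wsi_like"
    n_classes: int = 2
    n: int = 100
    target_overlap: float = 1.0
    image_size: int = 224
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("wsi_like", "natural_like", "ct_like"):
            raise ParameterError(f"unknown source-domain kind {self.kind!r}")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if self.n < self.n_classes:
            raise ParameterError("n must be >= n_classes")
        if not (0.0 <= self.target_overlap <= 1.0):
            raise ParameterError("target_overlap must be in [0, 1]")


@dataclass
class SourceDomain:
    """A labelled source-domain image set in [0, 1], shape (n, H, W, 3)."""

    images: np.ndarray
    labels: np.ndarray
    kind: str
    spec: SourceDomainSpec


# ---------------------------------------------------------------------------
# rendering


def render_nodule(params: NoduleParams, size: int = 224) -> np.ndarray:
    """Render a centred nodule on a ``size x size`` pseudo-HU grid.

    The grid spans a fixed 50 mm field of view, so nodule pixel area
    scales with ``diameter_mm ** 2`` independently of ``size``.  The lung
    background sits near -820 HU; the nodule core near
    ``params.base_intensity`` with seeded smoothed-noise texture.
    """
    if size < 32:
        raise ParameterError("size must be >= 32")
    rng = np.random.default_rng(params.texture_seed)

    px_per_mm = size / _FOV_MM
    radius_px = 0.5 * params.diameter_mm * px_per_mm

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # lobulation: low-frequency boundary undulation
    boundary = np.ones_like(theta)
    for _ in range(params.lobulation_count):
        freq = rng.integers(2, 5)
        phase = rng.uniform(0, 2 * np.pi)
        boundary += (0.13 / max(1.0, np.sqrt(params.lobulation_count))) * np.cos(
            freq * theta + phase
        )
    # spiculation: narrow radial spikes (~1 mm wide at the boundary)
    for _ in range(params.spicule_count):
        th0 = rng.uniform(-np.pi, np.pi)
        dth = np.angle(np.exp(1j * (theta - th0)))
        boundary += 0.6 * np.exp(-0.5 * (dth / 0.12) ** 2)
    # irregular margin: high-frequency, low-amplitude boundary roughness
    if params.margin_irregular:
        for freq in (8, 11, 14):
            boundary += 0.05 * np.cos(freq * theta + rng.uniform(0, 2 * np.pi))

    local_radius = radius_px * boundary
    edge_width = max(0.8, 0.08 * radius_px)
    membership = 1.0 / (1.0 + np.exp((r - local_radius) / edge_width))

    background = -820.0 + 40.0 * gaussian_filter(
        rng.standard_normal((size, size)), sigma=size / 32
    )
    texture = params.base_intensity + 3.0 * gaussian_filter(
        rng.standard_normal((size, size)), sigma=max(1.0, size / 112)
    ) * (1.0 + 0.02 * abs(params.base_intensity))
    return background * (1 - membership) + texture * membership


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and sd."""
    var = sd**2
    sigma2 = np.log(1 + var / mean**2)
    mu = np.log(mean) - sigma2 / 2
    return mu, np.sqrt(sigma2)


def _windowed_patch(hu: np.ndarray) -> np.ndarray:
    ch = apply_window(hu, LUNG_WINDOW)
    return np.stack([ch, ch, ch], axis=-1)


def generate_target_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[CtPatch], pd.DataFrame]:
    """Sample a synthetic cohort: nodule patches plus the clinical table.

    Returns windowed three-channel patches and a DataFrame with columns
    ``patient_id, cohort, gender, age, nodule_size, location, margin,
    lobulated, spiculated, label``.  Covariate-class associations follow
    the class-conditional distributions in ``spec.morphology`` (defaults:
    LAC older, larger, more often lobulated/spiculated, more often women).
    """
    rng = np.random.default_rng(spec.seed)
    n_lac = int(round(spec.n * spec.prevalence_lac))
    n_lac = min(max(n_lac, 1), spec.n - 1)
    labels = np.array([1] * n_lac + [0] * (spec.n - n_lac))
    labels = labels[rng.permutation(spec.n)]

    rows = []
    patches = []
    for i, label in enumerate(labels):
        m = spec.morphology[int(label)]
        age = float(np.clip(rng.normal(m.age_mean, m.age_sd), 16, 95))
        gender = "men" if rng.random() < m.p_men else "women"
        mu, sig = _lognormal_moments(m.diam_mean, m.diam_sd)
        diameter = float(np.clip(rng.lognormal(mu, sig), 2.5, 30.0))
        lobulated = rng.random() < m.p_lobulated
        spiculated = rng.random() < m.p_spiculated
        irregular = rng.random() < m.p_irregular_margin
        lob_count = int(1 + rng.poisson(m.lobulation_rate)) if lobulated else 0
        spic_count = int(1 + rng.poisson(m.spicule_rate)) if spiculated else 0
        location = LOCATIONS[rng.choice(len(LOCATIONS), p=np.asarray(m.location_p))]
        intensity = float(rng.normal(m.intensity_mean, m.intensity_sd))
        texture_seed = int(rng.integers(0, 2**31 - 1))

        params = NoduleParams(
            diameter_mm=diameter,
            lobulation_count=lob_count,
            spicule_count=spic_count,
            base_intensity=intensity,
            margin_irregular=irregular,
            texture_seed=texture_seed,
        )
        hu = render_nodule(params, size=spec.patch_size)
        pid = f"P{i:05d}"
        patches.append(
            CtPatch(
                pixels=_windowed_patch(hu),
                label=int(label),
                patient_id=pid,
                cohort=spec.cohort,
                provenance=f"synthetic seed={spec.seed}",
            )
        )
        rows.append(
            dict(
                patient_id=pid,
                cohort=spec.cohort,
                gender=gender,
                age=age,
                nodule_size=diameter,
                location=location,
                margin="irregular" if irregular else "regular",
                lobulated="presence" if lobulated else "absence",
                spiculated="presence" if spiculated else "absence",
                label=int(label),
            )
        )
    return patches, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# source domains


def _render_target_family(rng: np.random.Generator, cls: int, size: int) -> np.ndarray:
    """Class-structured images from the same renderer family as the target."""
    shapes = [
        dict(lobulation_count=0, spicule_count=0, intensity=0.0),
        dict(lobulation_count=3, spicule_count=0, intensity=25.0),
        dict(lobulation_count=0, spicule_count=6, intensity=40.0),
        dict(lobulation_count=3, spicule_count=6, intensity=55.0),
    ]
    s = shapes[cls % len(shapes)]
    params = NoduleParams(
        diameter_mm=float(rng.uniform(8, 26)),
        lobulation_count=s["lobulation_count"],
        spicule_count=s["spicule_count"],
        base_intensity=s["intensity"] + float(rng.normal(0, 8)),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )
    return _windowed_patch(render_nodule(params, size=size))


def _render_wsi_like(rng: np.random.Generator, cls: int, size: int) -> np.ndarray:
    """Cellular-texture tiles: many small bright blobs on a pale background."""
    n_blobs = 40 + 25 * cls
    img = np.full((size, size), 0.82)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, size, 2)
        rad = rng.uniform(size / 60, size / 25) * (1 + 0.3 * cls)
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * rad**2)))
        img -= 0.5 * blob
    img += 0.04 * rng.standard_normal((size, size))
    img = np.clip(img, 0, 1)
    return np.stack([img, img * 0.75, img * 0.9], axis=-1)


def _render_natural_like(rng: np.random.Generator, cls: int, size: int) -> np.ndarray:
    """Gradient-plus-geometry images reminiscent of natural photographs."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    angle = rng.uniform(0, np.pi)
    img = 0.5 + 0.4 * np.sin(
        2 * np.pi * (1 + cls) * (np.cos(angle) * xx + np.sin(angle) * yy)
        + rng.uniform(0, 2 * np.pi)
    )
    for _ in range(2 + cls):
        cy, cx = rng.uniform(0.2, 0.8, 2) * size
        h = rng.uniform(size / 10, size / 4)
        mask = (np.abs(np.mgrid[0:size, 0:size][0] - cy) < h) & (
            np.abs(np.mgrid[0:size, 0:size][1] - cx) < h
        )
        img = np.where(mask, rng.uniform(0, 1), img)
    img = np.clip(img + 0.05 * rng.standard_normal((size, size)), 0, 1)
    rgb = np.stack([img, np.roll(img, size // 8, 0), np.roll(img, size // 8, 1)], -1)
    return rgb


def _render_ct_like(rng: np.random.Generator, cls: int, size: int) -> np.ndarray:
    """Nodule-like blobs from an independent generator (different spectrum)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2
    r = np.hypot(yy - cy, xx - cx)
    rad = size * (0.12 + 0.07 * cls) * rng.uniform(0.8, 1.2)
    core = np.where(r < rad, 0.65, 0.12)  # hard-edged, unlike the target family
    stripes = 0.08 * np.sign(np.sin(2 * np.pi * yy / rng.uniform(6, 14)))
    img = np.clip(core + stripes + 0.05 * rng.standard_normal((size, size)), 0, 1)
    return np.stack([img, img, img], axis=-1)


_INDEPENDENT = {
    "wsi_like": _render_wsi_like,
    "natural_like": _render_natural_like,
    "ct_like": _render_ct_like,
}


def generate_source_domain(spec: SourceDomainSpec) -> SourceDomain:
    """Generate a class-balanced labelled source-domain image set.

    Each image is drawn from the target renderer family with probability
    ``target_overlap`` and from the kind-specific independent generator
    otherwise, so the distributional distance to a fixed target cohort
    decreases in ``target_overlap``.
    """
    rng = np.random.default_rng(spec.seed)
    per_class = spec.n // spec.n_classes
    counts = [per_class] * spec.n_classes
    for k in range(spec.n - per_class * spec.n_classes):
        counts[k] += 1

    images, labels = [], []
    for cls, cnt in enumerate(counts):
        for _ in range(cnt):
            shared = rng.random() < spec.target_overlap
            if shared:
                img = _render_target_family(rng, cls, spec.image_size)
            else:
                img = _INDEPENDENT[spec.kind](rng, cls, spec.image_size)
            images.append(img)
            labels.append(cls)
    return SourceDomain(
        images=np.stack(images, axis=0),
        labels=np.asarray(labels, dtype=np.int64),
        kind=spec.kind,
        spec=spec,
    )


def cohort_checksum(patches: list[CtPatch]) -> str:
    """SHA-256 over all patch pixel buffers, for reproducibility checks."""
    h = hashlib.sha256()
    for p in patches:
        h.update(np.ascontiguousarray(p.pixels).tobytes())
    return h.hexdigest()
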