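"""Field-image quantification: from a 3-channel z-stack to four measurements.

The processing chain for one field is

    max-project each channel -> align channels (mutual information)
    -> illumination-correct -> rescale to [0, 1]
    -> dendrite channel: tubeness enhancement + 3-class Otsu -> neurite mask
    -> presynaptic channel: speckle tophat + 2-class Otsu + de-clumping
       + equivalent-diameter gate -> puncta
    -> colocalize puncta with the neurite mask
    -> report (neurite area, on-neurite puncta count, nuclei count,
       total puncta area)

Alignment corrects translational misalignment between channels by maximizing
the mutual information of the nuclear and dendrite planes over integer shifts;
the same shift is applied to the presynaptic plane.  Illumination correction
divides by the plate-wide mean image smoothed with a large Gaussian filter.

Conventions: 0-based row-major (y, x) coordinates, areas in pixels,
equivalent diameter = 2*sqrt(area/pi).  All thresholds operate on 256-bin
histograms of the [0, 1] rescaled range for cross-platform determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import sato, threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, erosion, reconstruction, white_tophat
from skimage.segmentation import watershed

CHANNELS = ("nuclear", "dendrite", "presynaptic")


@dataclass
class FieldStack:
    """Raw input unit: one field's 3-channel z-stack.

    channels maps channel name -> float array (n_slices, height, width).
    """

    plate_id: str
    well: str
    field_index: int
    channels: dict[str, np.ndarray]
    pixel_size: float = 0.6  # micrometers per pixel

    def __post_init__(self) -> None:
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if set(self.channels) != set(CHANNELS):
            raise ValueError(f"need channels {CHANNELS}, got {tuple(self.channels)}")
        if len({s for s in shapes.values()}) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 3:
                raise ValueError(f"channel {name} must be (z, y, x), got {ch.shape}")


@dataclass
class ProjectedField:
    """Per-channel maximum projections, after channel alignment."""

    planes: dict[str, np.ndarray]
    alignment_offset: tuple[int, int] = (0, 0)
    alignment_degenerate: bool = False


@dataclass
class PipelineConfig:
    tubeness_sigma: float = 2.0
    illumination_filter_size: int = 100          # pixels, Gaussian kernel extent
    puncta_equivalent_diameter_range: tuple[float, float] = (1.0, 6.0)
    neurite_otsu_classes: int = 3
    puncta_otsu_classes: int = 2
    alignment_search_radius: int = 10
    alignment_smooth_sigma: float = 1.0      # pre-smoothing before MI quantization
    mi_histogram_bins: int = 64
    histogram_bins: int = 256                    # Otsu quantization
    neurite_foreground: str = "middle+upper"     # or "upper"
    speckle_radius: int = 4                      # tophat disk radius, px
    puncta_min_separation: int = 2               # de-clump seed separation, px
    puncta_noise_k: float = 6.0                  # noise floor: median + k*MAD
    nuclei_min_diameter_um: float = 6.0
    nuclei_smooth_sigma: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.puncta_equivalent_diameter_range
        if not (self.tubeness_sigma > 0 and lo <= hi):
            raise ValueError("sigma must be > 0 and diameter range ordered")
        if self.neurite_otsu_classes not in (2, 3) or self.puncta_otsu_classes != 2:
            raise ValueError("neurite Otsu uses 2 or 3 classes; puncta Otsu uses 2")
        if self.neurite_foreground not in ("middle+upper", "upper"):
            raise ValueError("neurite_foreground is 'middle+upper' or 'upper'")


@dataclass
class NeuriteMask:
    mask: np.ndarray  # bool
    thresholds: tuple[float, ...] = ()
    fallback_two_class: bool = False

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class Punctum:
    label: int
    area: int
    equivalent_diameter: float
    centroid: tuple[float, float]
    on_neurite: bool = False


@dataclass
class PunctaSet:
    labels: np.ndarray  # int label image, 0 = background
    puncta: list[Punctum] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.puncta)

    @property
    def total_area(self) -> int:
        return int(sum(p.area for p in self.puncta))

    @property
    def on_neurite_count(self) -> int:
        return int(sum(p.on_neurite for p in self.puncta))


@dataclass
class FieldMeasurement:
    """The four per-field outputs, one CSV row."""

    plate_id: str
    well: str
    field_index: int
    map2_area: int
    syn_on_map2_count: int
    nuclei_count: int
    syn_total_area: int
    qc_pass: bool = True


# ---------------------------------------------------------------------------
# projection and alignment


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over z of a (z, y, x) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected a non-empty (z, y, x) stack, got {stack.shape}")
    return stack.max(axis=0)


def translate(plane: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Integer translation with constant edge padding."""
    out = np.full_like(plane, fill)
    h, w = plane.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    yo = slice(max(-dy, 0), min(h - dy, h))
    xo = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = plane[yo, xo]
    return out


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Mutual information (nats) of the joint 2-D histogram of two planes."""
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def _quantize(plane: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(plane.min()), float(plane.max())
    if hi == lo:
        return np.zeros(plane.shape, dtype=np.int64)
    q = ((plane - lo) * (bins / (hi - lo))).astype(np.int64)
    return np.clip(q, 0, bins - 1)


def _mi_surface(ref: np.ndarray, mov: np.ndarray, radius: int, bins: int) -> np.ndarray:
    """MI of the central crop of ref vs mov translated by each (dy, dx) in the
    +/-radius window.  Using a fixed central reference crop keeps the sample
    size constant across shifts (MI on a shrinking overlap is biased upward at
    large shifts)."""
    rq = _quantize(ref, bins)
    mq = _quantize(mov, bins)
    h, w = ref.shape
    if min(h, w) <= 2 * radius:
        raise ValueError("search radius too large for the image")
    a = rq[radius : h - radius, radius : w - radius].ravel()
    size = 2 * radius + 1
    surface = np.full((size, size), -np.inf)
    for i, dy in enumerate(range(-radius, radius + 1)):
        for j, dx in enumerate(range(-radius, radius + 1)):
            b = mq[radius - dy : h - radius - dy, radius - dx : w - radius - dx].ravel()
            joint = np.bincount(a * bins + b, minlength=bins * bins).astype(float)
            joint /= joint.sum()
            pxy = joint.reshape(bins, bins)
            px = pxy.sum(axis=1, keepdims=True)
            py = pxy.sum(axis=0, keepdims=True)
            nz = pxy > 0
            surface[i, j] = np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz]))
    return surface


def align_channels(
    nuclear: np.ndarray,
    dendrite: np.ndarray,
    presynaptic: np.ndarray,
    config: PipelineConfig | None = None,
) -> ProjectedField:
    """Register the dendrite plane to the nuclear plane by exhaustive integer
    translation search maximizing mutual information; apply the same shift to
    the presynaptic plane.

    Ties on the MI surface break toward the smaller shift magnitude, then
    lexicographically on (dy, dx).  A constant (degenerate) plane yields
    offset (0, 0) with ``alignment_degenerate`` set.
    """
    config = config or PipelineConfig()
    if not (nuclear.shape == dendrite.shape == presynaptic.shape):
        raise ValueError("planes must share shape")
    if np.ptp(nuclear) == 0 or np.ptp(dendrite) == 0:
        warnings.warn("degenerate (constant) plane; skipping alignment")
        return ProjectedField(
            planes={"nuclear": nuclear, "dendrite": dendrite, "presynaptic": presynaptic},
            alignment_offset=(0, 0),
            alignment_degenerate=True,
        )
    r = config.alignment_search_radius
    ref, mov = nuclear, dendrite
    if config.alignment_smooth_sigma > 0:
        ref = ndimage.gaussian_filter(ref, config.alignment_smooth_sigma)
        mov = ndimage.gaussian_filter(mov, config.alignment_smooth_sigma)
    surface = _mi_surface(ref, mov, r, config.mi_histogram_bins)
    offsets = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]
    mi = surface.ravel()
    mags = np.array([dy * dy + dx * dx for dy, dx in offsets])
    dys = np.array([o[0] for o in offsets])
    dxs = np.array([o[1] for o in offsets])
    # sort: highest MI first, then smallest magnitude, then lexicographic
    best = np.lexsort((dxs, dys, mags, -mi))[0]
    dy, dx = offsets[best]
    fill_d = float(dendrite.min())
    fill_p = float(presynaptic.min())
    return ProjectedField(
        planes={
            "nuclear": nuclear,
            "dendrite": translate(dendrite, dy, dx, fill_d),
            "presynaptic": translate(presynaptic, dy, dx, fill_p),
        },
        alignment_offset=(dy, dx),
    )


# ---------------------------------------------------------------------------
# illumination and rescaling


def build_illumination_function(
    planes: list[np.ndarray] | np.ndarray,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Flat-field correction surface for one channel of one plate.

    Per-pixel mean over all the plate's projected planes, smoothed with a
    Gaussian filter of the configured (large) extent and normalized to mean 1.
    Correction is division by the surface.
    """
    config = config or PipelineConfig()
    planes = list(planes)
    if len(planes) == 0:
        raise ValueError("need at least one plane")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("all planes must share shape")
    mean = np.mean(np.stack(planes), axis=0)
    # "filter size" k is the kernel extent; sigma = k/4 puts +/-2 sigma inside it
    sigma = config.illumination_filter_size / 4.0
    smooth = ndimage.gaussian_filter(mean, sigma=sigma, mode="nearest")
    m = smooth.mean()
    if m <= 0:
        return np.ones(shape)
    return smooth / m


def correct_illumination(plane: np.ndarray, surface: np.ndarray) -> np.ndarray:
    return plane / np.maximum(surface, 1e-12)


def rescale_intensity(plane: np.ndarray) -> np.ndarray:
    """Stretch to [0, 1]: min -> 0, max -> 1; a constant plane maps to zeros."""
    plane = np.asarray(plane, dtype=float)
    lo, hi = float(plane.min()), float(plane.max())
    if hi == lo:
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# neurite segmentation


def enhance_neurites(plane: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Tubeness enhancement of curvilinear (ridge-like) structures.

    Hessian-based ridge measure (Sato tubeness) at the configured Gaussian
    scale, followed by a white tophat to suppress residual low-frequency
    background.  Output is non-negative.
    """
    config = config or PipelineConfig()
    s = config.tubeness_sigma
    ridge = sato(plane, sigmas=[s], black_ridges=False, mode="reflect")
    se = disk(max(int(round(4 * s)), 1))
    return white_tophat(np.clip(ridge, 0, None), footprint=se)


def _otsu_thresholds(plane: np.ndarray, classes: int, bins: int) -> tuple[float, ...]:
    vals = plane.ravel()
    if np.unique(vals).size < classes:
        raise ValueError("histogram has too few distinct values")
    if classes == 2:
        return (float(threshold_otsu(vals, nbins=bins)),)
    return tuple(float(t) for t in threshold_multiotsu(vals, classes=classes, nbins=bins))


def segment_neurites(
    enhanced: np.ndarray, config: PipelineConfig | None = None
) -> NeuriteMask:
    """Three-class Otsu on the enhanced plane; the foreground mask is the union
    of the middle and upper classes by default ('upper' keeps only the top
    class).  Falls back to two-class Otsu when fewer than 3 distinct intensity
    values exist."""
    config = config or PipelineConfig()
    fallback = False
    try:
        thr = _otsu_thresholds(enhanced, config.neurite_otsu_classes, config.histogram_bins)
    except ValueError:
        uniq = np.unique(enhanced)
        if uniq.size < 2:
            return NeuriteMask(mask=np.zeros(enhanced.shape, bool), fallback_two_class=True)
        warnings.warn("fewer than 3 distinct values; falling back to two-class Otsu")
        thr = (float(threshold_otsu(enhanced.ravel(), nbins=config.histogram_bins)),)
        fallback = True
    if len(thr) == 1 or config.neurite_foreground == "middle+upper":
        bound = thr[0]
    else:
        bound = thr[-1]
    return NeuriteMask(mask=enhanced >= bound, thresholds=thr, fallback_two_class=fallback)


# ---------------------------------------------------------------------------
# puncta detection


def _declump(binary: np.ndarray, intensity: np.ndarray, min_distance: int) -> np.ndarray:
    """Split touching puncta at intensity saddle points: watershed on the
    inverted intensity, seeded at local maxima separated by >= min_distance.
    peak_local_max breaks ties toward larger intensity then smaller (y, x)."""
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    peaks = peak_local_max(
        intensity, min_distance=min_distance, labels=binary, exclude_border=False
    )
    if len(peaks) == 0:
        return cc_label(binary, connectivity=1).astype(np.int32)
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-intensity, markers=markers, mask=binary).astype(np.int32)


def detect_puncta(plane: np.ndarray, config: PipelineConfig | None = None) -> PunctaSet:
    """Speckle-enhance, binarize, de-clump and size-gate presynaptic puncta.

    A white tophat by reconstruction with a disk just larger than the maximum
    valid punctum radius removes every structure that can contain the disk
    (extended objects leave no rim residue); two-class Otsu binarizes the enhanced
    image (subject to a robust noise floor of median + k*MAD, so a blank field
    yields no puncta); touching puncta are split by an intensity-guided
    watershed; objects outside the configured equivalent-diameter range are
    discarded.
    """
    config = config or PipelineConfig()
    # white tophat by reconstruction: structures that cannot contain the disk
    # are removed entirely, with no rim residues around larger objects
    seed_img = erosion(plane, footprint=disk(config.speckle_radius))
    enhanced = plane - reconstruction(seed_img, plane, method="dilation")
    flat = enhanced.ravel()
    med = float(np.median(flat))
    mad = float(np.median(np.abs(flat - med)))
    floor = med + config.puncta_noise_k * 1.4826 * mad
    if np.unique(flat).size < 2:
        return PunctaSet(labels=np.zeros(plane.shape, np.int32))
    thr = max(float(threshold_otsu(flat, nbins=config.histogram_bins)), floor)
    binary = enhanced > thr
    labels = _declump(binary, enhanced, config.puncta_min_separation)
    lo, hi = config.puncta_equivalent_diameter_range
    puncta: list[Punctum] = []
    keep = np.zeros(labels.shape, dtype=np.int32)
    new_label = 0
    for prop in regionprops(labels):
        eq_d = 2.0 * np.sqrt(prop.area / np.pi)
        if lo <= eq_d <= hi:
            new_label += 1
            keep[labels == prop.label] = new_label
            puncta.append(
                Punctum(
                    label=new_label,
                    area=int(prop.area),
                    equivalent_diameter=float(eq_d),
                    centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                )
            )
    return PunctaSet(labels=keep, puncta=puncta)


def colocalize(puncta: PunctaSet, mask: NeuriteMask) -> PunctaSet:
    """Flag each punctum on-neurite iff its pixel set overlaps the neurite mask
    in at least one pixel (contained or partly touching)."""
    if puncta.labels.shape != mask.mask.shape:
        raise ValueError("puncta and mask must share the image frame")
    if len(puncta) == 0:
        return puncta
    overlap_labels = np.unique(puncta.labels[(puncta.labels > 0) & mask.mask])
    on = set(int(v) for v in overlap_labels)
    flagged = [replace(p, on_neurite=(p.label in on)) for p in puncta.puncta]
    return PunctaSet(labels=puncta.labels, puncta=flagged)


def measure_field(
    mask: NeuriteMask,
    puncta: PunctaSet,
    nuclei_count: int,
    plate_id: str = "",
    well: str = "",
    field_index: int = 0,
) -> FieldMeasurement:
    """Assemble the four per-field quantities.  Total puncta area sums over
    ALL retained puncta (on- and off-neurite)."""
    return FieldMeasurement(
        plate_id=plate_id,
        well=well,
        field_index=field_index,
        map2_area=mask.area,
        syn_on_map2_count=puncta.on_neurite_count,
        nuclei_count=int(nuclei_count),
        syn_total_area=puncta.total_area,
    )


# ---------------------------------------------------------------------------
# whole-field / whole-plate drivers


def process_field(
    stack: FieldStack,
    config: PipelineConfig | None = None,
    illumination: dict[str, np.ndarray] | None = None,
) -> tuple[FieldMeasurement, ProjectedField, NeuriteMask, PunctaSet]:
    """Run the full chain on one field.  `illumination` maps channel name to a
    plate-level correction surface (optional)."""
    from .plating import detect_nuclei  # local import to avoid a cycle

    config = config or PipelineConfig()
    proj = {name: max_project(stack.channels[name]) for name in CHANNELS}
    aligned = align_channels(
        proj["nuclear"], proj["dendrite"], proj["presynaptic"], config
    )
    planes = dict(aligned.planes)
    if illumination:
        for name, surf in illumination.items():
            planes[name] = correct_illumination(planes[name], surf)
    planes = {name: rescale_intensity(p) for name, p in planes.items()}
    enhanced = enhance_neurites(planes["dendrite"], config)
    mask = segment_neurites(enhanced, config)
    puncta = colocalize(detect_puncta(planes["presynaptic"], config), mask)
    nuclei = detect_nuclei(
        planes["nuclear"],
        pixel_size=stack.pixel_size,
        min_diameter_um=config.nuclei_min_diameter_um,
        smooth_sigma=config.nuclei_smooth_sigma,
    )
    meas = measure_field(
        mask,
        puncta,
        nuclei_count=len(nuclei),
        plate_id=stack.plate_id,
        well=stack.well,
        field_index=stack.field_index,
    )
    return meas, aligned, mask, puncta


def build_plate_illumination(
    stacks: list[FieldStack], config: PipelineConfig | None = None
) -> dict[str, np.ndarray]:
    """Per-channel illumination surfaces from all fields of a plate."""
    config = config or PipelineConfig()
    return {
        name: build_illumination_function(
            [max_project(s.channels[name]) for s in stacks], config
        )
        for name in CHANNELS
    }


def process_plate(
    stacks: list[FieldStack],
    config: PipelineConfig | None = None,
    illumination_correct: bool = True,
):
    """Measure every field of a plate; returns a pandas DataFrame in the
    field-CSV schema."""
    import pandas as pd

    config = config or PipelineConfig()
    illum = build_plate_illumination(stacks, config) if illumination_correct else None
    rows = []
    for s in stacks:
        meas, *_ = process_field(s, config, illum)
        rows.append(measurement_row(meas))
    return pd.DataFrame(rows, columns=FIELD_CSV_COLUMNS)


FIELD_CSV_COLUMNS = [
    "plate_id",
    "well",
    "field",
    "AreaOccupied_MAP2PositiveNeurites",
    "Count_SYNAPSIN1PunctaOnMAP2PositiveNeurites",
    "Count_Nuclei",
    "AreaOccupied_SYNAPSIN1",
]


def measurement_row(m: FieldMeasurement) -> dict:
    return {
        "plate_id": m.plate_id,
        "well": m.well,
        "field": m.field_index,
        "AreaOccupied_MAP2PositiveNeurites": m.map2_area,
        "Count_SYNAPSIN1PunctaOnMAP2PositiveNeurites": m.syn_on_map2_count,
        "Count_Nuclei": m.nuclei_count,
        "AreaOccupied_SYNAPSIN1": m.syn_total_area,
    }
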