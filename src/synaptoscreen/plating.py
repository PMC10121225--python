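"""Plating-consistency quality control.

One day after automated seeding, a randomly chosen plate is imaged to check
that neurons were dispensed uniformly.  Nuclei are detected on the nuclear
(DAPI) projection, neuronal nuclei are discriminated from astrocytic nuclei by
rule-based gates (intensity, contrast, area, roundness, and a dendrite-marker
positive perinuclear soma), and the plate passes when every well's neuronal
count sits inside an acceptance band and the across-plate coefficient of
variation is low.

Default acceptance band: 4,000-12,000 neuronal nuclei per well; maximum
covariance (100 * SD / mean): 8%.  Nucleus detection discards objects with
equivalent diameter below 20 um, emulating a diameter-gated detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed


@dataclass
class NucleusObject:
    centroid: tuple[float, float]
    area: int
    diameter: float                  # equivalent diameter, pixels
    mean_intensity: float
    contrast: float
    roundness: float                 # 4*pi*area / perimeter^2, clipped to 1
    has_dendrite_soma: bool = False
    nucleus_class: str = "unclassified"   # neuronal | astrocytic | unclassified


@dataclass
class QCThresholds:
    min_nuclei_per_well: int = 4000
    max_nuclei_per_well: int = 12000
    max_covariance_pct: float = 8.0
    min_nucleus_diameter_um: float = 20.0
    band_fraction: float = 1.0       # fraction of wells required inside the band
                                     # (1.0 = every well; relax to e.g. 0.95 to
                                     # tolerate isolated outlier wells)

    def __post_init__(self) -> None:
        if not 0 < self.min_nuclei_per_well < self.max_nuclei_per_well:
            raise ValueError("count band must satisfy 0 < min < max")
        if self.max_covariance_pct <= 0 or self.min_nucleus_diameter_um <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ClassifierGates:
    """Rule gates for neuronal-nucleus classification, applied on planes
    rescaled to [0, 1].  A nucleus is neuronal iff ALL gates pass."""

    min_intensity: float = 0.33
    min_contrast: float = 0.85
    area_band: tuple[float, float] = (100.0, 900.0)   # pixels
    min_roundness: float = 0.70
    soma_ring_width: int = 3                          # px annulus on dendrite plane
    min_soma_intensity: float = 0.16


@dataclass
class PlateConsistencyReport:
    well_counts: dict[str, int]
    mean: float
    sd: float
    covariance_pct: float
    count_rule_pass: bool
    covariance_rule_pass: bool
    passed: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "covariance_pct": self.covariance_pct,
            "pass": self.passed,
        }


def detect_nuclei(
    plane: np.ndarray,
    pixel_size: float,
    min_diameter_um: float = 20.0,
    smooth_sigma: float = 2.0,
) -> list[NucleusObject]:
    """Detect nuclei on a 2-D nuclear-stain projection.

    Gaussian smoothing, two-class Otsu thresholding, then a seeded watershed on
    the distance transform to split touching nuclei; objects whose equivalent
    diameter falls below `min_diameter_um` are discarded.  Contrast is the
    relative excess of a nucleus's mean intensity over the image background
    (the median of sub-threshold pixels).
    """
    if plane.ndim != 2:
        raise ValueError("expected a 2-D plane")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    smooth = ndimage.gaussian_filter(np.asarray(plane, float), smooth_sigma)
    if np.unique(smooth).size < 2:
        return []
    thr = threshold_otsu(smooth.ravel(), nbins=256)
    binary = smooth > thr
    if not binary.any():
        return []
    min_diam_px = min_diameter_um / pixel_size
    dist = ndimage.distance_transform_edt(binary)
    min_sep = max(int(min_diam_px / 2), 1)
    peaks = peak_local_max(dist, min_distance=min_sep, labels=binary, exclude_border=False)
    if len(peaks) == 0:
        labels, _ = ndimage.label(binary)
    else:
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers=markers, mask=binary)
    background = smooth[~binary]
    bg = float(np.median(background)) if background.size else 0.0
    out: list[NucleusObject] = []
    for prop in regionprops(labels, intensity_image=smooth):
        eq_d = 2.0 * np.sqrt(prop.area / np.pi)
        if eq_d < min_diam_px:
            continue
        perim = max(prop.perimeter, 1e-9)
        roundness = min(4.0 * np.pi * prop.area / perim**2, 1.0)
        mean_i = float(prop.intensity_mean)
        contrast = (mean_i - bg) / (mean_i + bg) if (mean_i + bg) > 0 else 0.0
        out.append(
            NucleusObject(
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area=int(prop.area),
                diameter=float(eq_d),
                mean_intensity=mean_i,
                contrast=float(contrast),
                roundness=float(roundness),
            )
        )
    return out


def classify_neuronal(
    nuclei: list[NucleusObject],
    dendrite_plane: np.ndarray | None,
    gates: ClassifierGates | None = None,
) -> list[NucleusObject]:
    """Set each nucleus's class by the rule gates.

    neuronal iff intensity, contrast, area-band and roundness gates all pass
    AND the mean dendrite-channel intensity in a perinuclear annulus clears the
    soma gate; otherwise astrocytic.  Without a dendrite plane all nuclei stay
    unclassified (with a warning).
    """
    gates = gates or ClassifierGates()
    if dendrite_plane is None:
        warnings.warn("no dendrite plane; nuclei left unclassified")
        return [replace(n, nucleus_class="unclassified") for n in nuclei]
    out = []
    for n in nuclei:
        soma = _soma_ring_mean(n, dendrite_plane, gates.soma_ring_width)
        has_soma = soma >= gates.min_soma_intensity
        lo_a, hi_a = gates.area_band
        neuronal = (
            n.mean_intensity >= gates.min_intensity
            and n.contrast >= gates.min_contrast
            and lo_a <= n.area <= hi_a
            and n.roundness >= gates.min_roundness
            and has_soma
        )
        out.append(
            replace(
                n,
                has_dendrite_soma=bool(has_soma),
                nucleus_class="neuronal" if neuronal else "astrocytic",
            )
        )
    return out


def _soma_ring_mean(n: NucleusObject, dendrite: np.ndarray, width: int) -> float:
    """Mean dendrite intensity in an annulus of `width` px just outside the
    nucleus's equivalent circle."""
    h, w = dendrite.shape
    cy, cx = n.centroid
    r_in = n.diameter / 2.0
    r_out = r_in + width
    y0, y1 = max(int(cy - r_out) - 1, 0), min(int(cy + r_out) + 2, h)
    x0, x1 = max(int(cx - r_out) - 1, 0), min(int(cx + r_out) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return 0.0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rr = np.hypot(yy - cy, xx - cx)
    ring = (rr >= r_in) & (rr < r_out)
    if not ring.any():
        return 0.0
    return float(dendrite[y0:y1, x0:x1][ring].mean())


def plate_consistency(
    per_well_counts: dict[str, int],
    thresholds: QCThresholds | None = None,
) -> PlateConsistencyReport:
    """Plate-level verdict from per-well neuronal nuclei counts.

    covariance_pct = 100 * SD / mean (sample SD, n-1).  The plate passes iff
    at least `band_fraction` of wells fall inside [min, max] AND the
    covariance is below the threshold.  A zero mean is a degenerate failure.
    """
    thresholds = thresholds or QCThresholds()
    if len(per_well_counts) < 2:
        raise ValueError("plate consistency needs at least 2 wells")
    counts = np.array(list(per_well_counts.values()), dtype=float)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    if mean == 0:
        return PlateConsistencyReport(
            well_counts=dict(per_well_counts),
            mean=0.0,
            sd=sd,
            covariance_pct=float("nan"),
            count_rule_pass=False,
            covariance_rule_pass=False,
            passed=False,
            degenerate=True,
        )
    cov = 100.0 * sd / mean
    inside = np.mean(
        (counts >= thresholds.min_nuclei_per_well)
        & (counts <= thresholds.max_nuclei_per_well)
    )
    count_ok = bool(inside >= thresholds.band_fraction)
    cov_ok = bool(cov < thresholds.max_covariance_pct)
    return PlateConsistencyReport(
        well_counts=dict(per_well_counts),
        mean=mean,
        sd=sd,
        covariance_pct=cov,
        count_rule_pass=count_ok,
        covariance_rule_pass=cov_ok,
        passed=count_ok and cov_ok,
    )
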