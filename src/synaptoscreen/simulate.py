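"""Synthetic fluorescence fields and plates with planted ground truth.

Emulates the structure of a high-content synaptic assay field: a curvilinear
neurite network (dendrite channel), small bright presynaptic puncta planted on
and off the neurites (presynaptic channel), and elliptical nuclei of two
classes — bright round neuronal nuclei with a dendrite-positive soma, and
dimmer elongated astrocytic nuclei (nuclear channel).  Objects live on one of
``n_slices`` focal planes with defocus blur on the others, so maximum
projection is meaningful.  Optional artifacts stress the correction stages:
integer channel shifts, a multiplicative illumination gradient, and a
vignette.  Noise is Poisson shot noise on the signal plus additive Gaussian
read noise.

Every planted object is recorded in a :class:`GroundTruth` inventory, the
oracle for recovery tests.  Identical (spec, artifacts) inputs produce
bit-identical images and truth tables.

Whole plates are generated lazily (one field at a time) to keep memory flat;
the per-field seed is derived from the top-level seed and the (well, field)
position, so any field can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .layout import PlateLayout
from .pipeline import CHANNELS, FieldStack

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma -> full width at half maximum


@dataclass
class FieldSpec:
    """Geometry and content of one synthetic field.

    Intensities are in arbitrary camera units; pixel_size in um/px.  The
    default pixel size (0.6 um/px) makes a 0.4-1.6 um^2 punctum footprint
    correspond to roughly 1-3 pixels, matching a x20 water objective.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_slices: int = 5
    pixel_size: float = 0.6
    n_neurite_segments: int = 6
    neurite_width: int = 4
    n_on_puncta: int = 60
    n_off_puncta: int = 15
    punctum_diameter_range: tuple[float, float] = (2.0, 4.0)
    n_neuronal_nuclei: int = 8
    n_astrocyte_nuclei: int = 12
    background_level: float = 100.0
    punctum_amplitude: float = 500.0
    noise_sd: float = 5.0
    seed: int = 0
    # secondary rendering knobs
    neurite_amplitude: float = 300.0
    neuronal_nucleus_diameter: float = 16.0      # px
    astrocyte_nucleus_diameter: float = 22.0     # px
    neuronal_nucleus_amplitude: float = 600.0
    astrocyte_nucleus_amplitude: float = 300.0
    soma_amplitude: float = 350.0
    nuclear_bleedthrough: float = 0.08           # fraction of nuclear signal in dendrite channel
    defocus_per_slice: float = 1.2               # blur sigma per slice of defocus

    def __post_init__(self) -> None:
        lo, hi = self.punctum_diameter_range
        counts = (
            self.n_neurite_segments,
            self.n_on_puncta,
            self.n_off_puncta,
            self.n_neuronal_nuclei,
            self.n_astrocyte_nuclei,
        )
        if any(c < 0 for c in counts):
            raise ValueError("object counts must be non-negative")
        if lo > hi or lo <= 0:
            raise ValueError("punctum diameter range must satisfy 0 < low <= high")
        if not (1 <= self.n_slices <= 8):
            raise ValueError("n_slices must be in [1, 8]")
        if min(self.image_shape) < 16:
            raise ValueError("image_shape too small")


@dataclass
class ArtifactSpec:
    """Acquisition artifacts applied to a clean field.

    channel_shift: integer (dy, dx) applied to both non-reference channels
    (the nuclear channel is the reference).  illumination_gradient (a, b, c)
    defines the multiplicative gain plane a + b*y + c*x; vignette_strength
    adds a radial falloff 1 - v*(r/r_max)^2.
    """

    channel_shift: tuple[int, int] = (0, 0)
    illumination_gradient: tuple[float, float, float] = (1.0, 0.0, 0.0)
    vignette_strength: float = 0.0
    max_shift: int = 10

    def __post_init__(self) -> None:
        dy, dx = self.channel_shift
        if abs(dy) > self.max_shift or abs(dx) > self.max_shift:
            raise ValueError(f"shift {self.channel_shift} exceeds max {self.max_shift}")
        if self.vignette_strength < 0 or self.vignette_strength >= 1:
            raise ValueError("vignette_strength must be in [0, 1)")

    def gain_plane(self, shape: tuple[int, int]) -> np.ndarray:
        a, b, c = self.illumination_gradient
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float32)
        gain = a + b * yy + c * xx
        if self.vignette_strength > 0:
            cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
            r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
            gain = gain * (1.0 - self.vignette_strength * r2)
        if gain.min() <= 0:
            raise ValueError("gain plane must be positive over the image domain")
        return gain


@dataclass
class PlantedPunctum:
    y: float
    x: float
    equivalent_diameter: float
    on_neurite: bool


@dataclass
class PlantedNucleus:
    y: float
    x: float
    diameter: float
    nucleus_class: str  # neuronal | astrocytic


@dataclass
class GroundTruth:
    """Planted-object inventory of one field."""

    neurite_mask_true: np.ndarray
    puncta: list[PlantedPunctum]
    nuclei: list[PlantedNucleus]
    applied_shift: tuple[int, int]
    planted_density: float  # on-neurite puncta per neurite-mask pixel

    @property
    def n_on_neurite(self) -> int:
        return sum(p.on_neurite for p in self.puncta)


@dataclass
class EffectMap:
    """Per-well treatment effects: multiplier on planted on-neurite puncta
    density (> 0) and viability multiplier on nuclei counts (in (0, 1])."""

    density_multipliers: dict[str, float] = dc_field(default_factory=dict)
    viability_multipliers: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for w, m in self.density_multipliers.items():
            if m <= 0:
                raise ValueError(f"density multiplier for {w} must be > 0")
        for w, v in self.viability_multipliers.items():
            if not 0 < v <= 1:
                raise ValueError(f"viability multiplier for {w} must be in (0, 1]")

    def density(self, well: str) -> float:
        return self.density_multipliers.get(well, 1.0)

    def viability(self, well: str) -> float:
        return self.viability_multipliers.get(well, 1.0)


# ---------------------------------------------------------------------------
# field generation


def _neurite_skeleton(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random-walk polylines rasterized into a skeleton image."""
    h, w = spec.image_shape
    skel = np.zeros((h, w), dtype=bool)
    step = 6.0
    n_steps = int(1.5 * max(h, w) / step)
    for _ in range(spec.n_neurite_segments):
        y = rng.uniform(0, h - 1)
        x = rng.uniform(0, w - 1)
        theta = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.35)
            y2 = float(np.clip(y + step * np.sin(theta), 0, h - 1))
            x2 = float(np.clip(x + step * np.cos(theta), 0, w - 1))
            rr, cc = draw_line(int(round(y)), int(round(x)), int(round(y2)), int(round(x2)))
            skel[rr, cc] = True
            y, x = y2, x2
    return skel


def _render_spot(canvas: np.ndarray, y: float, x: float, sigma: float, amp: float) -> None:
    """Add a 2-D Gaussian spot in place (local window, 4-sigma support)."""
    h, w = canvas.shape
    r = max(int(np.ceil(4 * sigma)), 2)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] += amp * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2)
    ).astype(np.float32)


def _sample_positions(
    mask: np.ndarray, n: int, rng: np.random.Generator, label: str
) -> np.ndarray:
    coords = np.argwhere(mask)
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    if len(coords) < n:
        raise ValueError(
            f"image too small: {n} {label} requested, {len(coords)} candidate pixels"
        )
    idx = rng.choice(len(coords), size=n, replace=False)
    return coords[idx]


def generate_field(
    spec: FieldSpec,
    artifacts: ArtifactSpec | None = None,
    plate_id: str = "SIM",
    well: str = "B02",
    field_index: int = 1,
    render: bool = True,
) -> tuple[FieldStack | None, GroundTruth]:
    """Generate one 3-channel field and its planted ground truth.

    With ``render=False`` only object placement is performed (identical truth,
    no pixel data) — used to build plate truth tables cheaply.
    """
    artifacts = artifacts or ArtifactSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape

    # --- placement (all randomness that defines the truth) -----------------
    skel = _neurite_skeleton(spec, rng)
    neurite_mask = dilation(skel, disk(max(spec.neurite_width // 2, 1)))
    if spec.n_on_puncta > 0 and not neurite_mask.any():
        raise ValueError("no neurite mask to place on-neurite puncta on")
    on_pos = _sample_positions(neurite_mask, spec.n_on_puncta, rng, "on-neurite puncta")
    off_pos = _sample_positions(~neurite_mask, spec.n_off_puncta, rng, "off-neurite puncta")
    lo_d, hi_d = spec.punctum_diameter_range
    diam_on = rng.uniform(lo_d, hi_d, size=spec.n_on_puncta)
    diam_off = rng.uniform(lo_d, hi_d, size=spec.n_off_puncta)
    puncta = [
        PlantedPunctum(float(p[0]), float(p[1]), float(d), True)
        for p, d in zip(on_pos, diam_on)
    ] + [
        PlantedPunctum(float(p[0]), float(p[1]), float(d), False)
        for p, d in zip(off_pos, diam_off)
    ]
    n_nuc = spec.n_neuronal_nuclei + spec.n_astrocyte_nuclei
    margin = int(spec.astrocyte_nucleus_diameter)
    interior = np.zeros((h, w), dtype=bool)
    if h > 2 * margin and w > 2 * margin:
        interior[margin:-margin, margin:-margin] = True
    else:
        interior[:] = True
    nuc_pos = _sample_positions(interior, n_nuc, rng, "nuclei") if n_nuc else np.empty((0, 2))
    nuclei = []
    for i, p in enumerate(nuc_pos):
        neuronal = i < spec.n_neuronal_nuclei
        d = spec.neuronal_nucleus_diameter if neuronal else spec.astrocyte_nucleus_diameter
        d *= rng.uniform(0.9, 1.1)
        nuclei.append(
            PlantedNucleus(
                float(p[0]), float(p[1]), float(d),
                "neuronal" if neuronal else "astrocytic",
            )
        )
    # focal-slice assignment for every object
    z_neurite = int(rng.integers(spec.n_slices))
    z_puncta = rng.integers(spec.n_slices, size=len(puncta))
    z_nuclei = rng.integers(spec.n_slices, size=len(nuclei))

    area = int(neurite_mask.sum())
    truth = GroundTruth(
        neurite_mask_true=neurite_mask,
        puncta=puncta,
        nuclei=nuclei,
        applied_shift=tuple(artifacts.channel_shift),
        planted_density=(spec.n_on_puncta / area) if area else 0.0,
    )
    if not render:
        return None, truth

    # --- rendering ----------------------------------------------------------
    focal: dict[str, dict[int, np.ndarray]] = {c: {} for c in CHANNELS}

    def layer(channel: str, z: int) -> np.ndarray:
        if z not in focal[channel]:
            focal[channel][z] = np.zeros((h, w), dtype=np.float32)
        return focal[channel][z]

    # neurites: dilated skeleton with a Gaussian cross-section profile
    profile = ndimage.gaussian_filter(
        neurite_mask.astype(np.float32), sigma=spec.neurite_width / 2.0
    )
    if profile.max() > 0:
        profile *= spec.neurite_amplitude / profile.max()
    layer("dendrite", z_neurite)[:] += profile

    for p, z in zip(puncta, z_puncta):
        _render_spot(
            layer("presynaptic", int(z)),
            p.y, p.x,
            sigma=p.equivalent_diameter / _FWHM,
            amp=spec.punctum_amplitude,
        )
    for nuc, z in zip(nuclei, z_nuclei):
        canvas = layer("nuclear", int(z))
        if nuc.nucleus_class == "neuronal":
            ry = rx = nuc.diameter / 2.0
            amp = spec.neuronal_nucleus_amplitude
        else:
            ry = nuc.diameter / 2.0 * 1.3
            rx = nuc.diameter / 2.0 * 0.7
            amp = spec.astrocyte_nucleus_amplitude
        rr, cc = draw_ellipse(nuc.y, nuc.x, ry, rx, shape=(h, w), rotation=rng.uniform(0, np.pi))
        stamp = np.zeros((h, w), dtype=np.float32)
        stamp[rr, cc] = amp
        canvas += ndimage.gaussian_filter(stamp, sigma=1.0)
        if nuc.nucleus_class == "neuronal":
            # dendrite-positive soma around the neuronal nucleus: Gaussian
            # radial profile, attenuated inside the nucleus itself (the
            # dendrite marker is cytoplasmic and excluded from the nucleus),
            # which gives the two channels a sharp common edge
            soma = np.zeros((h, w), dtype=np.float32)
            _render_spot(soma, nuc.y, nuc.x, sigma=nuc.diameter * 0.55,
                         amp=spec.soma_amplitude)
            srr, scc = draw_ellipse(nuc.y, nuc.x, ry, rx, shape=(h, w))
            soma[srr, scc] *= 0.25
            layer("dendrite", z_neurite)[:] += soma

    gain = artifacts.gain_plane((h, w))
    signal: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        stack = np.empty((spec.n_slices, h, w), dtype=np.float32)
        for z in range(spec.n_slices):
            plane = np.zeros((h, w), dtype=np.float32)
            for z0, lay in focal[name].items():
                dz = abs(z - z0)
                plane += lay if dz == 0 else ndimage.gaussian_filter(
                    lay, sigma=spec.defocus_per_slice * dz
                )
            stack[z] = plane
        signal[name] = stack
    # spectral bleed-through of the nuclear dye into the dendrite channel
    # (it is emitted by the sample, so it travels with the dendrite
    # acquisition and is subject to the same channel shift)
    if spec.nuclear_bleedthrough > 0:
        signal["dendrite"] = (
            signal["dendrite"] + spec.nuclear_bleedthrough * signal["nuclear"]
        )
    channels: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        stack = signal[name]
        if name != "nuclear":
            dy, dx = artifacts.channel_shift
            if (dy, dx) != (0, 0):
                for z in range(spec.n_slices):
                    stack[z] = _translate_fill(stack[z], dy, dx, 0.0)
        stack += spec.background_level
        stack *= gain[None, :, :]
        # Poisson shot noise on the (non-negative) signal + Gaussian read noise
        noisy = rng.poisson(np.clip(stack, 0, None)).astype(np.float32)
        noisy += rng.normal(0.0, spec.noise_sd, size=stack.shape).astype(np.float32)
        channels[name] = np.clip(noisy, 0, None)

    stack_obj = FieldStack(
        plate_id=plate_id,
        well=well,
        field_index=field_index,
        channels=channels,
        pixel_size=spec.pixel_size,
    )
    return stack_obj, truth


def _translate_fill(plane: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(plane, fill)
    h, w = plane.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    yo = slice(max(-dy, 0), min(h - dy, h))
    xo = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = plane[yo, xo]
    return out


def apply_artifacts(stack: FieldStack, artifacts: ArtifactSpec) -> FieldStack:
    """Shift the non-reference channels by the integer offset (edge padding at
    the channel's background level, taken as its minimum) and multiply every
    channel by the gain plane."""
    h, w = next(iter(stack.channels.values())).shape[1:]
    gain = artifacts.gain_plane((h, w))
    dy, dx = artifacts.channel_shift
    out = {}
    for name, ch in stack.channels.items():
        ch2 = ch.astype(np.float32, copy=True)
        if name != "nuclear" and (dy, dx) != (0, 0):
            fill = float(ch2.min())
            for z in range(ch2.shape[0]):
                ch2[z] = _translate_fill(ch2[z], dy, dx, fill)
        out[name] = ch2 * gain[None, :, :]
    return FieldStack(
        plate_id=stack.plate_id,
        well=stack.well,
        field_index=stack.field_index,
        channels=out,
        pixel_size=stack.pixel_size,
    )


# ---------------------------------------------------------------------------
# plate generation


def field_seed(base_seed: int, well: str, field_index: int) -> int:
    """Deterministic per-field seed below 2**31, derived from the top-level
    seed and the field's position."""
    ss = np.random.SeedSequence(
        [int(base_seed), sum(ord(c) * 131**i for i, c in enumerate(well)), field_index]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def generate_plate(
    layout: PlateLayout,
    base_spec: FieldSpec,
    effects: EffectMap | None = None,
    fields_per_well: int = 12,
    artifacts: ArtifactSpec | None = None,
    render: bool = True,
) -> Iterator[tuple[FieldStack | None, GroundTruth, str, int]]:
    """Lazily generate `fields_per_well` fields for each inner well of the
    plate, applying the effect map's per-well multipliers to planted content.

    Yields (stack, truth, well, field_index).  Control wells must carry a
    multiplier of exactly 1 (vehicle); an effect on a well outside the layout
    is an error.
    """
    effects = effects or EffectMap()
    inner = set(layout.inner_wells())
    for well in (set(effects.density_multipliers) | set(effects.viability_multipliers)):
        if well not in inner:
            raise ValueError(f"effect map references well {well} outside the layout")
    for well in layout.control_wells():
        if effects.density(well) != 1.0 or effects.viability(well) != 1.0:
            raise ValueError(f"control well {well} must have multiplier exactly 1")
    for well in layout.inner_wells():
        m = effects.density(well)
        v = effects.viability(well)
        for fi in range(1, fields_per_well + 1):
            spec = replace(
                base_spec,
                n_on_puncta=int(round(base_spec.n_on_puncta * m)),
                n_neuronal_nuclei=int(round(base_spec.n_neuronal_nuclei * v)),
                n_astrocyte_nuclei=int(round(base_spec.n_astrocyte_nuclei * v)),
                seed=field_seed(base_spec.seed, well, fi),
            )
            stack, truth = generate_field(
                spec,
                artifacts,
                plate_id=layout.plate_id,
                well=well,
                field_index=fi,
                render=render,
            )
            yield stack, truth, well, fi


def plate_truth_table(
    layout: PlateLayout,
    base_spec: FieldSpec,
    effects: EffectMap | None = None,
    fields_per_well: int = 12,
    artifacts: ArtifactSpec | None = None,
) -> pd.DataFrame:
    """Per-field planted-truth table for a plate (no rendering)."""
    effects = effects or EffectMap()
    rows = []
    for _stack, truth, well, fi in generate_plate(
        layout, base_spec, effects, fields_per_well, artifacts, render=False
    ):
        area = int(truth.neurite_mask_true.sum())
        rows.append(
            {
                "plate_id": layout.plate_id,
                "well": well,
                "field": fi,
                "role": layout.role(well),
                "condition": layout.condition_of(well),
                "density_multiplier": effects.density(well),
                "n_on_neurite_true": truth.n_on_neurite,
                "neurite_area_true": area,
                "planted_density": truth.planted_density,
                "n_nuclei_true": len(truth.nuclei),
            }
        )
    return pd.DataFrame(rows)


def wellwise_planted_density(truth_table: pd.DataFrame) -> pd.DataFrame:
    """Per-well planted density: total on-neurite puncta / total neurite area."""
    g = truth_table.groupby("well", sort=True)
    out = g.agg(
        n_on=("n_on_neurite_true", "sum"),
        area=("neurite_area_true", "sum"),
        role=("role", "first"),
        condition=("condition", "first"),
        density_multiplier=("density_multiplier", "first"),
    )
    out["planted_density"] = out["n_on"] / out["area"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# table-level screen simulator (no images)


def simulate_field_records(
    layouts: list[PlateLayout],
    effects_by_plate: dict[str, EffectMap] | None = None,
    fields_per_well: int = 12,
    seed: int = 0,
    base_map2_area: float = 30_000.0,
    map2_area_cv: float = 0.05,
    base_density: float = 0.004,          # on-neurite puncta per neurite pixel
    base_nuclei: float = 600.0,
    mean_punctum_area: float = 4.0,
    outlier_field_rate: float = 0.04,
) -> pd.DataFrame:
    """Simulate the field-level measurement table directly, without rendering
    images — for exercising the screen-analytics layer at batch scale.

    Per field: neurite area ~ Normal(mu, cv*mu), with a small fraction of
    gross-outlier fields (empty or debris-covered: area scaled by 0.2x or
    2.5x) emulating the heavy-tailed field-quality distribution that the
    mean +/- SD field filter exists to remove; on-neurite count ~
    Poisson(multiplier * base_density * area); nuclei ~ Poisson(viability *
    base_nuclei); total puncta area ~ count * mean punctum area.  Emulates
    sampling noise and per-well effects, not optics.
    """
    effects_by_plate = effects_by_plate or {}
    rng = np.random.default_rng(seed)
    rows = []
    for layout in layouts:
        eff = effects_by_plate.get(layout.plate_id, EffectMap())
        for well in layout.inner_wells():
            m, v = eff.density(well), eff.viability(well)
            for fi in range(1, fields_per_well + 1):
                area = max(rng.normal(base_map2_area, map2_area_cv * base_map2_area), 1.0)
                if rng.random() < outlier_field_rate:
                    area *= float(rng.choice([0.2, 2.5]))
                count = rng.poisson(m * base_density * area)
                nuclei = rng.poisson(v * base_nuclei)
                rows.append(
                    {
                        "plate_id": layout.plate_id,
                        "well": well,
                        "field": fi,
                        "AreaOccupied_MAP2PositiveNeurites": area,
                        "Count_SYNAPSIN1PunctaOnMAP2PositiveNeurites": int(count),
                        "Count_Nuclei": int(nuclei),
                        "AreaOccupied_SYNAPSIN1": float(count * mean_punctum_area),
                    }
                )
    return pd.DataFrame(rows)
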