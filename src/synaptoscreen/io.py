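"""File formats: per-field multi-page TIFF, truth/field CSVs, YAML configs.

A field is stored as one grayscale multi-page TIFF, one page per z-slice per
channel in channel-major order (nuclear, dendrite, presynaptic); acquisition
metadata travels in the TIFF description as JSON.  Measurement tables are
plain CSV in the documented schema.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .pipeline import CHANNELS, FIELD_CSV_COLUMNS, FieldStack
from .simulate import ArtifactSpec, EffectMap, FieldSpec, GroundTruth

TRUTH_CSV_COLUMNS = [
    "field_id",
    "well",
    "object_type",
    "y",
    "x",
    "equivalent_diameter",
    "on_neurite",
    "class",
]


def field_filename(stack: FieldStack) -> str:
    return f"{stack.plate_id}_{stack.well}_f{stack.field_index:02d}.tif"


def write_field_tiff(stack: FieldStack, path: str | Path) -> None:
    n_slices = next(iter(stack.channels.values())).shape[0]
    meta = {
        "plate_id": stack.plate_id,
        "well": stack.well,
        "field_index": stack.field_index,
        "pixel_size": stack.pixel_size,
        "n_slices": n_slices,
        "channel_order": list(CHANNELS),
    }
    pages = np.concatenate([stack.channels[c] for c in CHANNELS], axis=0)
    tifffile.imwrite(
        str(path), pages.astype(np.float32), description=json.dumps(meta), photometric="minisblack"
    )


def read_field_tiff(path: str | Path) -> FieldStack:
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    n = int(meta["n_slices"])
    channels = {
        name: pages[i * n : (i + 1) * n]
        for i, name in enumerate(meta["channel_order"])
    }
    return FieldStack(
        plate_id=meta["plate_id"],
        well=meta["well"],
        field_index=int(meta["field_index"]),
        channels=channels,
        pixel_size=float(meta["pixel_size"]),
    )


def truth_rows(truth: GroundTruth, field_id: str, well: str) -> list[dict]:
    rows = []
    for p in truth.puncta:
        rows.append(
            {
                "field_id": field_id,
                "well": well,
                "object_type": "punctum",
                "y": p.y,
                "x": p.x,
                "equivalent_diameter": p.equivalent_diameter,
                "on_neurite": p.on_neurite,
                "class": "",
            }
        )
    for nuc in truth.nuclei:
        rows.append(
            {
                "field_id": field_id,
                "well": well,
                "object_type": "nucleus",
                "y": nuc.y,
                "x": nuc.x,
                "equivalent_diameter": nuc.diameter,
                "on_neurite": False,
                "class": nuc.nucleus_class,
            }
        )
    return rows


def write_truth_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=TRUTH_CSV_COLUMNS).to_csv(path, index=False)


def write_fields_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=FIELD_CSV_COLUMNS)


def read_fields_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FIELD_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"field CSV missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# simulation config


def load_simulation_config(path: str | Path) -> dict:
    """YAML mirroring FieldSpec/ArtifactSpec/EffectMap with a top-level seed.

    Keys: seed, fields_per_well, field (FieldSpec fields), artifacts
    (ArtifactSpec fields), effects {density: {well: m}, viability: {well: v}}.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    seed = int(cfg.get("seed", 0))
    field_kwargs = dict(cfg.get("field", {}))
    for key in ("image_shape", "punctum_diameter_range"):
        if key in field_kwargs:
            field_kwargs[key] = tuple(field_kwargs[key])
    field_kwargs.setdefault("seed", seed)
    art_kwargs = dict(cfg.get("artifacts", {}))
    for key in ("channel_shift", "illumination_gradient"):
        if key in art_kwargs:
            art_kwargs[key] = tuple(art_kwargs[key])
    eff = cfg.get("effects", {})
    return {
        "seed": seed,
        "fields_per_well": int(cfg.get("fields_per_well", 12)),
        "field_spec": FieldSpec(**field_kwargs),
        "artifacts": ArtifactSpec(**art_kwargs),
        "effects": EffectMap(
            density_multipliers={str(k): float(v) for k, v in eff.get("density", {}).items()},
            viability_multipliers={str(k): float(v) for k, v in eff.get("viability", {}).items()},
        ),
    }


def config_hash(obj) -> str:
    """Stable short hash of a config object for run manifests."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, **entries) -> None:
    from . import __version__

    manifest = {"tool": "synaptoscreen", "version": __version__, **entries}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
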