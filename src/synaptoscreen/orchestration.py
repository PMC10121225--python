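"""End-to-end runs: simulate a plate to disk, process a plate directory to a
field CSV, analyze a screen.  All randomness flows from a single top-level
seed via the documented per-field derivation; every output directory carries
a manifest (tool version, config hash, seed)."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as sio
from .analytics import analyze_screen, library_fractions
from .layout import PlateLayout, ScreenLayout
from .pipeline import (
    FIELD_CSV_COLUMNS,
    PipelineConfig,
    build_illumination_function,
    max_project,
    measurement_row,
    process_field,
)
from .simulate import ArtifactSpec, EffectMap, FieldSpec, generate_plate

log = logging.getLogger("synaptoscreen")


def simulate_plate_to_dir(
    layout: PlateLayout,
    spec: FieldSpec,
    effects: EffectMap,
    out_dir: str | Path,
    fields_per_well: int = 12,
    artifacts: ArtifactSpec | None = None,
) -> int:
    """Write one simulated plate (TIFFs + truth CSV + layout + manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_rows: list[dict] = []
    n = 0
    for stack, truth, well, fi in generate_plate(
        layout, spec, effects, fields_per_well, artifacts
    ):
        assert stack is not None
        sio.write_field_tiff(stack, out / sio.field_filename(stack))
        truth_rows.extend(
            sio.truth_rows(truth, f"{layout.plate_id}_{well}_f{fi:02d}", well)
        )
        n += 1
    sio.write_truth_csv(truth_rows, out / "truth.csv")
    ScreenLayout(plates={layout.plate_id: layout}).to_yaml(out / "layout.yaml")
    sio.write_manifest(
        out / "manifest.json",
        seed=spec.seed,
        config_hash=sio.config_hash(
            {"spec": str(spec), "artifacts": str(artifacts), "fields_per_well": fields_per_well}
        ),
        n_fields=n,
    )
    return n


def run_field_pipeline(
    in_dir: str | Path,
    out_csv: str | Path,
    config: PipelineConfig | None = None,
    illumination_correct: bool = True,
) -> pd.DataFrame:
    """Process every field TIFF in a directory into the field CSV.

    Two passes: the first accumulates per-plate, per-channel mean projections
    for the illumination surfaces; the second measures each field.  Unreadable
    files are skipped and logged; the manifest records the skip count.
    """
    config = config or PipelineConfig()
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("*.tif")) + sorted(in_dir.glob("*.tiff"))
    skipped: list[str] = []

    illum = None
    if illumination_correct:
        sums: dict[str, dict] = {}
        counts: dict[str, int] = {}
        for p in paths:
            try:
                stack = sio.read_field_tiff(p)
            except Exception as e:  # corrupted input: skip, log
                log.warning("skipping unreadable field %s: %s", p.name, e)
                continue
            acc = sums.setdefault(stack.plate_id, {})
            for name, ch in stack.channels.items():
                proj = max_project(ch)
                acc[name] = proj if name not in acc else acc[name] + proj
            counts[stack.plate_id] = counts.get(stack.plate_id, 0) + 1
        illum = {
            pid: {
                name: build_illumination_function([total / counts[pid]], config)
                for name, total in acc.items()
            }
            for pid, acc in sums.items()
        }

    rows = []
    for p in paths:
        try:
            stack = sio.read_field_tiff(p)
            meas, *_ = process_field(
                stack, config, illum.get(stack.plate_id) if illum else None
            )
        except Exception as e:
            skipped.append(p.name)
            log.warning("skipping field %s: %s", p.name, e)
            continue
        rows.append(measurement_row(meas))
    df = pd.DataFrame(rows, columns=FIELD_CSV_COLUMNS)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    sio.write_fields_csv(df, out_csv)
    sio.write_manifest(
        out_csv.with_suffix(".manifest.json"),
        config_hash=sio.config_hash(config),
        n_fields=len(df),
        n_skipped=len(skipped),
        skipped=skipped,
    )
    return df


def run_screen(
    fields_csv: str | Path,
    layout_yaml: str | Path,
    out_dir: str | Path,
    apply_pattern_correction: bool = False,
    library_size: int | None = None,
) -> dict:
    """Analyze a screen from a field CSV and a layout YAML; writes well,
    condition and rejection tables plus a JSON report."""
    records = sio.read_fields_csv(fields_csv)
    layout = ScreenLayout.from_yaml(layout_yaml)
    known = set(layout.plates)
    seen = set(records["plate_id"].astype(str))
    unknown = sorted(seen - known)
    if unknown:
        raise ValueError(f"field CSV references plates absent from layout: {unknown}")
    result = analyze_screen(
        records, layout, apply_pattern_correction=apply_pattern_correction
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["wells"].to_csv(out / "wells.csv", index=False)
    result["conditions"].to_csv(out / "conditions.csv", index=False)
    result["rejections"].to_csv(out / "rejections.csv", index=False)
    n_cond = len(result["conditions"])
    fractions = library_fractions(
        result["conditions"], library_size or max(n_cond, 1)
    )
    fractions.to_csv(out / "library_fractions.csv", index=False)
    ctrl = result["wells"][result["wells"]["role"].isin(["control", "sentinel"])]
    ctrl_z = (
        ctrl.groupby("plate_id")["z_density"].mean().to_dict() if len(ctrl) else {}
    )
    report = {
        "n_conditions": n_cond,
        "hit_counts": result["conditions"]["hit_class"].value_counts().to_dict()
        if n_cond
        else {},
        "control_z_mean_by_plate": ctrl_z,
    }
    sio.write_manifest(
        out / "manifest.json",
        config_hash=sio.config_hash(
            {"pattern_correction": apply_pattern_correction, "library_size": library_size}
        ),
        **report,
    )
    return report
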