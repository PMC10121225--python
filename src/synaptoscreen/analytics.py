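"""Screen-level analytics: QC filtering, aggregation, normalization, hits.

The field-level measurement table is condensed in three QC'd steps:

1. field filter — fields whose neurite (MAP2) area lies outside the
   mean +/- SD band of all fields in scope (batch by default) are removed;
2. well filter — wells with fewer than five surviving fields are excluded;
   surviving wells carry the mean of their fields' metrics, and presynaptic
   density = mean on-neurite count / mean neurite area;
3. condition filter — a condition (compound) needs at least two of its
   (nominally three) replicate wells to survive.

Normalization is intra-plate: percent-of-control against the mean of the
plate's vehicle (DMSO) control wells, and the Z-score
(X - control_mean) / control_sd with the sample SD (n-1) of the control
wells.  An optional pattern-correction step (two-way median polish of the
row/column pattern seen in vehicle-only sentinel plates and control wells)
can remove plate-geometric drift before Z-scoring; it is off by default and
is an approximation of proprietary screening software behaviour.

Hit calling at condition level: ``toxic`` when presynaptic density drops by
z <= -3 AND neurite area drops by z <= -2 (both conjuncts required);
``enhancer_candidate`` when density rises by z >= +2 without the neurite
loss; otherwise ``inactive``.  QC failures propagate as ``qc_fail``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import ROWS, INNER_COLS, INNER_ROWS, VEHICLE, ScreenLayout, parse_well

AREA_COL = "AreaOccupied_MAP2PositiveNeurites"
COUNT_COL = "Count_SYNAPSIN1PunctaOnMAP2PositiveNeurites"
NUCLEI_COL = "Count_Nuclei"
SYN_AREA_COL = "AreaOccupied_SYNAPSIN1"

METRICS = ("density", "map2_area", "nuclei")
HIT_CLASSES = ("enhancer_candidate", "toxic", "inactive", "qc_fail")


@dataclass
class HitRules:
    toxic_density_z: float = -3.0
    toxic_map2_z: float = -2.0
    enhancer_density_z: float = 2.0


def density(count: float, area: float) -> float:
    """Presynaptic density: on-neurite puncta count per neurite-mask pixel."""
    if area <= 0:
        raise ValueError("density undefined for non-positive neurite area")
    return count / area


# ---------------------------------------------------------------------------
# QC filters


def filter_fields(
    records: pd.DataFrame, scope: str = "batch"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop fields whose neurite area lies outside mean +/- SD of the scope.

    scope='batch' pools all fields (the default, matching screen practice);
    scope='plate' computes the band per plate.  Bounds are inclusive.  Returns
    (kept records, rejection log).
    """
    if scope not in ("batch", "plate"):
        raise ValueError("scope must be 'batch' or 'plate'")
    rejections = []

    def _band(group: pd.DataFrame) -> pd.Series:
        if len(group) == 1:
            warnings.warn("single field in QC scope; kept without banding")
            return pd.Series(True, index=group.index)
        mu = group[AREA_COL].mean()
        sd = group[AREA_COL].std(ddof=1)
        return (group[AREA_COL] >= mu - sd) & (group[AREA_COL] <= mu + sd)

    if scope == "batch":
        keep = _band(records)
    else:
        keep = records.groupby("plate_id", group_keys=False).apply(
            _band, include_groups=False
        )
        keep = keep.reindex(records.index)
    kept = records[keep].copy()
    rej = records[~keep]
    for _, r in rej.iterrows():
        rejections.append(
            {
                "plate_id": r["plate_id"],
                "well": r["well"],
                "field": r["field"],
                "reason": "map2_area_outside_band",
            }
        )
    return kept, pd.DataFrame(rejections, columns=["plate_id", "well", "field", "reason"])


def filter_wells_and_conditions(
    records: pd.DataFrame,
    layout: ScreenLayout,
    min_fields_per_well: int = 5,
    min_wells_per_condition: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Condense surviving fields to wells, then wells to conditions.

    Wells need >= `min_fields_per_well` surviving fields; their metrics are
    the arithmetic means of their fields, with density = mean count / mean
    area.  Treated conditions need >= `min_wells_per_condition` surviving
    wells; their metrics are means over wells.  Returns (well table,
    condition table, rejection log).
    """
    rejections = []
    rows = []
    for (pid, well), g in records.groupby(["plate_id", "well"], sort=True):
        plate = layout.plates[pid]
        n = len(g)
        if n < min_fields_per_well:
            rejections.append(
                {"plate_id": pid, "well": well, "field": None, "reason": "fewer_than_min_fields"}
            )
            continue
        mean_area = g[AREA_COL].mean()
        rows.append(
            {
                "plate_id": pid,
                "well": well,
                "batch_id": plate.batch_id,
                "role": plate.role(well),
                "condition": plate.condition_of(well),
                "n_fields": n,
                "map2_area": mean_area,
                "count": g[COUNT_COL].mean(),
                "nuclei": g[NUCLEI_COL].mean(),
                "syn_area": g[SYN_AREA_COL].mean(),
                "density": density(g[COUNT_COL].mean(), mean_area),
                "qc_fail": False,
            }
        )
    wells = pd.DataFrame(rows)
    conditions = condense_conditions(wells, layout, min_wells_per_condition, rejections)
    rej = pd.DataFrame(rejections, columns=["plate_id", "well", "field", "reason"])
    return wells, conditions, rej


def condense_conditions(
    wells: pd.DataFrame,
    layout: ScreenLayout,
    min_wells: int = 2,
    rejections: list | None = None,
) -> pd.DataFrame:
    """Aggregate treated wells to condition level (mean over surviving wells)."""
    rows = []
    value_cols = ["map2_area", "count", "nuclei", "syn_area", "density"]
    z_cols = [c for c in wells.columns if c.startswith("z_") or c.startswith("pct_")]
    treated = wells[wells["role"] == "assay"] if len(wells) else wells
    groups = (
        {c: g for c, g in treated.groupby("condition", sort=True)} if len(wells) else {}
    )
    for compound in sorted(layout.conditions()):
        g = groups.get(compound)
        ok = g[~g["qc_fail"]] if g is not None else None
        n_ok = 0 if ok is None else len(ok)
        qc_fail = n_ok < min_wells
        use = ok if not qc_fail else g
        row = {
            "condition": compound,
            "n_wells_used": int(n_ok),
            "qc_fail": bool(qc_fail),
        }
        for c in value_cols + z_cols:
            row[c] = float(use[c].mean()) if use is not None and len(use) else float("nan")
        rows.append(row)
        if qc_fail and rejections is not None:
            rejections.append(
                {
                    "plate_id": None,
                    "well": None,
                    "field": None,
                    "reason": f"condition_{compound}_fewer_than_{min_wells}_wells",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normalization


def percent_of_control(wells: pd.DataFrame, metrics=METRICS) -> pd.DataFrame:
    """Express each well metric as a percent of the plate's mean control-well
    value.  Plates without a surviving, non-degenerate control mean have all
    their wells flagged qc_fail."""
    wells = wells.copy()
    for m in metrics:
        wells[f"pct_{m}"] = np.nan
    for pid, g in wells.groupby("plate_id"):
        ctrl = g[(g["role"].isin(["control", "sentinel"])) & (~g["qc_fail"])]
        idx = g.index
        for m in metrics:
            cmean = ctrl[m].mean() if len(ctrl) else np.nan
            if not np.isfinite(cmean) or cmean == 0:
                wells.loc[idx, "qc_fail"] = True
            else:
                wells.loc[idx, f"pct_{m}"] = 100.0 * g[m] / cmean
    return wells


def zscore(wells: pd.DataFrame, metrics=METRICS) -> pd.DataFrame:
    """Intra-plate Z-scores: (X - control_mean) / control_sd per metric, with
    the sample SD (n-1) of the plate's surviving control wells.  Control wells
    are scored too.  A plate with < 2 control wells or zero control SD is a
    QC failure."""
    wells = wells.copy()
    short = {"density": "density", "map2_area": "map2", "nuclei": "nuclei"}
    for m in metrics:
        wells[f"z_{short.get(m, m)}"] = np.nan
    for pid, g in wells.groupby("plate_id"):
        ctrl = g[(g["role"].isin(["control", "sentinel"])) & (~g["qc_fail"])]
        idx = g.index
        if len(ctrl) < 2:
            wells.loc[idx, "qc_fail"] = True
            continue
        for m in metrics:
            cmean = ctrl[m].mean()
            csd = ctrl[m].std(ddof=1)
            if csd == 0 or not np.isfinite(csd):
                wells.loc[idx, "qc_fail"] = True
            else:
                wells.loc[idx, f"z_{short.get(m, m)}"] = (g[m] - cmean) / csd
    return wells


# ---------------------------------------------------------------------------
# pattern correction (approximate; off by default)


def _plate_matrix(wells: pd.DataFrame, pid: str, metric: str) -> np.ndarray:
    mat = np.full((len(INNER_ROWS), len(INNER_COLS)), np.nan)
    sub = wells[wells["plate_id"] == pid]
    for _, r in sub.iterrows():
        row, col = parse_well(r["well"])
        if row in INNER_ROWS and col in INNER_COLS:
            mat[INNER_ROWS.index(row), INNER_COLS.index(col)] = r[metric]
    return mat


def _median_polish(mat: np.ndarray, n_iter: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """NaN-tolerant two-way median polish; returns (row effects, col effects)
    as deviations around the overall median."""
    work = mat.copy()
    rows = np.zeros(mat.shape[0])
    cols = np.zeros(mat.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for _ in range(n_iter):
            rmed = np.nanmedian(work, axis=1)
            rmed = np.where(np.isfinite(rmed), rmed, 0.0)
            work -= rmed[:, None]
            rows += rmed
            cmed = np.nanmedian(work, axis=0)
            cmed = np.where(np.isfinite(cmed), cmed, 0.0)
            work -= cmed[None, :]
            cols += cmed
    rmid = np.nanmedian(rows)
    cmid = np.nanmedian(cols)
    rows = rows - (rmid if np.isfinite(rmid) else 0.0)
    cols = cols - (cmid if np.isfinite(cmid) else 0.0)
    return rows, cols


def pattern_correct(
    wells: pd.DataFrame,
    layout: ScreenLayout,
    metrics=METRICS,
) -> pd.DataFrame:
    """Subtract the plate-geometric (row + column) pattern estimated from
    vehicle-only wells: all wells of sentinel plates plus the control wells of
    assay plates.  The pattern is the additive row/column decomposition of
    the elementwise median vehicle matrix (two-way median polish).  Wells not
    explained by the vehicle pattern (true treatment effects) are untouched
    up to that additive term.  Pass-through with a warning when no vehicle
    data exist."""
    wells = wells.copy()
    vehicle_pids = set(layout.sentinel_plates())
    out = wells
    for metric in metrics:
        mats = []
        for pid in layout.plates:
            mat = _plate_matrix(wells, pid, metric)
            if pid in vehicle_pids:
                mats.append(mat)
            else:
                ctrl_cols = layout.plates[pid].control_columns
                keep = np.full(mat.shape, np.nan)
                for c in ctrl_cols:
                    keep[:, INNER_COLS.index(c)] = mat[:, INNER_COLS.index(c)]
                mats.append(keep)
        stack = np.stack(mats)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vehicle = np.nanmedian(stack, axis=0)
        if not np.isfinite(vehicle).any():
            warnings.warn("no vehicle data for pattern correction; pass-through")
            continue
        reff, ceff = _median_polish(vehicle)
        pattern = reff[:, None] + ceff[None, :]
        for i, r in out.iterrows():
            row, col = parse_well(r["well"])
            if row in INNER_ROWS and col in INNER_COLS:
                out.at[i, metric] = r[metric] - pattern[
                    INNER_ROWS.index(row), INNER_COLS.index(col)
                ]
    return out


# ---------------------------------------------------------------------------
# hit calling


def call_hits(conditions: pd.DataFrame, rules: HitRules | None = None) -> pd.DataFrame:
    """Classify each condition.  toxic requires BOTH a strong density drop
    (z <= -3) and a neurite-area drop (z <= -2); enhancer_candidate requires a
    density rise (z >= +2) without the neurite loss; otherwise inactive."""
    rules = rules or HitRules()
    conditions = conditions.copy()
    classes = []
    for _, r in conditions.iterrows():
        if r.get("qc_fail", False) or not np.isfinite(r.get("z_density", np.nan)):
            classes.append("qc_fail")
        elif r["z_density"] <= rules.toxic_density_z and r["z_map2"] <= rules.toxic_map2_z:
            classes.append("toxic")
        elif r["z_density"] >= rules.enhancer_density_z and r["z_map2"] > rules.toxic_map2_z:
            classes.append("enhancer_candidate")
        else:
            classes.append("inactive")
    conditions["hit_class"] = classes
    return conditions


def library_fractions(conditions: pd.DataFrame, library_size: int) -> pd.DataFrame:
    """Per-hit-class counts and library percentages (rounded to 2 decimals)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rows = []
    for cls in HIT_CLASSES:
        n = int((conditions["hit_class"] == cls).sum())
        rows.append(
            {"hit_class": cls, "count": n, "percent": round(100.0 * n / library_size, 2)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end driver


def analyze_screen(
    records: pd.DataFrame,
    layout: ScreenLayout,
    field_scope: str = "batch",
    apply_pattern_correction: bool = False,
    rules: HitRules | None = None,
    min_fields_per_well: int = 5,
    min_wells_per_condition: int = 2,
) -> dict[str, pd.DataFrame]:
    """Full screen analysis: field QC -> well/condition condensation ->
    (optional pattern correction) -> percent-of-control + Z-scores ->
    hit calls.  Returns {'wells', 'conditions', 'rejections'}."""
    kept, rej_fields = filter_fields(records, scope=field_scope)
    wells, _, rej_wells = filter_wells_and_conditions(
        kept, layout, min_fields_per_well, min_wells_per_condition
    )
    if apply_pattern_correction:
        wells = pattern_correct(wells, layout)
    wells = percent_of_control(wells)
    wells = zscore(wells)
    rejections = pd.concat([rej_fields, rej_wells], ignore_index=True)
    conditions = condense_conditions(
        wells, layout, min_wells_per_condition,
        rejections=None,
    )
    conditions = call_hits(conditions, rules)
    return {"wells": wells, "conditions": conditions, "rejections": rejections}
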