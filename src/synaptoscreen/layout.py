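"""96-well plate layouts for plate-based screening.

A 96-well plate is an 8 x 12 grid (rows A-H, columns 1-12).  Only the 60
inner wells (rows B-G, columns 2-11) carry cultures; the outer ring is
excluded to limit evaporation artifacts.  Two inner columns are vehicle
(0.1% DMSO) control wells, the rest are assay wells.  Sentinel plates carry
vehicle in every inner well and are used to estimate batch-level spatial
drift.  Treated conditions are run in triplicate wells within a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

ROWS = "ABCDEFGH"
N_COLS = 12
INNER_ROWS = "BCDEFG"
INNER_COLS = tuple(range(2, 12))
DEFAULT_CONTROL_COLUMNS = (2, 11)
VEHICLE = "DMSO"


def well_name(row: str, col: int) -> str:
    return f"{row}{col:02d}"


def parse_well(well: str) -> tuple[str, int]:
    row, col = well[0].upper(), int(well[1:])
    if row not in ROWS or not 1 <= col <= N_COLS:
        raise ValueError(f"not a 96-well position: {well!r}")
    return row, col


def inner_wells() -> list[str]:
    """The 60 inner assay-capable wells of a 96-well plate."""
    return [well_name(r, c) for r in INNER_ROWS for c in INNER_COLS]


@dataclass
class PlateLayout:
    """Well roles and treatment map of one 96-well plate.

    treatments maps well -> (compound_id, concentration, replicate_index);
    control wells implicitly carry the vehicle and must not appear in the
    treatment map.
    """

    plate_id: str
    batch_id: str = "batch1"
    control_columns: tuple[int, ...] = DEFAULT_CONTROL_COLUMNS
    sentinel: bool = False
    treatments: dict[str, tuple[str, float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        inner = set(inner_wells())
        for col in self.control_columns:
            if col not in INNER_COLS:
                raise ValueError(f"control column {col} is not an inner column")
        for well in self.treatments:
            parse_well(well)
            if well not in inner:
                raise ValueError(f"treated well {well} is not an inner well")
            if well in self.control_wells():
                raise ValueError(f"treated well {well} is a control well")
        if self.sentinel and self.treatments:
            raise ValueError("sentinel plates carry vehicle only")

    def inner_wells(self) -> list[str]:
        return inner_wells()

    def control_wells(self) -> list[str]:
        return [
            well_name(r, c) for r in INNER_ROWS for c in self.control_columns
        ]

    def assay_wells(self) -> list[str]:
        ctrl = set(self.control_wells())
        return [w for w in inner_wells() if w not in ctrl]

    def role(self, well: str) -> str:
        row, col = parse_well(well)
        if row not in INNER_ROWS or col not in INNER_COLS:
            return "excluded"
        if col in self.control_columns:
            return "control"
        return "sentinel" if self.sentinel else "assay"

    def condition_of(self, well: str) -> str:
        """Condition label of a well: compound id, or the vehicle name."""
        if self.role(well) in ("control", "sentinel"):
            return VEHICLE
        if well in self.treatments:
            return self.treatments[well][0]
        return VEHICLE


@dataclass
class ScreenLayout:
    """All plates of a screen, keyed by plate id."""

    plates: dict[str, PlateLayout]

    def __post_init__(self) -> None:
        for pid, plate in self.plates.items():
            if plate.plate_id != pid:
                raise ValueError(f"plate id mismatch: {pid} vs {plate.plate_id}")

    def sentinel_plates(self) -> list[str]:
        return [pid for pid, p in self.plates.items() if p.sentinel]

    def conditions(self) -> dict[str, list[tuple[str, str]]]:
        """compound_id -> list of (plate_id, well) carrying it."""
        out: dict[str, list[tuple[str, str]]] = {}
        for pid, plate in self.plates.items():
            for well, (compound, _conc, _rep) in plate.treatments.items():
                out.setdefault(compound, []).append((pid, well))
        return out

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "plates": {
                pid: {
                    "batch_id": p.batch_id,
                    "control_columns": list(p.control_columns),
                    "sentinel": p.sentinel,
                    "treatments": {
                        w: [c, conc, rep]
                        for w, (c, conc, rep) in sorted(p.treatments.items())
                    },
                }
                for pid, p in self.plates.items()
            }
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenLayout":
        plates = {}
        for pid, pd_ in d["plates"].items():
            plates[pid] = PlateLayout(
                plate_id=pid,
                batch_id=pd_.get("batch_id", "batch1"),
                control_columns=tuple(pd_.get("control_columns", DEFAULT_CONTROL_COLUMNS)),
                sentinel=bool(pd_.get("sentinel", False)),
                treatments={
                    w: (str(v[0]), float(v[1]), int(v[2]))
                    for w, v in pd_.get("treatments", {}).items()
                },
            )
        return cls(plates=plates)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenLayout":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def triplicate_screen_layout(
    compounds: list[str],
    n_replicates: int = 3,
    concentration: float = 3.0,
    batch_id: str = "batch1",
    n_sentinels: int = 2,
    control_columns: tuple[int, ...] = DEFAULT_CONTROL_COLUMNS,
    plate_prefix: str = "P",
) -> ScreenLayout:
    """Standard screen layout: each compound occupies one assay well position,
    replicated at the same position on `n_replicates` plates; `n_sentinels`
    all-vehicle plates are appended per batch.  Compounds beyond one plate's
    assay capacity spill onto further plate trios."""
    template = PlateLayout(plate_id="_t", control_columns=control_columns)
    assay = template.assay_wells()
    per_plate = len(assay)
    plates: dict[str, PlateLayout] = {}
    n_trios = (len(compounds) + per_plate - 1) // per_plate if compounds else 0
    idx = 0
    for trio in range(n_trios):
        chunk = compounds[trio * per_plate : (trio + 1) * per_plate]
        tmap_by_rep = []
        for rep in range(n_replicates):
            tmap = {
                assay[i]: (comp, concentration, rep + 1)
                for i, comp in enumerate(chunk)
            }
            tmap_by_rep.append(tmap)
        for rep in range(n_replicates):
            idx += 1
            pid = f"{plate_prefix}{idx:02d}"
            plates[pid] = PlateLayout(
                plate_id=pid,
                batch_id=batch_id,
                control_columns=control_columns,
                treatments=tmap_by_rep[rep],
            )
    for s in range(n_sentinels):
        idx += 1
        pid = f"{plate_prefix}{idx:02d}"
        plates[pid] = PlateLayout(
            plate_id=pid,
            batch_id=batch_id,
            control_columns=control_columns,
            sentinel=True,
        )
    return ScreenLayout(plates=plates)
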