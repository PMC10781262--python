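"""Comparison metrics: ratio-error pairs, camera-placement selection, and
per-part error / accuracy aggregation.

Two scale-free ratio errors validate a generated body against a reference:
``A`` compares the chest/waist circumference ratio, ``B`` the arm/thigh
ratio.  A grid of such pairs measured over candidate camera placements
(height above ground x distance to subject) is reduced to a single placement
by minimising A + B per generation model; the bundled reference grid from
physical capture trials with SMPL- and PIFuHD-generated bodies selects
camera height 1 m and subject distance 3 m.

Per-part accuracy aggregates percent errors |actual - generated|/actual x 100
across parts; accuracy = 100 - mean error.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import MeasurementError, ParameterError
from .measure import MeasurementReport


@dataclass(frozen=True)
class RatioErrorPair:
    """A = chest/waist-ratio error, B = arm/thigh-ratio error (fractions >= 0)."""

    A: float
    B: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ParameterError("ratio errors must be non-negative")


@dataclass
class CameraGrid:
    """Per-model ratio-error pairs keyed by (cam_height_m, cam_distance_m).

    ``cells[model][(h, d)]`` is a :class:`RatioErrorPair`; placements where a
    model's generation broke down are listed in ``broken[model]`` and are
    never selectable for that model.
    """

    cells: dict[str, dict[tuple[float, float], RatioErrorPair]]
    broken: dict[str, set[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ok = any(
            cell not in self.broken.get(model, set())
            for model, grid in self.cells.items()
            for cell in grid
        )
        if not ok:
            raise ParameterError("camera grid has no usable cell")


def ratio_error_pair(measured: MeasurementReport,
                     reference: MeasurementReport,
                     relative: bool = True) -> RatioErrorPair:
    """Ratio errors of ``measured`` against ``reference``.

    A uses r = chest/waist, B uses r = left_arm/left_thigh;
    each error is |r_m - r_ref| / r_ref (or |r_m - r_ref| with
    ``relative=False``).  Ratios make the comparison scale-free, so uniform
    rescaling of either report leaves both errors unchanged.
    """
    def ratio(rep: MeasurementReport, num: str, den: str) -> float:
        c = rep.circumferences
        if num not in c or den not in c:
            raise MeasurementError(f"report lacks girth {num!r} or {den!r}")
        if c[den] == 0:
            raise MeasurementError(f"zero {den!r} girth; ratio undefined")
        return c[num] / c[den]

    pairs = (("chest", "waist"), ("left_arm", "left_thigh"))
    errs = []
    for num, den in pairs:
        r_m = ratio(measured, num, den)
        r_ref = ratio(reference, num, den)
        if r_ref == 0:
            raise MeasurementError(f"zero reference ratio {num}/{den}")
        err = abs(r_m - r_ref)
        errs.append(err / r_ref if relative else err)
    return RatioErrorPair(A=errs[0], B=errs[1])


def select_camera(grid: CameraGrid) -> tuple[float, float]:
    """Placement minimising A + B, required to agree across models.

    For each model the non-broken cell with minimal A + B is found; if every
    model picks the same cell it is returned.  Otherwise the cell minimising
    the summed A + B over all models is returned with a warning (the models
    disagree).
    """
    per_model = {}
    for model, cells in grid.cells.items():
        usable = {
            cell: pair for cell, pair in cells.items()
            if cell not in grid.broken.get(model, set())
        }
        if not usable:
            continue
        per_model[model] = min(usable, key=lambda c: usable[c].A + usable[c].B)
    if not per_model:
        raise ParameterError("no model has a usable cell")
    picks = set(per_model.values())
    if len(picks) == 1:
        return picks.pop()
    warnings.warn(f"models disagree on the best placement: {per_model}")
    totals: dict[tuple[float, float], float] = {}
    for model, cells in grid.cells.items():
        for cell, pair in cells.items():
            if cell in grid.broken.get(model, set()):
                continue
            totals[cell] = totals.get(cell, 0.0) + pair.A + pair.B
    return min(totals, key=totals.get)


@dataclass
class ErrorSummary:
    """Per-part percent errors, their mean, and accuracy = 100 - mean."""

    per_part: dict[str, float]
    mean_error: float
    accuracy: float


def aggregate_errors(per_part_errors: dict[str, float]) -> ErrorSummary:
    """Aggregate already-computed per-part percent errors."""
    if not per_part_errors:
        raise ParameterError("no parts to aggregate")
    mean = sum(per_part_errors.values()) / len(per_part_errors)
    return ErrorSummary(per_part=dict(per_part_errors), mean_error=mean,
                        accuracy=100.0 - mean)


def error_summary(measured: MeasurementReport,
                  reference: MeasurementReport,
                  parts: list[str]) -> ErrorSummary:
    """Percent error per part between two reports, averaged into an accuracy.

    Per-part error = 100 * |actual - generated| / actual where ``reference``
    holds the actual values.  Parts whose actual value is zero are excluded
    with a warning.  Scaling both reports by the same factor leaves every
    percent error unchanged.
    """

    def value(rep: MeasurementReport, part: str) -> float:
        if part == "height":
            return rep.height
        if part == "chest_volume":
            return rep.chest_volume
        if part in rep.circumferences:
            return rep.circumferences[part]
        if part in rep.lengths:
            return rep.lengths[part]
        raise MeasurementError(f"part {part!r} not present in report")

    per_part = {}
    for part in parts:
        actual = value(reference, part)
        generated = value(measured, part)
        if actual == 0:
            warnings.warn(f"part {part!r} has zero actual value; excluded")
            continue
        per_part[part] = 100.0 * abs(actual - generated) / abs(actual)
    return aggregate_errors(per_part)


# ---------------------------------------------------------------------------
# bundled reference grid

#: (A, B) ratio errors by model, camera height (m) and subject distance (m),
#: measured in the physical capture trials that fixed the default placement.
#: PIFuHD generation broke down entirely at 4 m.
_REFERENCE_GRID_ROWS = [
    # (height_m, distance_m, SMPL_A, SMPL_B, PIFuHD_A, PIFuHD_B)
    (0.5, 1.5, 0.223, 0.326, 0.174, 0.210),
    (1.0, 1.5, 0.251, 0.284, 0.186, 0.240),
    (1.5, 1.5, 0.204, 0.274, 0.155, 0.232),
    (0.5, 2.0, 0.250, 0.124, 0.142, 0.129),
    (1.0, 2.0, 0.197, 0.140, 0.127, 0.146),
    (1.5, 2.0, 0.257, 0.290, 0.115, 0.178),
    (0.5, 2.5, 0.114, 0.157, 0.070, 0.184),
    (1.0, 2.5, 0.188, 0.237, 0.034, 0.240),
    (1.5, 2.5, 0.192, 0.160, 0.094, 0.153),
    (0.5, 3.0, 0.081, 0.074, 0.058, 0.074),
    (1.0, 3.0, 0.063, 0.057, 0.021, 0.034),
    (1.5, 3.0, 0.115, 0.047, 0.045, 0.041),
    (0.5, 3.5, 0.125, 0.155, 0.065, 0.081),
    (1.0, 3.5, 0.245, 0.156, 0.242, 0.213),
    (1.5, 3.5, 0.162, 0.122, 0.172, 0.084),
    (0.5, 4.0, 0.224, 0.172, None, None),
    (1.0, 4.0, 0.120, 0.149, None, None),
    (1.5, 4.0, 0.092, 0.157, None, None),
]


def reference_camera_grid() -> CameraGrid:
    """The bundled camera-placement error grid (SMPL and PIFuHD columns)."""
    cells: dict[str, dict] = {"SMPL": {}, "PIFuHD": {}}
    broken: dict[str, set] = {"SMPL": set(), "PIFuHD": set()}
    for h, d, sa, sb, pa, pb in _REFERENCE_GRID_ROWS:
        cell = (h, d)
        cells["SMPL"][cell] = RatioErrorPair(sa, sb)
        if pa is None:
            broken["PIFuHD"].add(cell)
        else:
            cells["PIFuHD"][cell] = RatioErrorPair(pa, pb)
    return CameraGrid(cells=cells, broken=broken)


def read_camera_grid_csv(path: str | Path) -> CameraGrid:
    """Load a grid from CSV columns height_m, distance_m, model, A, B, broken."""
    cells: dict[str, dict] = {}
    broken: dict[str, set] = {}
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            model = row["model"]
            cell = (float(row["height_m"]), float(row["distance_m"]))
            is_broken = str(row.get("broken", "")).strip().lower() in ("1", "true", "yes")
            if is_broken:
                broken.setdefault(model, set()).add(cell)
                continue
            cells.setdefault(model, {})[cell] = RatioErrorPair(
                float(row["A"]), float(row["B"])
            )
    return CameraGrid(cells=cells, broken=broken)
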