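"""Seed-point detection and body segmentation on frontal depth maps.

Eleven named keypoints are located on the silhouette of a frontal A-pose
depth map — head top, neck, two shoulders, two armpits, two fingertips, two
toes and the crotch — using width-profile rules:

* the topmost silhouette row is the head end;
* the neck is the thinnest row within the top 30 % of the body (searched
  below the widest head row so the rounded head apex cannot win);
* each shoulder is the inflection point of the side contour below the neck;
* each armpit is the first row below the shoulder where a gap opens between
  arm and torso (the interval count rises);
* fingertips come from a range search over the columns outside the torso;
* toes are the bottommost pixels of each leg, and the crotch is the lowest
  row, scanning up the midline from the toes, where the two leg intervals
  merge.

The rules assume an A-pose: arms abducted clear of the torso and legs apart,
otherwise the gap rules cannot fire and a :class:`DetectionError` names the
landmark that failed.  Detection is deterministic and purely 2D; world
heights are attached by casting each pixel back through the camera.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DetectionError, SegmentationError
from .projection import DepthMap, back_project

SEED_NAMES = (
    "head_top",
    "neck",
    "left_shoulder",
    "right_shoulder",
    "left_armpit",
    "right_armpit",
    "left_fingertip",
    "right_fingertip",
    "left_toe",
    "right_toe",
    "crotch",
)

SEGMENT_LABELS = (
    "background",
    "head",
    "neck",
    "torso",
    "left_arm",
    "right_arm",
    "left_leg",
    "right_leg",
)


@dataclass
class SeedPointSet:
    """The 11 named keypoints in pixel and world coordinates.

    ``points`` maps each name to (row, col); ``world_heights`` to world Y in
    mm; ``world_points`` to the full 3D world point (mm).
    """

    points: dict[str, tuple[int, int]]
    world_heights: dict[str, float]
    world_points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(SEED_NAMES) - set(self.points)
        if missing:
            raise SegmentationError(f"missing seed points: {sorted(missing)}")
        self.validate_ordering()

    def validate_ordering(self) -> None:
        """Vertical anatomy: head < neck < shoulder <= armpit < crotch < toe
        in image rows (row 0 at the top)."""
        p = self.points
        r = {k: p[k][0] for k in p}
        ok = (
            r["head_top"] < r["neck"]
            and r["neck"] < r["left_shoulder"]
            and r["neck"] < r["right_shoulder"]
            and r["left_shoulder"] <= r["left_armpit"]
            and r["right_shoulder"] <= r["right_armpit"]
            and max(r["left_armpit"], r["right_armpit"]) < r["crotch"]
            and r["crotch"] < r["left_toe"]
            and r["crotch"] < r["right_toe"]
        )
        if not ok:
            raise SegmentationError(f"seed rows violate vertical ordering: {r}")
        for left, right in (
            ("left_shoulder", "right_shoulder"),
            ("left_armpit", "right_armpit"),
            ("left_fingertip", "right_fingertip"),
            ("left_toe", "right_toe"),
        ):
            if not p[left][1] < p[right][1]:
                raise SegmentationError(
                    f"{left} column must be left of {right} column"
                )

    def to_json_dict(self) -> dict:
        return {
            name: [int(self.points[name][0]), int(self.points[name][1]),
                   float(self.world_heights[name])]
            for name in SEED_NAMES
        }


@dataclass
class BodySegmentMap:
    """Per-pixel part labels partitioning the silhouette."""

    labels: np.ndarray  # H x W of indices into SEGMENT_LABELS

    def mask(self, name: str) -> np.ndarray:
        return self.labels == SEGMENT_LABELS.index(name)

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == i).sum())
            for i, name in enumerate(SEGMENT_LABELS)
        }


# ---------------------------------------------------------------------------
# width profile


def _row_intervals(mask_row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as [start, stop) column intervals."""
    idx = np.flatnonzero(mask_row)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), stops.tolist()))


def width_profile(dm: DepthMap):
    """Per-row silhouette width and interval decomposition.

    Returns ``(width, smooth, intervals)``: total nonzero-pixel count per row,
    a 5-row moving average of it, and the per-row list of maximal column
    intervals.  The smoothed profile feeds the thinnest-row and inflection
    rules; the raw intervals feed the gap (interval-count) rules.
    """
    sil = dm.silhouette()
    if not sil.any():
        raise DetectionError("silhouette", "depth map has no nonzero pixels")
    width = sil.sum(axis=1).astype(np.float64)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(width, kernel, mode="same")
    intervals = [_row_intervals(sil[r]) for r in range(sil.shape[0])]
    return width, smooth, intervals


# ---------------------------------------------------------------------------
# seed-point rules


def find_crotch_row(
    intervals: list[list[tuple[int, int]]],
    bottom_row: int,
    stop_row: int,
    left_col: int,
    right_col: int,
) -> int | None:
    """Lowest row, scanning upward from ``bottom_row``, where the intervals
    containing the two toe columns are one and the same.  Returns None if the
    legs never merge before ``stop_row``."""
    for r in range(bottom_row, stop_row, -1):
        ivs = intervals[r]
        li = next((iv for iv in ivs if iv[0] <= left_col < iv[1]), None)
        ri = next((iv for iv in ivs if iv[0] <= right_col < iv[1]), None)
        if li is not None and ri is not None and li == ri:
            return r
    return None


def _side_contour(sil: np.ndarray, rows: np.ndarray, side: str) -> np.ndarray:
    """Outermost silhouette column per row (min col on the left side)."""
    out = np.full(len(rows), np.nan)
    for i, r in enumerate(rows):
        cols = np.flatnonzero(sil[r])
        if cols.size:
            out[i] = cols[0] if side == "left" else cols[-1]
    return out


def _smooth5(x: np.ndarray) -> np.ndarray:
    return np.convolve(x, np.ones(5) / 5.0, mode="same")


def detect_seed_points(dm: DepthMap) -> SeedPointSet:
    """Locate the 11 seed points on a frontal A-pose depth map.

    Rules fire top-down in anatomical order; each failure raises a
    :class:`DetectionError` naming the landmark.  Ties break toward the
    topmost row.  The "top 30 %" window is measured over silhouette rows
    (head-top row to lowest toe row), not image rows.
    """
    sil = dm.silhouette()
    width, smooth, intervals = width_profile(dm)
    occupied = np.flatnonzero(width > 0)
    top_row, bottom_row = int(occupied[0]), int(occupied[-1])
    sil_height = bottom_row - top_row + 1
    if sil_height < 100:
        raise DetectionError("silhouette", f"height {sil_height}px < 100px")

    # (1) head top: topmost row, centroid column
    head_cols = np.flatnonzero(sil[top_row])
    head = (top_row, int(round(head_cols.mean())))

    # (2) neck: thinnest smoothed row within the top 30%, searched below the
    # widest head row (the rounded apex would otherwise always win)
    win_end = top_row + int(round(0.30 * sil_height))
    win = np.arange(top_row, min(win_end, bottom_row) + 1)
    w = smooth[win]
    # first local max of the smoothed width going down = widest head row
    head_peak = 0
    for i in range(1, len(w) - 1):
        if w[i] >= w[i - 1] and w[i] > w[i + 1]:
            head_peak = i
            break
    else:
        head_peak = int(np.argmax(w))
    seg = w[head_peak:]
    if seg.size == 0:
        raise DetectionError("neck", "no rows below the head peak in the top 30%")
    neck_row = int(win[head_peak + int(np.argmin(seg))])
    neck_cols = np.flatnonzero(sil[neck_row])
    neck = (neck_row, int(round(neck_cols.mean())))

    # (3) shoulders: first sign change of the second difference of the
    # smoothed side contour below the neck.  Curvature below 0.5 px is
    # treated as zero to ignore rasterisation jitter; the first three rows
    # are skipped because the moving average is edge-padded there.
    shoulders = {}
    for side in ("left", "right"):
        rows = np.arange(neck_row, bottom_row + 1)
        contour = _side_contour(sil, rows, side)
        valid = np.isfinite(contour)
        contour = np.where(valid, contour, np.nanmean(contour))
        sm = _smooth5(contour)
        d2 = np.diff(sm, n=2)  # d2[i] is curvature at rows[i+1]
        shoulder_row = None
        prev_sign = 0
        for i, v in enumerate(d2):
            if i + 1 < 3:
                continue
            s = 0 if abs(v) < 0.5 else (1 if v > 0 else -1)
            if prev_sign != 0 and s != 0 and s != prev_sign:
                shoulder_row = int(rows[i + 1])
                break
            if s != 0:
                prev_sign = s
        if shoulder_row is None:
            raise DetectionError(f"{side}_shoulder", "no contour inflection below neck")
        col = int(contour[shoulder_row - neck_row])
        shoulders[side] = (shoulder_row, col)

    # (4) armpits: first row below the shoulder where the interval count
    # increases (gap opens between arm and torso); point at the torso-side
    # gap boundary.  The increase must persist for 3 consecutive rows so a
    # single-row rasterisation sliver cannot fire the rule early.
    armpits = {}
    for side in ("left", "right"):
        sh_row = shoulders[side][0]
        base = len(intervals[sh_row])
        armpit = None
        for r in range(sh_row + 1, bottom_row + 1):
            cnt = len(intervals[r])
            if cnt > base:
                persistent = all(
                    len(intervals[rr]) > base
                    for rr in range(r, min(r + 3, bottom_row + 1))
                )
                if not persistent:
                    continue
                ivs = intervals[r]
                # torso = interval containing the midline
                mid = neck[1]
                torso_iv = min(
                    ivs, key=lambda iv: abs((iv[0] + iv[1]) / 2.0 - mid)
                )
                col = torso_iv[0] if side == "left" else torso_iv[1] - 1
                armpit = (r, int(col))
                break
            base = min(base, cnt)
        if armpit is None:
            raise DetectionError(
                f"{side}_armpit", "no gap below the shoulder line (arms touch torso?)"
            )
        armpits[side] = armpit

    armpit_row = max(armpits["left"][0], armpits["right"][0])
    torso_iv = min(
        intervals[armpit_row],
        key=lambda iv: abs((iv[0] + iv[1]) / 2.0 - neck[1]),
    )

    # (5) fingertips: range search over columns outside the central body
    # span (torso interval widened by the legs' bottom-row span, so leg
    # pixels never shadow the search); arms hang abducted, so the arm end
    # is the bottommost such pixel on each side
    bottom_ivs = intervals[bottom_row]
    legs_span = (
        min(iv[0] for iv in bottom_ivs),
        max(iv[1] for iv in bottom_ivs),
    )
    excl = (min(torso_iv[0], legs_span[0]), max(torso_iv[1], legs_span[1]))
    tips = {}
    for side in ("left", "right"):
        if side == "left":
            region = sil[:, : excl[0]]
            col_off = 0
        else:
            region = sil[:, excl[1]:]
            col_off = excl[1]
        rows_any = np.flatnonzero(region.any(axis=1))
        rows_any = rows_any[rows_any > shoulders[side][0]]
        if rows_any.size == 0:
            raise DetectionError(f"{side}_fingertip", "no pixels outside torso columns")
        tip_row = int(rows_any[-1])
        cols = np.flatnonzero(region[tip_row])
        tip_col = int(cols[0] + col_off) if side == "left" else int(cols[-1] + col_off)
        tips[side] = (tip_row, tip_col)

    # (6) toes: bottommost pixel of each leg interval.  Legs are the
    # intervals at the bottom silhouette row.
    if len(bottom_ivs) < 2:
        raise DetectionError("toes", f"expected 2 leg intervals at the bottom row, got {len(bottom_ivs)}")
    bottom_sorted = sorted(bottom_ivs, key=lambda iv: iv[0])
    left_iv, right_iv = bottom_sorted[0], bottom_sorted[-1]
    toes = {
        "left": (bottom_row, int((left_iv[0] + left_iv[1] - 1) // 2)),
        "right": (bottom_row, int((right_iv[0] + right_iv[1] - 1) // 2)),
    }

    # (7) crotch: scan upward from the toes; lowest row where the two leg
    # intervals have merged into one
    crotch_row = find_crotch_row(
        intervals, bottom_row, armpit_row, toes["left"][1], toes["right"][1]
    )
    if crotch_row is None:
        raise DetectionError("crotch", "leg intervals never merge (legs joined or missing)")
    crotch = (crotch_row, int((toes["left"][1] + toes["right"][1]) // 2))

    points = {
        "head_top": head,
        "neck": neck,
        "left_shoulder": shoulders["left"],
        "right_shoulder": shoulders["right"],
        "left_armpit": armpits["left"],
        "right_armpit": armpits["right"],
        "left_fingertip": tips["left"],
        "right_fingertip": tips["right"],
        "left_toe": toes["left"],
        "right_toe": toes["right"],
        "crotch": crotch,
    }

    world_points = {}
    world_heights = {}
    for name, (r, c) in points.items():
        rr, cc = int(r), int(c)
        if dm.pixels[rr, cc] == 0:  # centroid cols can fall on background
            cols = np.flatnonzero(sil[rr])
            cc = int(cols[np.argmin(np.abs(cols - cc))])
            points[name] = (rr, cc)
        wp = back_project(dm, rr, cc)
        world_points[name] = wp
        world_heights[name] = float(wp[1])

    return SeedPointSet(points=points, world_heights=world_heights,
                        world_points=world_points)


# ---------------------------------------------------------------------------
# segmentation


def segment_body(dm: DepthMap, seeds: SeedPointSet) -> BodySegmentMap:
    """Partition the silhouette into head/neck/torso/arms/legs.

    Head: rows above the neck.  Neck: rows from the neck to the shoulder.
    Arms: pixels below the armpit rows outside the torso column interval.
    Legs: pixels below the crotch, split at the midline.  Torso: the rest.
    The labels exactly cover the silhouette.
    """
    seeds.validate_ordering()
    sil = dm.silhouette()
    H, W = sil.shape
    labels = np.zeros((H, W), dtype=np.uint8)
    p = seeds.points

    neck_row = p["neck"][0]
    shoulder_row = min(p["left_shoulder"][0], p["right_shoulder"][0])
    armpit_row_l = p["left_armpit"][0]
    armpit_row_r = p["right_armpit"][0]
    crotch_row = p["crotch"][0]
    torso_left = p["left_armpit"][1]
    torso_right = p["right_armpit"][1]
    mid_col = p["crotch"][1]

    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]

    head = sil & (rows < neck_row)
    neck = sil & (rows >= neck_row) & (rows < shoulder_row)
    left_arm = sil & (rows >= armpit_row_l) & (cols < torso_left) & ~head & ~neck
    right_arm = sil & (rows >= armpit_row_r) & (cols > torso_right) & ~head & ~neck
    legs = sil & (rows > crotch_row) & ~left_arm & ~right_arm
    left_leg = legs & (cols <= mid_col)
    right_leg = legs & (cols > mid_col)
    assigned = head | neck | left_arm | right_arm | left_leg | right_leg
    torso = sil & ~assigned

    for name, mask in (
        ("head", head),
        ("neck", neck),
        ("torso", torso),
        ("left_arm", left_arm),
        ("right_arm", right_arm),
        ("left_leg", left_leg),
        ("right_leg", right_leg),
    ):
        labels[mask] = SEGMENT_LABELS.index(name)

    return BodySegmentMap(labels=labels)
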