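"""Sperm motility quantification from dark-field movie stacks.

Three estimators, mirroring the standard dark-field workflow:

- a global **motility score**: per frame pair, the number of pixels that
  change between binarized frames, with an aggregate normalized to sperm
  density (mean raw pixel intensity);
- **percent motile** by per-cell detection (Otsu threshold + connected
  components) and nearest-neighbour frame-to-frame linking, classifying a
  cell as motile if its net displacement over a sliding window exceeds a
  threshold (default 2 cell diameters over 1 s);
- per-cell **response latency** after a flash frame: the first post-flash
  time a cell's frame-to-frame displacement exceeds a speed threshold.

Thresholds are declared tunables (the original analysis software is not
published): link radius 3 cell diameters, motile displacement 2 diameters
per 1-s window, minimum blob area 4 px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


class InputError(ValueError):
    pass


@dataclass
class MovieStack:
    """T x H x W nonnegative intensity movie with acquisition metadata."""

    frames: np.ndarray
    fps: float                      # 25 Hz (sea urchin) or 40 Hz (salmon)
    flash_index: int | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise InputError("movie must be T x H x W with T >= 2")
        if self.fps <= 0:
            raise InputError("frame rate must be positive")
        if np.any(self.frames < 0):
            raise InputError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def from_tiff(cls, path, fps: float, flash_index: int | None = None):
        return cls(frames=tifffile.imread(str(path)), fps=fps,
                   flash_index=flash_index)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(str(path), self.frames)


@dataclass
class TrackingParams:
    min_area_px: int = 4
    max_link_diameters: float = 3.0   # link radius, in cell diameters
    motile_displacement_diameters: float = 2.0
    window_s: float = 1.0
    latency_speed_diameters: float = 0.25  # per-frame step threshold


@dataclass
class MotilityReport:
    score_series: np.ndarray
    score: float | None          # density-normalized aggregate
    mean_intensity: float
    percent_motile: float | None = None
    cell_count: int | None = None
    cells: pd.DataFrame | None = None
    latencies_s: np.ndarray | None = None
    responder_fraction: float | None = None


# ---------------------------------------------------------------------------
# Binarization and global score
# ---------------------------------------------------------------------------

def binarize(frame: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Boolean foreground mask; a constant frame yields an all-false mask."""
    frame = np.asarray(frame)
    if np.any(frame < 0):
        raise InputError("intensities must be nonnegative")
    if frame.max() == frame.min():
        return np.zeros(frame.shape, dtype=bool)
    if method == "otsu":
        # normalize to the frame maximum so the threshold (and hence the
        # mask) is invariant under global intensity scaling
        norm = frame / frame.max()
        return norm > threshold_otsu(norm)
    raise InputError(f"unknown binarization method {method!r}")


def motility_score(stack: MovieStack) -> MotilityReport:
    """Frame-subtraction motility score.

    Per consecutive frame pair, the count of pixels whose binarized value
    changes; the aggregate is the mean count divided by the raw stack's
    mean pixel intensity (sperm-density proxy).  A zero-intensity stack
    gets a flagged (None) aggregate.
    """
    masks = np.stack([binarize(f) for f in stack.frames])
    series = (masks[1:] ^ masks[:-1]).sum(axis=(1, 2)).astype(float)
    mean_intensity = float(stack.frames.mean())
    score = None if mean_intensity == 0 else float(series.mean() / mean_intensity)
    return MotilityReport(score_series=series, score=score,
                          mean_intensity=mean_intensity)


# ---------------------------------------------------------------------------
# Detection and tracking
# ---------------------------------------------------------------------------

def _detect(frame: np.ndarray, min_area: int):
    """Centroids (x=col, y=row) and areas of blobs above the area cutoff."""
    mask = binarize(frame)
    lab = label(mask)
    cents, areas = [], []
    for region in regionprops(lab):
        if region.area >= min_area:
            cents.append((region.centroid[1], region.centroid[0]))
            areas.append(region.area)
    return np.asarray(cents, dtype=float).reshape(-1, 2), np.asarray(areas)


class _Track:
    __slots__ = ("start", "pos", "missed")

    def __init__(self, start: int, first_pos):
        self.start = start
        self.pos: list = [first_pos]
        self.missed = 0

    def append(self, frame_pos, gap: int):
        """Append an observation, linearly interpolating skipped frames."""
        if gap > 1:
            last = self.pos[-1]
            for g in range(1, gap):
                self.pos.append(last + (frame_pos - last) * (g / gap))
        self.pos.append(frame_pos)
        self.missed = 0


def _link_tracks(stack: MovieStack, params: TrackingParams,
                 memory: int = 2):
    """Greedy nearest-neighbour linking into frame-contiguous tracks.

    A track that misses a detection (e.g. two cells transiently merging
    into one blob) stays alive for up to ``memory`` frames and is re-linked
    at its last position, with the gap filled by linear interpolation.
    Returns (tracks, diameter): each track has a start frame and an (n, 2)
    position array; diameter is the median-area-equivalent cell diameter.
    """
    detections = [_detect(f, params.min_area_px) for f in stack.frames]
    area_lists = [a for _, a in detections if a.size]
    if not area_lists:
        raise InputError("no cells detected")
    all_areas = np.concatenate(area_lists)
    diameter = 2.0 * math.sqrt(np.median(all_areas) / math.pi)
    max_link = params.max_link_diameters * diameter

    finished: list[_Track] = []
    active: list[_Track] = [_Track(0, p) for p in detections[0][0]]
    for t in range(1, stack.n_frames):
        pts, _ = detections[t]
        matched_tracks: set[int] = set()
        matched_pts: set[int] = set()
        if len(pts) and active:
            last = np.array([tr.pos[-1] for tr in active])
            tree = cKDTree(pts)
            k = min(len(pts), 3)
            dist, idx = tree.query(
                last, k=k, distance_upper_bound=max_link)
            dist = np.atleast_2d(dist.reshape(len(active), -1))
            idx = np.atleast_2d(idx.reshape(len(active), -1))
            # greedy unique assignment over all candidate pairs by distance
            pairs = [(dist[j, c], j, idx[j, c])
                     for j in range(len(active)) for c in range(dist.shape[1])
                     if np.isfinite(dist[j, c])]
            pairs.sort()
            for d, j, i in pairs:
                if j in matched_tracks or i in matched_pts:
                    continue
                matched_tracks.add(j)
                matched_pts.add(i)
                active[j].append(pts[i], gap=active[j].missed + 1)
        survivors = []
        for j, tr in enumerate(active):
            if j in matched_tracks:
                survivors.append(tr)
            else:
                tr.missed += 1
                if tr.missed > memory:
                    finished.append(tr)
                else:
                    survivors.append(tr)
        for i, p in enumerate(pts):
            if i not in matched_pts:
                survivors.append(_Track(t, p))
        active = survivors
    finished.extend(active)
    tracks = [(tr.start, np.asarray(tr.pos)) for tr in finished]
    return tracks, diameter


def percent_motile(
    stack: MovieStack, params: TrackingParams | None = None,
    min_track_frames: int = 5,
) -> MotilityReport:
    """Percent of tracked cell-time classified as motile.

    A track is motile if its path diameter within a sliding window of
    ``window_s`` (the largest displacement between any two positions at
    most one window apart; robust to direction reversals at the field
    edge) exceeds the motile threshold, pro-rated for tracks shorter than
    the window.  Tracks are weighted by their length in frames, so a cell
    whose track breaks into fragments (crossings, transient blob merges)
    contributes the same as an unbroken one; this keeps the estimate
    unbiased at realistic cell densities.
    """
    params = params or TrackingParams()
    tracks, diameter = _link_tracks(stack, params)
    w_full = max(int(round(params.window_s * stack.fps)), 1)
    thresh_full = params.motile_displacement_diameters * diameter
    rows = []
    for k, (start, tr) in enumerate(tracks):
        if len(tr) < min_track_frames:
            continue
        w = min(w_full, len(tr) - 1)
        thresh = thresh_full * (w / w_full)
        disp = max(
            float(np.linalg.norm(tr[d:] - tr[:-d], axis=1).max())
            for d in range(1, w + 1))
        rows.append({"track": k, "start": start, "length": len(tr),
                     "max_window_displacement_px": disp,
                     "motile": bool(disp > thresh)})
    if not rows:
        raise InputError("no track spans the analysis window")
    cells = pd.DataFrame(rows)
    weights = cells["length"].to_numpy(dtype=float)
    pct = 100.0 * float(
        (cells["motile"].to_numpy() * weights).sum() / weights.sum())
    base = motility_score(stack)
    base.percent_motile = pct
    base.cell_count = len(cells)
    base.cells = cells
    return base


def response_latency(
    stack: MovieStack, flash_index: int | None = None,
    params: TrackingParams | None = None,
) -> MotilityReport:
    """Per-cell latency of motility onset after the flash frame.

    For each track alive at the flash, the latency is the first post-flash
    time its frame-to-frame displacement exceeds the speed threshold;
    non-responders get ``inf``.  The responder fraction is the share of
    analysed cells with finite latency.
    """
    params = params or TrackingParams()
    flash = stack.flash_index if flash_index is None else flash_index
    if flash is None:
        raise InputError("flash frame index required")
    if not 0 <= flash < stack.n_frames - 2:
        raise InputError("flash index must leave >= 2 post-flash frames")
    tracks, diameter = _link_tracks(stack, params)
    step_thresh = params.latency_speed_diameters * diameter

    latencies = []
    for start, tr in tracks:
        end = start + len(tr)  # exclusive
        # analyse tracks that cover the flash and at least 2 frames after
        if start > flash or end < flash + 3:
            continue
        steps = np.linalg.norm(np.diff(tr, axis=0), axis=1)
        # steps[i] is the displacement from frame start+i to start+i+1
        post = steps[flash - start:]
        # sustained motion: two consecutive supra-threshold steps, so a
        # transient centroid jump from two blobs merging does not count
        above = post > step_thresh
        sustained = above[:-1] & above[1:] if above.size > 1 else above
        hit = np.nonzero(sustained)[0]
        # latency = onset of the first moving interval after the flash
        latencies.append(hit[0] / stack.fps if hit.size else math.inf)
    if not latencies:
        raise InputError("no track covers the flash frame")
    latencies = np.asarray(latencies)
    base = motility_score(stack)
    base.latencies_s = latencies
    base.cell_count = len(latencies)
    base.responder_fraction = float(np.isfinite(latencies).mean())
    return base
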