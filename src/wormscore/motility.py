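"""Swim-video processing: binarization, tracking, bend counting.

The chain mirrors a standard thrashing-assay workflow: subtract a static
background estimate, threshold to a binary worm mask, link connected
components across frames into per-animal tracks, and count body bends from
the oscillation of each animal's shape. The per-frame shape descriptor is
the normalized elongation

    e = (l1 - l2) / (l1 + l2)

of the component's second-moment (inertia) tensor eigenvalues l1 >= l2:
close to 1 for a straightened worm and dipping as the body curls, so it
oscillates once per body bend. BBPS is the hysteresis-filtered
zero-crossing rate of the mean-centered signal divided by two (two
crossings per bend).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats

from .stats import StatResult

__all__ = [
    "WormTrack", "SwimmingRecord", "binarize_frames", "track_worms",
    "count_body_bends", "defect_fraction", "swim_defect_test",
    "records_from_video", "BBPS_THRESHOLD",
]

#: Defect threshold in bends/s: the corroborated mean swimming rate of
#: lmn-1(Y59C) worms. Animals at or below it count as defective swimmers.
BBPS_THRESHOLD = 1.1


@dataclass
class WormTrack:
    """One animal's per-frame centroid and bend signal."""

    worm_id: int
    frames: np.ndarray          # frame indices, increasing
    centroids: np.ndarray       # (n, 2) as (x, y) px
    bend_signal: np.ndarray     # normalized elongation per frame
    fps: float

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.centroids) or \
                len(self.frames) != len(self.bend_signal):
            raise ValueError("track arrays must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class SwimmingRecord:
    """Body bends per second for one animal over one observation window."""

    genotype: str
    animal_id: str
    bbps: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.bbps < 0 or self.duration_s <= 0:
            raise ValueError("bbps must be >= 0 and duration_s > 0")


def binarize_frames(frames: np.ndarray, background: str = "median_stack",
                    threshold: str = "otsu", level: float | None = None,
                    rolling_window: int = 15, closing: int = 2) -> np.ndarray:
    """Background-subtract and threshold a grayscale stack.

    Parameters
    ----------
    frames
        ``(T, H, W)`` grayscale stack, T >= 2, constant dimensions.
    background
        ``median_stack`` — per-pixel median over (a uniform subsample of at
        most 64 of) the frames; ``rolling`` — per-pixel median over a
        centered temporal window of ``rolling_window`` frames.
    threshold
        ``otsu`` — one global Otsu level on the subtracted stack; ``fixed``
        — user-supplied ``level`` on the subtracted intensities.
    closing
        Iterations of 8-connected morphological closing applied per frame
        after thresholding; bridges the small holes the background model
        leaves where an animal lingers. 0 disables.

    Returns a boolean stack; True marks worm (foreground) pixels.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with at least 2 frames")
    n = len(frames)

    if background == "median_stack":
        idx = np.linspace(0, n - 1, min(n, 64)).astype(int)
        bg = np.median(frames[idx].astype(np.float32), axis=0)

        def subtracted(t: int) -> np.ndarray:
            return np.clip(frames[t].astype(np.float32) - bg, 0.0, None)
    elif background == "rolling":
        half = max(rolling_window // 2, 1)

        def subtracted(t: int) -> np.ndarray:
            lo, hi = max(0, t - half), min(n, t + half + 1)
            win = np.median(frames[lo:hi].astype(np.float32), axis=0)
            return np.clip(frames[t].astype(np.float32) - win, 0.0, None)
    else:
        raise ValueError(f"unknown background mode {background!r}")

    if threshold == "otsu":
        # histogram Otsu over a uniform frame subsample, streamed to keep
        # memory flat on long stacks
        from skimage.filters import threshold_otsu
        hist = np.zeros(512, dtype=np.int64)
        lo_seen, hi_seen = np.inf, -np.inf
        for t in range(0, n, max(n // 64, 1)):
            s = subtracted(t)
            lo_seen = min(lo_seen, float(s.min()))
            hi_seen = max(hi_seen, float(s.max()))
            hist += np.histogram(s, bins=512, range=(0.0, 512.0))[0]
        if hi_seen == lo_seen:
            raise ValueError("degenerate stack: constant intensity, "
                             "Otsu threshold is undefined")
        centers = np.arange(512, dtype=np.float64) + 0.5
        level = float(threshold_otsu(hist=(hist, centers)))
    elif threshold == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires a level")
    else:
        raise ValueError(f"unknown threshold mode {threshold!r}")

    binary = np.empty(frames.shape, dtype=bool)
    st = ndimage.generate_binary_structure(2, 2)
    for t in range(n):
        b = subtracted(t) > level
        if closing > 0 and b.any():
            b = ndimage.binary_closing(b, structure=st, iterations=closing)
        binary[t] = b
    return binary


def _frame_components(mask: np.ndarray, min_area: int,
                      merge_dist_px: float = 45.0):
    """Centroids (x, y), normalized elongation and area per component.

    Components whose centroids lie within ``merge_dist_px`` are treated as
    fragments of one animal and merged (exactly, by adding raw moments):
    distinct animals never approach that closely, but background
    subtraction can transiently split one animal where it lingers.
    """
    lbl, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 2))
    if n == 0:
        return []
    ys, xs = np.nonzero(lbl)
    labels = lbl[ys, xs]
    cnt = np.bincount(labels, minlength=n + 1)[1:].astype(float)
    sx = np.bincount(labels, weights=xs, minlength=n + 1)[1:]
    sy = np.bincount(labels, weights=ys, minlength=n + 1)[1:]
    sxx = np.bincount(labels, weights=xs * xs.astype(float), minlength=n + 1)[1:]
    syy = np.bincount(labels, weights=ys * ys.astype(float), minlength=n + 1)[1:]
    sxy = np.bincount(labels, weights=xs * ys.astype(float), minlength=n + 1)[1:]

    # union-find merge of fragment clusters by centroid distance
    mx, my = sx / cnt, sy / cnt
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(mx[i] - mx[j], my[i] - my[j]) < merge_dist_px:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    out = []
    for members in sorted(groups.values(), key=min):  # lowest label first
        m = np.asarray(members)
        c = cnt[m].sum()
        if c < min_area:
            continue
        gx, gy = sx[m].sum() / c, sy[m].sum() / c
        ixx = sxx[m].sum() / c - gx**2
        iyy = syy[m].sum() / c - gy**2
        ixy = sxy[m].sum() / c - gx * gy
        tr = ixx + iyy
        d = np.sqrt((ixx - iyy) ** 2 + 4 * ixy**2)
        elong = d / tr if tr > 0 else 0.0
        out.append(((float(gx), float(gy)), float(elong), int(c)))
    return out


def track_worms(binary: np.ndarray, fps: float, min_area: int = 20,
                max_gap: int = 2, max_jump_px: float = 25.0) -> list[WormTrack]:
    """Link per-frame connected components into per-animal tracks.

    Components smaller than ``min_area`` px^2 are discarded. Each component
    is greedily assigned (in label order; lower label wins ties) to the
    nearest live track head within ``max_jump_px``; tracks not extended for
    more than ``max_gap`` frames are closed. Empty frames simply do not
    extend any track.
    """
    binary = np.asarray(binary).astype(bool)
    if binary.ndim != 3:
        raise ValueError("need a (T, H, W) binary stack")
    live: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for t in range(len(binary)):
        comps = _frame_components(binary[t], min_area)
        still = [tr for tr in live if t - tr["frames"][-1] <= max_gap + 1]
        done += [tr for tr in live if t - tr["frames"][-1] > max_gap + 1]
        live = still
        claimed: set[int] = set()
        for (cx, cy), elong, _area in comps:
            best, best_d = None, np.inf
            for i, tr in enumerate(live):
                if i in claimed:
                    continue
                px, py = tr["centroids"][-1]
                d = float(np.hypot(px - cx, py - cy))
                if d < best_d:
                    best, best_d = i, d
            if best is not None and best_d <= max_jump_px:
                tr = live[best]
                claimed.add(best)
            else:
                tr = {"id": next_id, "frames": [], "centroids": [],
                      "signal": []}
                next_id += 1
                live.append(tr)
                claimed.add(len(live) - 1)
            tr["frames"].append(t)
            tr["centroids"].append((cx, cy))
            tr["signal"].append(elong)
    done += live
    done.sort(key=lambda tr: tr["id"])
    return [
        WormTrack(tr["id"], np.asarray(tr["frames"]),
                  np.asarray(tr["centroids"], dtype=float),
                  np.asarray(tr["signal"], dtype=float), fps)
        for tr in done if len(tr["frames"]) >= 2
    ]


def count_body_bends(track: WormTrack, hysteresis: float = 0.25,
                     sd_floor: float = 5e-3, genotype: str = "",
                     animal_id: str | None = None) -> SwimmingRecord:
    """BBPS from hysteresis-filtered zero crossings of the bend signal.

    The signal is mean-centered; a crossing is registered each time it
    passes from beyond ``-h`` to beyond ``+h`` (or back), with
    ``h = hysteresis * SD(signal)``. BBPS = crossings / 2 / duration.
    Signals with SD below ``sd_floor`` (a motionless animal) count 0 bends.
    """
    if track.duration_s < 1.0:
        raise ValueError("track must span at least 1 s to count bends")
    sig = track.bend_signal - track.bend_signal.mean()
    sd = float(sig.std())
    aid = animal_id if animal_id is not None else str(track.worm_id)
    if sd < sd_floor:
        return SwimmingRecord(genotype, aid, 0.0, track.duration_s)
    h = hysteresis * sd
    state = 0
    crossings = 0
    for v in sig:
        if v > h:
            if state == -1:
                crossings += 1
            state = 1
        elif v < -h:
            if state == 1:
                crossings += 1
            state = -1
    bbps = crossings / 2.0 / track.duration_s
    return SwimmingRecord(genotype, aid, bbps, track.duration_s)


def records_from_video(frames: np.ndarray, fps: float, genotype: str = "",
                       min_area: int = 20, **binarize_kw) -> list[SwimmingRecord]:
    """Full chain: binarize -> track -> count, one record per track."""
    binary = binarize_frames(frames, **binarize_kw)
    tracks = track_worms(binary, fps, min_area=min_area)
    return [count_body_bends(tr, genotype=genotype)
            for tr in tracks if tr.duration_s >= 1.0]


def defect_fraction(records, threshold: float = BBPS_THRESHOLD) -> float:
    """Fraction of animals swimming at or below ``threshold`` bends/s.

    Boundary values count as defective (ties at the threshold are defects).
    Accepts SwimmingRecord sequences or plain BBPS iterables.
    """
    vals = np.asarray([r.bbps if isinstance(r, SwimmingRecord) else float(r)
                       for r in records], dtype=float)
    if vals.size == 0:
        raise ValueError("defect_fraction needs at least one record")
    return float(np.mean(vals <= threshold))


def swim_defect_test(variant_records, wildtype_records,
                     threshold: float = BBPS_THRESHOLD,
                     comparison: str = "variant vs wild type",
                     alpha: float = 0.05) -> StatResult:
    """Pearson chi-squared test on the 2x2 defective-by-strain table.

    No continuity correction. A table with a zero margin (e.g. no defective
    animal in either strain) is degenerate: statistic 0, p = 1, flagged.
    """
    def counts(records):
        vals = np.asarray([r.bbps if isinstance(r, SwimmingRecord) else float(r)
                           for r in records], dtype=float)
        if vals.size == 0:
            raise ValueError("both groups must be non-empty")
        d = int(np.sum(vals <= threshold))
        return d, vals.size - d

    d1, n1 = counts(variant_records)
    d0, n0 = counts(wildtype_records)
    table = np.array([[d1, n1], [d0, n0]], dtype=float)
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate:
        return StatResult(comparison, 0.0, 1.0, 1.0, "chi_squared", alpha,
                          note="degenerate 2x2 table (zero margin)")
    stat, p, _, _ = sstats.chi2_contingency(table, correction=False)
    return StatResult(comparison, float(stat), float(p), float(p),
                      "chi_squared", alpha)
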