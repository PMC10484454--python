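"""Ground-truthed synthetic swim videos.

Renders thrashing worms as thickened sinusoid-backboned curves on a noisy
8-bit background, at a known bend frequency per worm, so the whole
video-processing chain (background subtraction, binarization, tracking,
bend counting) can be validated closed-loop against the truth.

Bend convention
---------------
One *body bend* is one one-sided flex of the animal (two bends per full
left-right cycle, the usual thrashing-assay count). The renderer advances
the undulation phase so that the worm straightens once per bend, which is
what an elongation-based bend counter detects; a worm with
``bend_freq_hz = f`` therefore has true BBPS ``f``.

Worms also drift slowly perpendicular to their body axis. Without drift an
in-place thrasher occupies its backbone nodes in every frame and a median
background model would absorb (and subtract away) those pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SwimVideoTruth", "generate_swim_video", "render_clean_frame"]


@dataclass(frozen=True)
class SwimVideoTruth:
    """Global parameters of one synthetic swim video.

    ``bend_freq_hz`` is the default per-worm bend frequency (true BBPS);
    per-worm overrides go through ``generate_swim_video(bend_freqs=...)``.
    """

    bend_freq_hz: float = 1.0
    fps: float = 30.0
    duration_s: float = 30.0
    worm_length_px: float = 70.0
    amplitude_px: float = 8.0
    seed: int = 0
    frame_shape: tuple[int, int] = (512, 512)
    noise_sd: float = 5.0
    drift_px_per_s: float = 1.0
    thickness_px: float = 3.0
    base_level: float = 10.0
    worm_brightness: float = 190.0

    def __post_init__(self) -> None:
        if self.fps * self.duration_s < 2:
            raise ValueError("video must span at least 2 frames")
        if not 0 <= self.bend_freq_hz < self.fps / 4:
            raise ValueError("bend_freq_hz must satisfy 0 <= f < fps/4")
        if self.worm_length_px <= 0 or self.amplitude_px < 0:
            raise ValueError("worm geometry must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


def _disk_offsets(thickness: float) -> np.ndarray:
    r = thickness / 2.0 + 0.5
    m = int(np.ceil(r))
    dy, dx = np.mgrid[-m:m + 1, -m:m + 1]
    keep = dy**2 + dx**2 <= r**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _backbone(truth: SwimVideoTruth, worm: pd.Series, t_s: float) -> np.ndarray:
    """Backbone pixel coordinates (y, x) of one worm at time ``t_s``."""
    L = truth.worm_length_px
    n = max(int(L * 3), 8)
    s = np.linspace(0.0, L, n)
    # amplitude envelope oscillates at half the physical cycle rate so that
    # the animal straightens once per bend (see module docstring)
    a = truth.amplitude_px * np.sin(np.pi * worm["bend_freq_hz"] * t_s
                                    + worm["phase"])
    x_loc = s - L / 2.0
    y_loc = a * np.sin(2.0 * np.pi * s / L)
    th = worm["theta"]
    x = worm["cx"] + worm["drift_dx"] * t_s + x_loc * np.cos(th) - y_loc * np.sin(th)
    y = worm["cy"] + worm["drift_dy"] * t_s + x_loc * np.sin(th) + y_loc * np.cos(th)
    return np.stack([y, x], axis=1)


def render_clean_frame(truth: SwimVideoTruth, worms: pd.DataFrame,
                       frame_idx: int) -> np.ndarray:
    """Noise-free frame: worm pixels at ``worm_brightness``, rest 0.

    The nonzero support of this image is the ground-truth worm mask for
    frame ``frame_idx``.
    """
    h, w = truth.frame_shape
    frame = np.zeros((h, w), dtype=np.uint8)
    offs = _disk_offsets(truth.thickness_px)
    t_s = frame_idx / truth.fps
    for _, worm in worms.iterrows():
        bb = np.round(_backbone(truth, worm, t_s)).astype(int)
        pts = (bb[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        keep = ((pts[:, 0] >= 0) & (pts[:, 0] < h)
                & (pts[:, 1] >= 0) & (pts[:, 1] < w))
        pts = pts[keep]
        frame[pts[:, 0], pts[:, 1]] = int(truth.worm_brightness)
    return frame


def _place_worms(truth: SwimVideoTruth, n_worms: int,
                 rng: np.random.Generator) -> list[tuple[float, float]]:
    """Non-overlapping cell-grid placement; raises when density is too high."""
    h, w = truth.frame_shape
    extent = truth.worm_length_px + 2 * (truth.amplitude_px + truth.thickness_px)
    drift_total = truth.drift_px_per_s * truth.duration_s
    cell = float(np.hypot(extent, 2 * truth.amplitude_px
                          + 2 * truth.thickness_px) + drift_total + 6.0)
    ny, nx = int(h // cell), int(w // cell)
    if ny * nx < n_worms:
        raise ValueError(
            f"cannot place {n_worms} non-overlapping worms in a "
            f"{h}x{w} frame (capacity {ny * nx})"
        )
    cells = [(i, j) for i in range(ny) for j in range(nx)]
    rng.shuffle(cells)
    centers = []
    for i, j in cells[:n_worms]:
        cy = (i + 0.5) * cell + (h - ny * cell) / 2.0
        cx = (j + 0.5) * cell + (w - nx * cell) / 2.0
        centers.append((cy, cx))
    return centers


def generate_swim_video(truth: SwimVideoTruth, n_worms: int,
                        bend_freqs: np.ndarray | list | None = None,
                        positions: list[tuple[float, float, float]] | None = None,
                        ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a grayscale frame stack plus per-worm ground truth.

    Parameters
    ----------
    truth
        Video-level parameters.
    n_worms
        Number of animals to place (non-overlapping; raises if they don't fit).
    bend_freqs
        Optional per-worm bend frequencies (default: ``truth.bend_freq_hz``
        for all). Each must satisfy the Nyquist margin ``f < fps/4``.
    positions
        Optional explicit ``(cx, cy, theta)`` per worm, bypassing grid
        placement (no bounds checks — used e.g. to stage a worm leaving
        the field of view).

    Returns
    -------
    frames : uint8 array, shape ``(n_frames, H, W)``
    worms : DataFrame with ``worm_id``, ``bend_freq_hz`` (the true BBPS),
        initial center ``cx, cy``, orientation ``theta``, bend ``phase`` and
        drift velocity ``drift_dx, drift_dy`` (px/s). The expected centroid
        at time t is ``(cx + drift_dx * t, cy + drift_dy * t)``.
    """
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    rng = np.random.default_rng(truth.seed)
    if bend_freqs is None:
        freqs = np.full(n_worms, truth.bend_freq_hz, dtype=float)
    else:
        freqs = np.asarray(bend_freqs, dtype=float)
        if freqs.shape != (n_worms,):
            raise ValueError("bend_freqs must have length n_worms")
        if ((freqs < 0) | (freqs >= truth.fps / 4)).any():
            raise ValueError("every bend frequency must satisfy 0 <= f < fps/4")

    if positions is None:
        centers = _place_worms(truth, n_worms, rng)
        thetas = rng.uniform(0, np.pi, size=n_worms)
    else:
        if len(positions) != n_worms:
            raise ValueError("positions must have length n_worms")
        centers = [(cy, cx) for cx, cy, _ in positions]
        thetas = np.array([th for _, _, th in positions], dtype=float)

    phases = rng.uniform(0, 2 * np.pi, size=n_worms)
    # drift perpendicular to the body axis
    drift_dx = -np.sin(thetas) * truth.drift_px_per_s
    drift_dy = np.cos(thetas) * truth.drift_px_per_s
    worms = pd.DataFrame({
        "worm_id": np.arange(n_worms),
        "bend_freq_hz": freqs,
        "cx": [c[1] for c in centers],
        "cy": [c[0] for c in centers],
        "theta": thetas,
        "phase": phases,
        "drift_dx": drift_dx,
        "drift_dy": drift_dy,
    })

    n_frames = truth.n_frames
    h, w = truth.frame_shape
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for k in range(n_frames):
        clean = render_clean_frame(truth, worms, k).astype(np.float32)
        img = clean + truth.base_level
        if truth.noise_sd > 0:
            img += rng.normal(0.0, truth.noise_sd, size=(h, w)).astype(np.float32)
        frames[k] = np.clip(img, 0, 255).astype(np.uint8)
    return frames, worms
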