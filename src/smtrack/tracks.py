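"""Trajectory container shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = [
    "cell_id",
    "track_id",
    "frame",
    "x_um",
    "y_um",
    "psf_width_px",
    "amplitude",
    "background",
]


@dataclass
class Track:
    """Time-ordered localizations of one molecule within one cell.

    Frames are 0-based and strictly increasing; a missing intermediate frame
    is a (blinking or missed-detection) gap.  Positions are in μm, PSF widths
    in pixels, amplitude/background in camera counts.
    """

    track_id: int
    cell_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    psf_width: np.ndarray | None = None
    amplitude: np.ndarray | None = None
    background: np.ndarray | None = None
    analysis_ok: bool = True  # False: kept (>=2 spots) but below analysis length

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.frames) < 1:
            raise ValueError("track must contain at least one localization")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")
        for name in ("psf_width", "amplitude", "background"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames_spanned(self) -> int:
        """Number of frames from first to last localization inclusive."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def gap_frames(self) -> np.ndarray:
        """Frames inside the track's span with no localization."""
        full = np.arange(self.frames[0], self.frames[-1] + 1)
        return np.setdiff1d(full, self.frames)

    def mean_position(self) -> np.ndarray:
        return np.array([self.x.mean(), self.y.mean()])


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks into a tidy localization table (schema TRACK_COLUMNS)."""
    rows = []
    for t in tracks:
        n = len(t)
        nancol = np.full(n, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": np.full(n, t.cell_id),
                    "track_id": np.full(n, t.track_id),
                    "frame": t.frames,
                    "x_um": t.x,
                    "y_um": t.y,
                    "psf_width_px": t.psf_width if t.psf_width is not None else nancol,
                    "amplitude": t.amplitude if t.amplitude is not None else nancol,
                    "background": t.background if t.background is not None else nancol,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Inverse of :func:`tracks_to_frame`."""
    tracks = []
    if len(df) == 0:
        return tracks
    for (cell_id, track_id), g in df.groupby(["cell_id", "track_id"], sort=True):
        g = g.sort_values("frame")

        def _opt(col):
            v = g[col].to_numpy(dtype=float)
            return None if np.all(np.isnan(v)) else v

        tracks.append(
            Track(
                track_id=int(track_id),
                cell_id=int(cell_id),
                frames=g["frame"].to_numpy(dtype=int),
                x=g["x_um"].to_numpy(dtype=float),
                y=g["y_um"].to_numpy(dtype=float),
                psf_width=_opt("psf_width_px"),
                amplitude=_opt("amplitude"),
                background=_opt("background"),
            )
        )
    return tracks
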