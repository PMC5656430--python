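"""ROI trace extraction and conditioning.

Raw fluorescence is the per-frame mean of the pixels inside each cell's
outline.  Conditioning proceeds raw -> detrended -> global-subtracted ->
percent dF/F:

1. slow trends (photobleaching) are removed by subtracting locally fitted
   third-order polynomials (SALPA-style, sliding-window cubic least
   squares with a time constant of 1-15 s);
2. the mean brightness of the ganglion outside every ROI — detrended the
   same way — is subtracted per frame, removing the global fluctuation
   caused by fluorescent crosstalk between the two views;
3. the result is normalized to the cell's average raw fluorescence and
   expressed as a percent change in fluorescence (dF/F).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from skimage import draw
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ROI",
    "ROISet",
    "SalpaParams",
    "TraceSet",
    "extract_traces",
    "salpa_detrend",
    "subtract_global",
    "to_dff",
    "condition_traces",
    "SalpaDetrender",
]


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass
class ROI:
    """One cell outline: an ellipse (cx, cy, rx, ry, angle_deg) or polygon.

    Coordinates are 0-based pixels, x = column.
    """

    id: str
    view: str
    ellipse: tuple[float, float, float, float, float] | None = None
    polygon: np.ndarray | None = None   # (n, 2) array of (x, y) vertices

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        rows, cols = frame_shape
        m = np.zeros(frame_shape, dtype=bool)
        if self.ellipse is not None:
            cx, cy, rx, ry, ang = self.ellipse
            rr, cc = draw.ellipse(cy, cx, ry, rx, shape=frame_shape,
                                  rotation=np.deg2rad(ang))
            m[rr, cc] = True
        elif self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
            rr, cc = draw.polygon(poly[:, 1], poly[:, 0], shape=frame_shape)
            m[rr, cc] = True
        else:
            raise ValueError(f"ROI {self.id}: neither ellipse nor polygon given")
        if not m.any():
            raise ValueError(f"ROI {self.id}: no pixels inside the frame")
        # outline must genuinely lie within frame bounds
        if self.ellipse is not None:
            cx, cy, rx, ry, _ = self.ellipse
            if cx - rx < -0.5 or cx + rx > cols - 0.5 or \
               cy - ry < -0.5 or cy + ry > rows - 0.5:
                raise ValueError(f"ROI {self.id}: outline exceeds frame bounds")
        return m


@dataclass
class ROISet:
    """ROIs of one view, with unique ids."""

    rois: list[ROI]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.rois:
            key = (r.view, r.id)
            if key in seen:
                raise ValueError(f"duplicate ROI id {r.id!r} in view {r.view!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def for_view(self, view: str) -> "ROISet":
        return ROISet([r for r in self.rois if r.view == view])

    @classmethod
    def from_centers(cls, table: pd.DataFrame, view: str | None = None
                     ) -> "ROISet":
        """Build circular ROIs from a (id, view, center_x, center_y, radius)
        table, e.g. the synthetic generator's ground-truth ROI CSV."""
        rois = []
        for _, row in table.iterrows():
            if view is not None and row["view"] != view:
                continue
            r = float(row["radius"])
            rois.append(ROI(id=str(row["id"]), view=str(row["view"]),
                            ellipse=(float(row["center_x"]),
                                     float(row["center_y"]), r, r, 0.0)))
        return cls(rois)

    @classmethod
    def from_csv(cls, path: str | Path, view: str | None = None) -> "ROISet":
        return cls.from_centers(pd.read_csv(path), view=view)


# ---------------------------------------------------------------------------
# Trace containers and stages
# ---------------------------------------------------------------------------

STAGES = ("raw", "detrended", "global_subtracted", "dff")


@dataclass
class TraceSet:
    """Per-cell traces at one conditioning stage.

    ``data`` has one column per cell id; index is the frame time in
    seconds.  ``raw_means`` holds each cell's average raw fluorescence,
    the dF/F normalizer.
    """

    data: pd.DataFrame
    stage: str
    frame_rate_Hz: float
    raw_means: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("traces contain non-finite values")

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "frame_time_s"
        out.to_csv(path)


@dataclass(frozen=True)
class SalpaParams:
    """Local cubic detrending parameters.

    ``time_constant_s`` is the half-width of the sliding fit window; the
    polynomial order is fixed at 3.
    """

    time_constant_s: float = 15.0
    polynomial_order: int = 3

    def __post_init__(self) -> None:
        if not 1.0 <= self.time_constant_s <= 15.0:
            raise ValueError("time_constant_s must be within [1, 15] s")
        if self.polynomial_order != 3:
            raise ValueError("polynomial order is fixed at 3")

    def window_samples(self, frame_rate_Hz: float) -> int:
        """Full window length in samples (2 x time constant), odd, >= 5."""
        w = int(round(2.0 * self.time_constant_s * frame_rate_Hz))
        w = max(w, 5)
        return w + 1 if w % 2 == 0 else w


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_traces(stack: np.ndarray, rois: ROISet,
                   frame_rate_Hz: float,
                   frame_times: np.ndarray | None = None) -> TraceSet:
    """Average pixel values within each outline per frame (stage=raw)."""
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    t = (np.arange(n) / frame_rate_Hz if frame_times is None
         else np.asarray(frame_times, dtype=float))
    cols = {}
    for roi in rois:
        m = roi.mask(stack.shape[1:])
        cols[roi.id] = stack[:, m].mean(axis=1)
    data = pd.DataFrame(cols, index=pd.Index(t, name="time_s"))
    return TraceSet(data=data, stage="raw", frame_rate_Hz=frame_rate_Hz,
                    raw_means=data.mean(axis=0))


def _salpa_1d(x: np.ndarray, window: int) -> np.ndarray:
    """Local-cubic trend of one trace (sliding-window least squares)."""
    return savgol_filter(x, window_length=window, polyorder=3, mode="interp")


def salpa_detrend(traces: TraceSet, params: SalpaParams | None = None
                  ) -> TraceSet:
    """Subtract locally fitted third-order polynomials (stage=detrended).

    The trend at each sample is the center value of a cubic least-squares
    fit over a sliding window of 2 x ``time_constant_s``; edge samples use
    the polynomial fitted to the first/last full window.  Any cubic-in-time
    input is annihilated to numerical precision.
    """
    params = params or SalpaParams()
    n = len(traces.data)
    window = params.window_samples(traces.frame_rate_Hz)
    if window > n:
        raise ValueError(
            f"detrend window ({window} samples) exceeds trace length ({n}); "
            "reduce time_constant_s")
    values = traces.data.to_numpy()
    trend = np.apply_along_axis(_salpa_1d, 0, values, window)
    data = pd.DataFrame(values - trend, index=traces.data.index,
                        columns=traces.data.columns)
    return TraceSet(data=data, stage="detrended",
                    frame_rate_Hz=traces.frame_rate_Hz,
                    raw_means=traces.raw_means)


def subtract_global(traces: TraceSet, stack: np.ndarray, rois: ROISet,
                    params: SalpaParams | None = None,
                    ganglion_mask: np.ndarray | None = None) -> TraceSet:
    """Subtract the non-ROI background series (stage=global_subtracted).

    The background is the per-frame mean over all pixels inside the
    ganglion outline (whole frame if none is given) but outside every ROI,
    detrended with the same parameters before subtraction.
    """
    params = params or SalpaParams()
    stack = np.asarray(stack, dtype=float)
    shape = stack.shape[1:]
    bg = (np.ones(shape, dtype=bool) if ganglion_mask is None
          else np.asarray(ganglion_mask, dtype=bool).copy())
    for roi in rois:
        bg &= ~roi.mask(shape)
    if not bg.any():
        raise ValueError("no non-ROI pixels available for the global background")
    series = stack[:, bg].mean(axis=1)
    window = params.window_samples(traces.frame_rate_Hz)
    if window > len(series):
        raise ValueError("detrend window exceeds recording length")
    series = series - _salpa_1d(series, window)
    data = traces.data.sub(series, axis=0)
    return TraceSet(data=data, stage="global_subtracted",
                    frame_rate_Hz=traces.frame_rate_Hz,
                    raw_means=traces.raw_means)


def to_dff(traces: TraceSet) -> TraceSet:
    """Normalize to each cell's average raw fluorescence, percent units."""
    if traces.raw_means is None:
        raise ValueError("raw means unavailable; extract traces first")
    if (traces.raw_means <= 0).any():
        bad = traces.raw_means[traces.raw_means <= 0].index.tolist()
        raise ValueError(f"non-positive dF/F normalizer for cells {bad}")
    data = 100.0 * traces.data.div(traces.raw_means, axis=1)
    return TraceSet(data=data, stage="dff", frame_rate_Hz=traces.frame_rate_Hz,
                    raw_means=traces.raw_means)


def condition_traces(stack: np.ndarray, rois: ROISet, frame_rate_Hz: float,
                     salpa: SalpaParams | None = None,
                     ganglion_mask: np.ndarray | None = None,
                     frame_times: np.ndarray | None = None,
                     ) -> dict[str, TraceSet]:
    """Full conditioning chain; returns every stage keyed by name.

    If the requested detrend window does not fit the recording, the time
    constant is clipped to the largest value that does (and a warning is
    emitted), since short trials cannot support the longest windows.
    """
    salpa = salpa or SalpaParams()
    n = np.asarray(stack).shape[0]
    max_tau = (n - 2) / (2.0 * frame_rate_Hz)
    if salpa.window_samples(frame_rate_Hz) > n:
        clipped = max(1.0, min(15.0, max_tau))
        warnings.warn(
            f"SALPA time constant {salpa.time_constant_s} s does not fit a "
            f"{n}-frame recording; clipped to {clipped:.2f} s", stacklevel=2)
        salpa = SalpaParams(time_constant_s=clipped)
    raw = extract_traces(stack, rois, frame_rate_Hz, frame_times)
    det = salpa_detrend(raw, salpa)
    gs = subtract_global(det, stack, rois, salpa, ganglion_mask)
    dff = to_dff(gs)
    return {"raw": raw, "detrended": det, "global_subtracted": gs, "dff": dff}


class SalpaDetrender(BaseEstimator, TransformerMixin):
    """Transformer interface for local-cubic detrending.

    Operates on arrays of shape (n_traces, n_samples); each row is
    detrended independently.
    """

    def __init__(self, time_constant_s: float = 15.0,
                 frame_rate_Hz: float = 50.0):
        self.time_constant_s = time_constant_s
        self.frame_rate_Hz = frame_rate_Hz

    def fit(self, X, y=None):
        params = SalpaParams(time_constant_s=self.time_constant_s)
        self.window_samples_ = params.window_samples(self.frame_rate_Hz)
        return self

    def transform(self, X):
        if not hasattr(self, "window_samples_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.window_samples_ > X.shape[1]:
            raise ValueError("detrend window exceeds trace length")
        trend = savgol_filter(X, window_length=self.window_samples_,
                              polyorder=3, axis=1, mode="interp")
        return X - trend
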