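"""Autocorrelation-based signal-quality features FMin, MAmp and Sim.

Each 5-s sliding window of a segment yields a normalised autocorrelation
function (ACF) for lags 0-250 ms: within that range the ACF shape is
dominated by shifts of the QRS complex, so artefacts deform it in
characteristic ways.  Three segment-level features summarise the window
ACFs:

FMin
    minimum over windows of the lag (ms) of the first local ACF minimum.
    A clean QRS shift puts it near 35 ms; flat lines push it to the
    250 ms fallback, sharp high-amplitude spikes pull it down.
MAmp
    maximum over windows of the (signed) ACF value at 35 ms lag.  Clean
    windows sit well below zero there; flat lines and wide artefacts
    drive it toward +1.
Sim
    maximum pairwise Euclidean distance between window ACFs restricted
    to lags 30-115 ms.  A quasi-stationary ECG keeps all window ACFs
    alike (Sim near 0); artefacts make one window's ACF diverge.

The ACF is the biased *linear* (zero-padded, non-circular)
autocorrelation of the mean-removed window, computed through the power
spectral density and normalised by its lag-0 value, so features are
invariant to positive amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .ingest import EcgSegment, WindowGrid, slide_windows

__all__ = [
    "AcfMatrix",
    "FeatureVector",
    "DegenerateWindowError",
    "window_acf",
    "first_local_min_lag",
    "fmin",
    "mamp",
    "sim",
    "extract_features",
]

MAX_LAG_MS = 250.0
MAMP_LAG_MS = 35.0
SIM_LO_MS, SIM_HI_MS = 30.0, 115.0
FALLBACK_FMIN_MS = 250.0


class DegenerateWindowError(ValueError):
    """A window with zero variance (exact flat line) has no defined ACF."""


@dataclass
class AcfMatrix:
    """One normalised ACF row per sliding window, lags 0-250 ms."""

    rows: np.ndarray        # (n_windows, n_lags)
    lag_grid: np.ndarray    # ms, 0 .. 250 at 1000/fs spacing

    @property
    def n_windows(self) -> int:
        return self.rows.shape[0]


@dataclass
class FeatureVector:
    """The 3-D feature point of one segment."""

    fmin_ms: float
    mamp: float
    sim: float

    def as_array(self) -> np.ndarray:
        return np.array([self.fmin_ms, self.mamp, self.sim])


def lag_grid_ms(fs: float) -> np.ndarray:
    n_lags = int(np.floor(MAX_LAG_MS * fs / 1000.0)) + 1
    return np.arange(n_lags) * (1000.0 / fs)


def window_acf(window: np.ndarray, fs: float) -> np.ndarray:
    """Normalised linear ACF of one window on the 0-250 ms lag grid.

    Uses the Wiener-Khinchin route: the periodogram of the zero-padded,
    mean-removed window is inverted back to the lag domain, which equals
    the direct sum ``r(tau) = sum_t x_t x_{t+tau}`` up to rounding.
    """
    x = np.asarray(window, dtype=float)
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))   # pad to avoid circular wrap
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)
    if r[0] <= 0:
        raise DegenerateWindowError("zero-variance window has no ACF")
    n_lags = lag_grid_ms(fs).size
    return r[:n_lags] / r[0]


def first_local_min_lag(row: np.ndarray, lag_grid: np.ndarray) -> float:
    """Lag (ms) of the first interior local minimum; 250 ms fallback.

    The first index with a strict decrease from the left and a non-strict
    increase to the right wins, so plateaus resolve to their first
    sample.  A row with no interior local minimum (e.g. monotonically
    decreasing, as for a flat-line-like window) maps to the fallback.
    """
    row = np.asarray(row, dtype=float)
    for i in range(1, row.size - 1):
        if row[i] < row[i - 1] and row[i] <= row[i + 1]:
            return float(lag_grid[i])
    return FALLBACK_FMIN_MS


def segment_acf(seg: EcgSegment, grid: WindowGrid | None = None) -> AcfMatrix:
    """ACF matrix of all sliding windows; flat-line windows map to ACF = 1.

    The all-ones row encodes perfect self-similarity of a constant
    signal: it has no interior minimum (FMin hits the fallback) and value
    1 at 35 ms, matching the interpretation of both features for flat
    lines.
    """
    grid = grid or WindowGrid()
    lags = lag_grid_ms(seg.fs)
    rows = []
    for window in slide_windows(seg, grid):
        try:
            rows.append(window_acf(window, seg.fs))
        except DegenerateWindowError:
            rows.append(np.ones_like(lags))
    return AcfMatrix(rows=np.vstack(rows), lag_grid=lags)


def fmin(acf: AcfMatrix) -> float:
    """Minimum over windows of the first-local-minimum lag (ms)."""
    if acf.n_windows < 1:
        raise ValueError("ACF matrix has no rows")
    return min(first_local_min_lag(row, acf.lag_grid) for row in acf.rows)


def mamp(acf: AcfMatrix) -> float:
    """Signed maximum over windows of the ACF value at 35 ms lag.

    When 35 ms falls between grid lags (e.g. fs = 300 Hz) the value is
    linearly interpolated from the two neighbouring lags.
    """
    if acf.lag_grid[-1] < MAMP_LAG_MS:
        raise ValueError("lag grid does not span 35 ms")
    vals = [np.interp(MAMP_LAG_MS, acf.lag_grid, row) for row in acf.rows]
    return float(max(vals))


def sim(acf: AcfMatrix) -> float:
    """Maximum pairwise distance between window ACFs on lags 30-115 ms.

    Single-window segments have no pairs and return 0.
    """
    if acf.n_windows < 2:
        return 0.0
    mask = (acf.lag_grid >= SIM_LO_MS - 1e-9) & (acf.lag_grid <= SIM_HI_MS + 1e-9)
    return float(np.max(pdist(acf.rows[:, mask])))


def extract_features(seg: EcgSegment, grid: WindowGrid | None = None) -> FeatureVector:
    """Full per-segment feature extraction; deterministic."""
    acf = segment_acf(seg, grid)
    return FeatureVector(fmin_ms=fmin(acf), mamp=mamp(acf), sim=sim(acf))


# ------------------------------------------------------ feature table I/O

FEATURE_COLUMNS = ["segment_id", "fmin_ms", "mamp", "sim", "label"]


def feature_table(segments: list[EcgSegment],
                  grid: WindowGrid | None = None) -> "pandas.DataFrame":
    """Extract features for many segments into a tidy table."""
    import pandas as pd

    rows = []
    for seg in segments:
        fv = extract_features(seg, grid)
        rows.append((seg.segment_id, fv.fmin_ms, fv.mamp, fv.sim, seg.label))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_feature_csv(frame, path) -> None:
    frame.to_csv(path, index=False, columns=FEATURE_COLUMNS)


def read_feature_csv(path) -> "pandas.DataFrame":
    import pandas as pd

    frame = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"feature CSV {path} lacks columns {sorted(missing)}")
    return frame[FEATURE_COLUMNS]
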