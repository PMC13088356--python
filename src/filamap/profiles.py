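"""Line-profile extraction and correlation analysis of filament fragments.

For every fragment, per-channel intensity profiles are sampled along the
filament centerline by bilinear interpolation, averaged over a short
perpendicular line (``line_width``).  Periodicity is measured from the
normalized autocorrelogram of each profile: the lag of the first
qualifying local maximum ("first peak") estimates the local repeat
distance.  Colocalization between two channels is the zero-lag normalized
cross-correlation, restricted to fragments that carry signal in both
channels (double-labeled).

Estimator conventions
---------------------
Autocorrelation uses the biased Pearson-style estimator

    r(k) = Σ_i (x_i − x̄)(x_{i+k} − x̄) / Σ_i (x_i − x̄)²

with the mean and denominator taken over the full fragment, which
guarantees r(0) = 1 and |r| ≤ 1.  Detrending is mean subtraction only:
fragments are short (1.5 µm), so slow trends are treated as signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from filamap.detection import FilamentPath, FragmentSpec
from filamap.io_preprocess import ImageStack


@dataclass
class ProfileFragment:
    """Per-channel intensity vectors sampled along one fragment.

    All channels are sampled at identical positions with spacing ``step``
    (µm); vectors have length ``round(fragment_length/step) + 1``.
    """

    fragment_id: int
    step: float
    intensities: dict[str, np.ndarray]
    line_width: float

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.intensities.values()}
        if len(lengths) > 1:
            raise ValueError("all channel vectors must have identical length")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.intensities.values())))

    @property
    def channels(self) -> list[str]:
        return list(self.intensities)


@dataclass
class Correlogram:
    """Lag-indexed normalized correlation values for one fragment."""

    lags: np.ndarray  # µm; auto: 0..max_lag, cross: −max_lag..max_lag
    values: np.ndarray  # dimensionless, |r| ≤ 1
    kind: str  # "auto" | "cross"
    fragment_id: int
    channels: tuple[str, ...]

    @property
    def step(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclass(frozen=True)
class PeakRecord:
    """First qualifying autocorrelogram peak of one fragment/channel."""

    fragment_id: int
    channel: str
    first_peak_lag: float  # µm
    prominence: float


@dataclass(frozen=True)
class ColocalizationRecord:
    """Zero-lag cross-correlation of a double-labeled fragment."""

    fragment_id: int
    channel_pair: tuple[str, str]
    zero_lag_r: float


# ---------------------------------------------------------------------------
# Profile sampling


def sample_profile(
    stack: ImageStack,
    path: FilamentPath,
    fragment: FragmentSpec,
    step: float,
    line_width: float,
) -> ProfileFragment | None:
    """Sample per-channel line profiles along one fragment.

    At each arclength ``s = start + k·step`` the intensity is the mean of
    bilinear interpolations at points spanning ±``line_width``/2 along the
    local normal to the path; every channel is sampled at identical
    positions.  Returns ``None`` when any sample point falls outside the
    image (the caller records the rejection).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if stack.has_z:
        raise ValueError("sample_profile expects a 2D stack (max-project first)")
    if fragment.end_arclength > path.arclength + 1e-9:
        raise ValueError("fragment extends beyond the path arclength")
    n = int(round(fragment.length / step)) + 1
    s = fragment.start_arclength + step * np.arange(n)
    s = np.clip(s, 0.0, path.arclength)
    centers = path.position_at(s)  # (n, 2) in µm, (x, y)

    # unit tangent from arclength parametrization, normal = tangent rotated 90°
    tx = np.gradient(centers[:, 0], s)
    ty = np.gradient(centers[:, 1], s)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm

    if line_width > 0:
        m = max(2, int(round(line_width / (0.5 * stack.pixel_size))) + 1)
        offsets = np.linspace(-line_width / 2, line_width / 2, m)
    else:
        offsets = np.array([0.0])

    # physical (x, y) µm -> fractional array indices (row, col)
    xs = centers[:, 0][None, :] + offsets[:, None] * nx[None, :]
    ys = centers[:, 1][None, :] + offsets[:, None] * ny[None, :]
    cols = xs / stack.pixel_size - 0.5
    rows = ys / stack.pixel_size - 0.5

    h, w = stack.shape_yx
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() > h - 1
        or cols.max() > w - 1
    ):
        return None

    intensities = {}
    for ci, name in enumerate(stack.channel_names):
        vals = ndimage.map_coordinates(
            stack.pixels[ci], [rows.ravel(), cols.ravel()], order=1, mode="nearest"
        ).reshape(rows.shape)
        intensities[name] = vals.mean(axis=0)
    return ProfileFragment(
        fragment_id=fragment.fragment_id,
        step=step,
        intensities=intensities,
        line_width=line_width,
    )


# ---------------------------------------------------------------------------
# Correlograms


def acf_biased(x: np.ndarray, max_lag_samples: int) -> np.ndarray:
    """Biased normalized autocorrelation of a 1D series, lags 0..max_lag.

    r(k) = Σ_{i=0}^{n−k−1} (x_i − x̄)(x_{i+k} − x̄) / Σ_i (x_i − x̄)² with the
    full-series mean; r(0) = 1 and |r(k)| ≤ 1.
    """
    x = np.asarray(x, dtype=float)
    c = x - x.mean()
    denom = float(c @ c)
    if denom == 0:
        raise ZeroDivisionError("zero-variance profile")
    kmax = min(max_lag_samples, len(x) - 1)
    return np.array([float(c[: len(c) - k] @ c[k:]) / denom for k in range(kmax + 1)])


def ccf_normalized(a: np.ndarray, b: np.ndarray, max_lag_samples: int) -> np.ndarray:
    """Normalized cross-correlation for lags −max_lag..+max_lag.

    r_AB(k) = Σ_i (a_i − ā)(b_{i+k} − b̄) / sqrt(Σ(a−ā)² Σ(b−b̄)²), summed
    over the overlapping indices; satisfies r_AB(k) = r_BA(−k) exactly and
    r(0) = Pearson correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("profiles must have equal length")
    ca, cb = a - a.mean(), b - b.mean()
    denom = float(np.sqrt((ca @ ca) * (cb @ cb)))
    if denom == 0:
        raise ZeroDivisionError("zero-variance profile")
    n = len(a)
    kmax = min(max_lag_samples, n - 1)
    out = np.empty(2 * kmax + 1)
    for j, k in enumerate(range(-kmax, kmax + 1)):
        if k >= 0:
            out[j] = float(ca[: n - k] @ cb[k:]) / denom
        else:
            out[j] = float(ca[-k:] @ cb[: n + k]) / denom
    return out


def autocorrelate(
    fragment: ProfileFragment, channel: str, max_lag: float
) -> Correlogram | None:
    """Normalized autocorrelogram of one channel of a fragment.

    Returns ``None`` for zero-variance profiles (the caller records the
    exclusion).  ``max_lag`` (µm) must be shorter than the fragment.
    """
    x = fragment.intensities[channel]
    kmax = int(round(max_lag / fragment.step))
    if kmax >= len(x):
        raise ValueError("max_lag must be shorter than the fragment")
    try:
        vals = acf_biased(x, kmax)
    except ZeroDivisionError:
        return None
    lags = fragment.step * np.arange(len(vals))
    return Correlogram(lags, vals, "auto", fragment.fragment_id, (channel,))


def cross_correlate(
    fragment: ProfileFragment, channel_a: str, channel_b: str, max_lag: float
) -> Correlogram | None:
    """Normalized cross-correlogram between two channels of one fragment.

    Lags run from −max_lag to +max_lag; positive lag means channel B is
    shifted toward larger arclength relative to channel A.  Returns ``None``
    if either channel has zero variance.
    """
    a = fragment.intensities[channel_a]
    b = fragment.intensities[channel_b]
    kmax = int(round(max_lag / fragment.step))
    try:
        vals = ccf_normalized(a, b, kmax)
    except ZeroDivisionError:
        return None
    kmax = (len(vals) - 1) // 2
    lags = fragment.step * np.arange(-kmax, kmax + 1)
    return Correlogram(
        lags, vals, "cross", fragment.fragment_id, (channel_a, channel_b)
    )


# ---------------------------------------------------------------------------
# Peaks and labeling


def first_peak(
    corr: Correlogram, min_lag: float, min_prominence: float
) -> PeakRecord | None:
    """First qualifying local maximum of an autocorrelogram.

    Returns the smallest lag ≥ ``min_lag`` at which the correlogram has a
    local maximum (strictly greater than its neighbors; plateaus count once,
    at their leftmost sample) with topographic prominence ≥
    ``min_prominence``; ``None`` when no such peak exists.
    """
    if corr.kind != "auto":
        raise ValueError("first_peak expects an autocorrelogram")
    if min_lag < 2 * corr.step - 1e-12:
        raise ValueError("min_lag must be at least 2 sampling steps")
    idx, props = find_peaks(
        corr.values, prominence=min_prominence, plateau_size=1
    )
    left = props["left_edges"]
    for i in range(len(idx)):
        lag = corr.lags[left[i]]
        if lag >= min_lag - 1e-12:
            return PeakRecord(
                fragment_id=corr.fragment_id,
                channel=corr.channels[0],
                first_peak_lag=float(lag),
                prominence=float(props["prominences"][i]),
            )
    return None


def is_double_labeled(
    fragment: ProfileFragment,
    channels: tuple[str, str],
    snr_min: float = 3.0,
) -> bool:
    """Robust test that both channels of a fragment carry signal.

    A channel counts as labeled when (max − median) / (MAD·1.4826) ≥
    ``snr_min``; a zero-MAD channel is treated as unlabeled.  Fragments
    passing in both channels are the unit of colocalization analysis.
    """
    if snr_min <= 0:
        raise ValueError("snr_min must be > 0")
    for ch in channels:
        x = fragment.intensities[ch]
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * 1.4826
        if mad == 0 or (x.max() - med) / mad < snr_min:
            return False
    return True


def zero_lag_colocalization(
    fragment: ProfileFragment, channel_pair: tuple[str, str]
) -> ColocalizationRecord | None:
    """Zero-lag normalized cross-correlation (Pearson r) of two channels."""
    a = fragment.intensities[channel_pair[0]]
    b = fragment.intensities[channel_pair[1]]
    ca, cb = a - a.mean(), b - b.mean()
    denom = np.sqrt((ca @ ca) * (cb @ cb))
    if denom == 0:
        return None
    return ColocalizationRecord(
        fragment_id=fragment.fragment_id,
        channel_pair=channel_pair,
        zero_lag_r=float(ca @ cb / denom),
    )
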