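"""End-to-end orchestration: detection and analysis over one image.

``run_detection`` chains preprocessing → segmentation → skeletonization →
path extraction → fragmenting; ``run_analysis`` samples line profiles,
computes correlograms, collects first-peak lags, fits Gaussian mixtures
with AIC selection, and summarizes colocalization on double-labeled
fragments.  Excluded fragments (out-of-bounds samples, zero variance, no
qualifying peak) are tallied with machine-readable reason codes so that
manifest counts stay internally consistent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from filamap import correlation_stats as cs
from filamap import detection, profiles
from filamap.io_preprocess import ImageStack, align_channels, max_project, subtract_background


@dataclass
class DetectionParams:
    """Parameters of the filament-detection stage (lengths in µm)."""

    dna_channel: str = "DNA"
    background_radius: float = 0.5
    align: bool = False
    max_shift: float = 0.3
    segmentation: str = "otsu"
    threshold: float | None = None
    min_area_um2: float = detection.DEFAULT_MIN_AREA_UM2
    min_length: float = 1.5
    max_width: float = 0.5
    pruning_radius: float = 0.25
    fragment_length: float = 1.5


@dataclass
class AnalysisParams:
    """Parameters of the profile/correlation stage (lengths in µm).

    ``step`` defaults to half a pixel and ``line_width`` to 3 pixels when
    left unset; ``sd_floor`` of the mixture fit defaults to the sampling
    step.
    """

    channels: list[str] | None = None  # None → all non-DNA channels
    dna_channel: str = "DNA"
    step: float | None = None
    line_width: float | None = None
    max_lag: float = 0.75
    min_lag: float = 0.05
    min_prominence: float = 0.05
    snr_min: float = 3.0
    bin_width: float = cs.DEFAULT_BIN_WIDTH
    lag_range: tuple[float, float] = (0.0, 0.75)
    seed: int = 0

    def resolved_step(self, pixel_size: float) -> float:
        return self.step if self.step is not None else pixel_size / 2

    def resolved_line_width(self, pixel_size: float) -> float:
        return self.line_width if self.line_width is not None else 3 * pixel_size


@dataclass
class DetectionResult:
    mask: np.ndarray
    paths: list[detection.FilamentPath]
    fragments: list[detection.FragmentSpec]
    stack: ImageStack  # preprocessed


@dataclass
class AnalysisResult:
    profiles: list[profiles.ProfileFragment]
    peaks: dict[str, list[profiles.PeakRecord]]
    histograms: dict[str, cs.PeriodicityHistogram]
    fits: dict[str, dict[str, cs.GaussianMixtureFit]]
    colocalization: dict[tuple[str, str], dict]
    exclusions: Counter = field(default_factory=Counter)
    n_fragments_total: int = 0

    def peak_fraction(self, channel: str) -> float:
        """Fraction of sampled fragments with a qualifying first peak."""
        n_prof = len(self.profiles)
        return len(self.peaks.get(channel, [])) / n_prof if n_prof else 0.0


def preprocess(stack: ImageStack, params: DetectionParams) -> ImageStack:
    """Alignment (optional) → max projection → background correction."""
    if stack.has_z:
        stack = max_project(stack)
    if params.align and stack.n_channels >= 2:
        stack = align_channels(stack, params.dna_channel, params.max_shift)
    if params.background_radius > 0:
        stack = subtract_background(stack, params.background_radius)
    return stack


def run_detection(stack: ImageStack, params: DetectionParams) -> DetectionResult:
    """Detect single thin filaments in the DNA channel and fragment them."""
    pre = preprocess(stack, params)
    mask = detection.segment_dna(
        pre,
        params.dna_channel,
        method=params.segmentation,
        threshold=params.threshold,
        min_area_um2=params.min_area_um2,
    )
    skel = detection.skeletonize_mask(mask, pre.pixel_size)
    paths = detection.extract_paths(
        skel,
        min_length=params.min_length,
        mask=mask,
        max_width=params.max_width,
        pruning_radius=params.pruning_radius,
    )
    fragments = detection.fragment_paths(paths, params.fragment_length)
    return DetectionResult(mask=mask, paths=paths, fragments=fragments, stack=pre)


def run_analysis(
    det: DetectionResult, params: AnalysisParams
) -> AnalysisResult:
    """Profile sampling, correlograms, peak statistics, colocalization."""
    stack = det.stack
    step = params.resolved_step(stack.pixel_size)
    line_width = params.resolved_line_width(stack.pixel_size)
    channels = params.channels
    if channels is None:
        channels = [c for c in stack.channel_names if c != params.dna_channel]

    path_by_id = {p.path_id: p for p in det.paths}
    exclusions: Counter = Counter()
    frags: list[profiles.ProfileFragment] = []
    for spec in det.fragments:
        prof = profiles.sample_profile(
            stack, path_by_id[spec.path_id], spec, step=step, line_width=line_width
        )
        if prof is None:
            exclusions["out_of_bounds"] += 1
            continue
        frags.append(prof)

    peaks: dict[str, list[profiles.PeakRecord]] = {c: [] for c in channels}
    for prof in frags:
        for ch in channels:
            corr = profiles.autocorrelate(prof, ch, params.max_lag)
            if corr is None:
                exclusions[f"zero_variance:{ch}"] += 1
                continue
            rec = profiles.first_peak(corr, params.min_lag, params.min_prominence)
            if rec is None:
                exclusions[f"no_peak:{ch}"] += 1
                continue
            peaks[ch].append(rec)

    histograms: dict[str, cs.PeriodicityHistogram] = {}
    fits: dict[str, dict[str, cs.GaussianMixtureFit]] = {}
    for ch in channels:
        histograms[ch] = cs.build_histogram(
            peaks[ch],
            bin_width=params.bin_width,
            lag_range=params.lag_range,
            n_fragments_total=len(frags),
        )
        lags = np.array([p.first_peak_lag for p in peaks[ch]])
        ch_fits: dict[str, cs.GaussianMixtureFit] = {}
        if len(lags) >= 10:
            ch_fits["K1"] = cs.fit_gaussian_mixture(
                lags, K=1, seed=params.seed, sd_floor=step
            )
        if len(lags) >= 20:
            ch_fits["K2"] = cs.fit_gaussian_mixture(
                lags, K=2, seed=params.seed, sd_floor=step
            )
        if "K1" in ch_fits and "K2" in ch_fits:
            ch_fits["selected"] = cs.select_model_aic(ch_fits["K1"], ch_fits["K2"])
        elif "K1" in ch_fits:
            ch_fits["selected"] = ch_fits["K1"]
        fits[ch] = ch_fits

    colocalization: dict[tuple[str, str], dict] = {}
    for i in range(len(channels)):
        for j in range(i + 1, len(channels)):
            pair = (channels[i], channels[j])
            records = []
            for prof in frags:
                if not profiles.is_double_labeled(prof, pair, params.snr_min):
                    continue
                rec = profiles.zero_lag_colocalization(prof, pair)
                if rec is not None:
                    records.append(rec)
            summary, fraction = cs.summarize_colocalization(records, len(frags))
            colocalization[pair] = {
                "records": records,
                "summary": summary,
                "fraction": fraction,
            }

    return AnalysisResult(
        profiles=frags,
        peaks=peaks,
        histograms=histograms,
        fits=fits,
        colocalization=colocalization,
        exclusions=exclusions,
        n_fragments_total=len(det.fragments),
    )


# ---------------------------------------------------------------------------
# Tabular export helpers (CSV formats of the tool's outputs)


def paths_to_frame(paths: list[detection.FilamentPath]) -> pd.DataFrame:
    rows = []
    for p in paths:
        for i, ((x, y), s) in enumerate(zip(p.points, p.cumulative_arclength)):
            rows.append(
                {"path_id": p.path_id, "point_index": i, "x_um": x, "y_um": y, "arclength_um": s}
            )
    return pd.DataFrame(rows, columns=["path_id", "point_index", "x_um", "y_um", "arclength_um"])


def fragments_to_frame(frags: list[detection.FragmentSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fragment_id": f.fragment_id,
                "path_id": f.path_id,
                "start_um": f.start_arclength,
                "end_um": f.end_arclength,
            }
            for f in frags
        ],
        columns=["fragment_id", "path_id", "start_um", "end_um"],
    )


def profiles_to_frame(profs: list[profiles.ProfileFragment]) -> pd.DataFrame:
    rows = []
    for p in profs:
        pos = p.step * np.arange(p.n_samples)
        for ch, vals in p.intensities.items():
            for s, v in zip(pos, vals):
                rows.append(
                    {"fragment_id": p.fragment_id, "channel": ch, "position_um": s, "intensity": v}
                )
    return pd.DataFrame(rows, columns=["fragment_id", "channel", "position_um", "intensity"])


def peaks_to_frame(peaks: dict[str, list[profiles.PeakRecord]]) -> pd.DataFrame:
    rows = [
        {
            "fragment_id": r.fragment_id,
            "channel": r.channel,
            "first_peak_um": r.first_peak_lag,
            "prominence": r.prominence,
        }
        for recs in peaks.values()
        for r in recs
    ]
    return pd.DataFrame(rows, columns=["fragment_id", "channel", "first_peak_um", "prominence"])


def fit_to_dict(fit: cs.GaussianMixtureFit) -> dict:
    return {
        "K": fit.K,
        "means_um": [float(m) for m in fit.means],
        "sds_um": [float(s) for s in fit.sds],
        "weights": [float(w) for w in fit.weights],
        "logL": fit.log_likelihood,
        "AIC": fit.aic,
        "n": fit.n,
        "converged": fit.converged,
    }
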