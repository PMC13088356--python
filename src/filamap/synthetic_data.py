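"""Ground-truthed synthetic images of filaments with labeled puncta.

Emulates the study conditions of multichannel super-resolution imaging of
DNA filaments: a continuous DNA-backbone channel plus protein channels
whose puncta sit on the filament either periodically (spacing ``d`` with
Gaussian jitter and sub-unity labeling efficiency ``p``) or as a Poisson
process at matched mean density.  Images are blurred with an isotropic
Gaussian PSF (sigma = FWHM/2.3548) at modality-matched scales and degraded
with Poisson shot noise, Gaussian read noise and diffuse background.

Modality presets (PSF FWHM / pixel size) follow the lateral resolutions of
the three imaging regimes: SIM ~100 nm, STED ~60 nm, SMLM ~25 nm, with
pixel sizes 32/20/10 nm.

Sub-unity labeling is the mechanism behind apparent bimodal periodicity:
when a fraction 1 − p of sites is dark, the nearest labeled neighbor is
often 2d away, so the first-peak distribution gains a mode at twice the
true spacing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from filamap.io_preprocess import ImageStack, write_stack

_FWHM_TO_SIGMA = 2 * np.sqrt(2 * np.log(2))  # 2.3548

MODALITY_PRESETS: dict[str, dict[str, float]] = {
    "sim": {"psf_fwhm": 0.100, "pixel_size": 0.032},
    "sted": {"psf_fwhm": 0.060, "pixel_size": 0.020},
    "smlm": {"psf_fwhm": 0.025, "pixel_size": 0.010},
}


class PlacementError(RuntimeError):
    """A filament could not be placed inside the image margin."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic filament image generator.

    Physical quantities are in µm unless noted.  ``curvature`` is the
    smoothing scale of the filament backbone (``inf`` gives straight
    filaments).  ``punctum_amplitude`` is the expected photon count per
    punctum; ``backbone_intensity`` is photons per µm of filament.
    """

    image_size: int = 512
    pixel_size: float = 0.032
    n_filaments: int = 5
    filament_length: float = 12.0
    curvature: float = 3.0
    backbone_intensity: float = 2000.0
    spacing_d: float = 0.37
    spacing_jitter: float = 0.03
    labeling_efficiency: float = 0.9
    punctum_amplitude: float = 800.0
    punctum_cv: float = 0.2
    placement: str = "periodic"  # "periodic" | "poisson"
    psf_fwhm: float = 0.100
    background: float = 5.0
    read_noise: float = 1.0
    shot_noise: bool = True
    n_protein_channels: int = 1
    colocalized: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_d <= 0:
            raise ValueError("spacing_d must be > 0")
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling_efficiency must be in (0, 1]")
        if self.psf_fwhm <= 0:
            raise ValueError("psf_fwhm must be > 0")
        if self.placement not in ("periodic", "poisson"):
            raise ValueError(f"unknown placement {self.placement!r}")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SimulationConfig":
        """Config with PSF FWHM and pixel size of a modality preset."""
        if name not in MODALITY_PRESETS:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(MODALITY_PRESETS)}"
            )
        params = dict(MODALITY_PRESETS[name])
        params.update(overrides)
        return cls(**params)

    @property
    def psf_sigma(self) -> float:
        return self.psf_fwhm / _FWHM_TO_SIGMA

    @property
    def channel_names(self) -> list[str]:
        return ["DNA"] + [f"protein{i + 1}" for i in range(self.n_protein_channels)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Generator-side truth for one simulated image."""

    paths: list[np.ndarray]  # dense (N, 2) (x, y) µm per filament
    puncta: pd.DataFrame  # filament_id, channel, punctum_index, arclength_um, x_um, y_um
    config: dict = field(default_factory=dict)


def _arclength(points: np.ndarray) -> np.ndarray:
    steps = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(steps)])


def make_filament(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Generate one smooth open filament path inside the image.

    A random-walk of headings is smoothed at the ``curvature`` scale and
    resampled to steps of at most half a pixel; ``curvature = inf`` gives a
    straight segment.  The path keeps a margin of 3 PSF FWHM from the image
    border; placement is retried up to 100 times.
    """
    margin = 3 * config.psf_fwhm
    extent = config.image_size * config.pixel_size
    avail = extent - 2 * margin
    if avail <= 0:
        raise PlacementError("image smaller than twice the placement margin")
    L = config.filament_length
    ds = 0.4 * config.pixel_size

    for _ in range(100):
        if np.isinf(config.curvature):
            theta = rng.uniform(0, 2 * np.pi)
            n = max(2, int(np.ceil(L / ds)) + 1)
            s = np.linspace(0, L, n)
            pts = np.column_stack([s * np.cos(theta), s * np.sin(theta)])
        else:
            h = max(ds, config.curvature / 10)
            n_ctrl = max(4, int(np.ceil(L / h)) + 1)
            dtheta = rng.normal(0, np.sqrt(h / config.curvature), size=n_ctrl - 1)
            theta = rng.uniform(0, 2 * np.pi) + np.concatenate([[0], np.cumsum(dtheta)])
            steps = h * np.column_stack([np.cos(theta), np.sin(theta)])
            pts = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
            sigma_ctrl = config.curvature / h
            pts = np.column_stack(
                [
                    ndimage.gaussian_filter1d(pts[:, 0], sigma_ctrl, mode="nearest"),
                    ndimage.gaussian_filter1d(pts[:, 1], sigma_ctrl, mode="nearest"),
                ]
            )
            cum = _arclength(pts)
            if cum[-1] < L * 0.2:  # smoothing collapsed the walk; retry
                continue
            # resample to the requested arclength at fine, even steps
            target = np.arange(0, min(L, cum[-1]) + ds / 2, ds)
            target = target[target <= cum[-1]]
            pts = np.column_stack(
                [
                    np.interp(target, cum, pts[:, 0]),
                    np.interp(target, cum, pts[:, 1]),
                ]
            )
        span = pts.max(axis=0) - pts.min(axis=0)
        if np.any(span > avail):
            continue
        offset = margin - pts.min(axis=0) + rng.uniform(0, avail - span, size=2)
        return pts + offset
    raise PlacementError(
        f"could not place a {L} µm filament in a {extent:.1f} µm image "
        f"with margin {margin:.2f} µm after 100 tries"
    )


def place_puncta(
    path: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place protein puncta on a filament path.

    Periodic mode: positions ``s0 + k·d + ε_k`` with ``s0 ~ U(0, d)``
    (fragment boundaries are therefore not phase-locked to puncta),
    ``ε_k ~ N(0, jitter)``, each retained with probability
    ``labeling_efficiency``.  Poisson mode: a Poisson number of uniform
    positions at the same mean density ``p/d``.

    Returns (arclengths, (x, y) coordinates), both sorted by arclength.
    """
    cum = _arclength(path)
    L = cum[-1]
    if L <= config.spacing_d:
        raise ValueError("path shorter than one punctum spacing")
    d, p = config.spacing_d, config.labeling_efficiency
    if config.placement == "periodic":
        s0 = rng.uniform(0, d)
        base = s0 + d * np.arange(int(np.floor((L - s0) / d)) + 1)
        s = base + rng.normal(0, config.spacing_jitter, size=base.size)
        keep = rng.random(base.size) < p
        s = np.sort(s[keep & (s >= 0) & (s <= L)])
    else:
        lam = p * L / d
        count = rng.poisson(lam)
        s = np.sort(rng.uniform(0, L, size=count))
    x = np.interp(s, cum, path[:, 0])
    y = np.interp(s, cum, path[:, 1])
    return s, np.column_stack([x, y])


def _splat_bilinear(
    canvas: np.ndarray, xy_um: np.ndarray, amplitudes: np.ndarray, pixel_size: float
) -> None:
    """Deposit point masses onto the pixel grid with bilinear weights."""
    if len(xy_um) == 0:
        return
    cols = xy_um[:, 0] / pixel_size - 0.5
    rows = xy_um[:, 1] / pixel_size - 0.5
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    h, w = canvas.shape
    for dr, dc, wgt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(canvas, (rr[ok], cc[ok]), amplitudes[ok] * wgt[ok])


def render_image(
    paths: list[np.ndarray],
    puncta: dict[str, list[tuple[np.ndarray, np.ndarray]]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ImageStack:
    """Render filaments and puncta into a noisy multichannel image.

    The DNA channel is the line integral of ``backbone_intensity`` along
    each path; protein channels are sums of punctum point masses whose
    amplitudes vary with coefficient of variation ``punctum_cv``.  All
    channels are convolved with the Gaussian PSF, then background, Poisson
    shot noise (if enabled) and Gaussian read noise are applied; negative
    values are clipped at zero.
    """
    n = config.image_size
    names = config.channel_names
    pixels = np.zeros((len(names), n, n))

    ds = None
    for path in paths:
        cum = _arclength(path)
        step = np.diff(cum)
        ds = float(np.median(step)) if step.size else 0.0
        amps = np.full(len(path), config.backbone_intensity * ds)
        _splat_bilinear(pixels[0], path, amps, config.pixel_size)

    for ci, name in enumerate(names[1:], start=1):
        for _s, xy in puncta.get(name, []):
            amp = config.punctum_amplitude * np.clip(
                1 + config.punctum_cv * rng.standard_normal(len(xy)), 0.05, None
            )
            _splat_bilinear(pixels[ci], xy, amp, config.pixel_size)

    sigma_px = config.psf_sigma / config.pixel_size
    for ci in range(len(names)):
        if sigma_px > 0:
            pixels[ci] = ndimage.gaussian_filter(pixels[ci], sigma_px, mode="constant")
        signal = pixels[ci] + config.background
        if config.shot_noise:
            signal = rng.poisson(np.clip(signal, 0, None)).astype(float)
        if config.read_noise > 0:
            signal = signal + rng.normal(0, config.read_noise, size=signal.shape)
        pixels[ci] = np.clip(signal, 0, None)

    return ImageStack(
        pixels,
        config.pixel_size,
        names,
        metadata={"seed": config.seed, "synthetic": True},
    )


def simulate_stack(
    config: SimulationConfig,
) -> tuple[ImageStack, GroundTruth]:
    """Generate filaments, puncta, and the rendered image in one call.

    All randomness flows from ``config.seed``; identical configs give
    bitwise-identical output.  When ``colocalized`` is true, all protein
    channels share the same punctum positions (amplitudes still vary
    independently); otherwise each channel draws its own.
    """
    rng = np.random.default_rng(config.seed)
    paths = [make_filament(config, rng) for _ in range(config.n_filaments)]
    protein_names = config.channel_names[1:]
    puncta: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        name: [] for name in protein_names
    }
    records = []
    for fid, path in enumerate(paths):
        shared = place_puncta(path, config, rng) if config.colocalized else None
        for name in protein_names:
            s, xy = shared if shared is not None else place_puncta(path, config, rng)
            puncta[name].append((s, xy))
            for j in range(len(s)):
                records.append(
                    {
                        "filament_id": fid,
                        "channel": name,
                        "punctum_index": j,
                        "arclength_um": s[j],
                        "x_um": xy[j, 0],
                        "y_um": xy[j, 1],
                    }
                )
    stack = render_image(paths, puncta, config, rng)
    truth = GroundTruth(
        paths=paths,
        puncta=pd.DataFrame(
            records,
            columns=[
                "filament_id",
                "channel",
                "punctum_index",
                "arclength_um",
                "x_um",
                "y_um",
            ],
        ),
        config=config.to_dict(),
    )
    return stack, truth


def simulate_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate one dataset and write image, ground truth and config echo.

    Writes ``image_seed<seed>.tif``, ``ground_truth_seed<seed>.csv`` and
    ``config_seed<seed>.yaml`` into ``out_dir``; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack, truth = simulate_stack(config)
    tag = f"seed{config.seed}"
    files = {
        "image": out_dir / f"image_{tag}.tif",
        "ground_truth": out_dir / f"ground_truth_{tag}.csv",
        "config": out_dir / f"config_{tag}.yaml",
    }
    write_stack(stack, files["image"])
    truth.puncta.to_csv(files["ground_truth"], index=False)
    with open(files["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return files
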