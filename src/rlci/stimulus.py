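"""Dynamic 1-D noise stimuli with a slowly ramping luminance target.

The stimulus is the front door of the whole pipeline: two adjacent
4.8 x 4.8 deg fields of 16 vertical bars whose contrasts refresh at
30 Hz as independent Gaussian noise (RMS contrast 0.1).  One field
additionally carries a target whose log10 contrast ramps linearly,
``log10 C_target(t) = min(alpha * t - 3, 0)`` with ``t`` the frame
number (33.3 ms per unit), so the target starts at contrast 1e-3 and
saturates at full contrast after ``3 / alpha`` frames.

Bar contrasts are the native representation; :func:`rasterize_to_samples`
expands them onto the 0.04-deg pixel grid on which the observer model's
spatial filter is parameterised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

#: Duration of one noise frame in milliseconds (30 Hz refresh).
FRAME_MS = 1000.0 / 30.0

Side = str  # "left" | "right"


@dataclass(frozen=True)
class StimulusConfig:
    """Geometry and statistics of the dynamic-noise stimulus.

    Defaults reproduce the detection display: 16 bars of 0.3 deg span a
    4.8 deg field sampled at 25 px/deg, noise refreshes at 30 Hz for
    8000 ms, and the target contrast ramps at ``alpha`` log10-units per
    frame on the two central bars.
    """

    n_bars: int = 16
    bar_width_deg: float = 0.3
    field_size_deg: float = 4.8
    noise_rms: float = 0.1
    frame_rate_hz: float = 30.0
    duration_ms: float = 8000.0
    alpha: float = 0.05
    mean_luminance: float = 88.9
    samples_per_degree: float = 25.0
    target_bars: Tuple[int, ...] = (7, 8)

    def __post_init__(self) -> None:
        if self.n_bars <= 0 or self.bar_width_deg <= 0:
            raise ValueError("n_bars and bar_width_deg must be positive")
        if not np.isclose(self.n_bars * self.bar_width_deg, self.field_size_deg):
            raise ValueError(
                "n_bars * bar_width_deg must equal field_size_deg "
                f"({self.n_bars} * {self.bar_width_deg} != {self.field_size_deg})"
            )
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.noise_rms <= 0:
            raise ValueError("noise_rms must be positive")
        if self.frame_rate_hz <= 0 or self.duration_ms <= 0:
            raise ValueError("frame_rate_hz and duration_ms must be positive")
        for b in self.target_bars:
            if not 0 <= b < self.n_bars:
                raise ValueError(f"target bar index {b} outside [0, {self.n_bars})")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms * self.frame_rate_hz / 1000.0))

    @property
    def n_samples(self) -> int:
        """Spatial samples per field on the pixel grid (4.8 deg * 25 px/deg = 120)."""
        return int(round(self.field_size_deg * self.samples_per_degree))

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    def with_alpha(self, alpha: float) -> "StimulusConfig":
        return replace(self, alpha=alpha)


@dataclass
class StimulusMovie:
    """One trial's stimulus: bar-contrast matrices for both fields.

    ``contrast_*`` are the displayed (noise + target, clipped) contrasts;
    ``noise_*`` retain the pre-increment, pre-clip noise record that the
    classification-image analysis correlates with responses.
    """

    contrast_left: np.ndarray
    contrast_right: np.ndarray
    noise_left: np.ndarray
    noise_right: np.ndarray
    target_side: Side
    alpha: float
    seed: int
    config: StimulusConfig = field(default_factory=StimulusConfig)

    def noise_for(self, side: Side) -> np.ndarray:
        return self.noise_left if side == "left" else self.noise_right

    def mirrored(self) -> "StimulusMovie":
        """Swap the two fields and reverse bar order within each field."""
        other = "right" if self.target_side == "left" else "left"
        return StimulusMovie(
            contrast_left=self.contrast_right[::-1].copy(),
            contrast_right=self.contrast_left[::-1].copy(),
            noise_left=self.noise_right[::-1].copy(),
            noise_right=self.noise_left[::-1].copy(),
            target_side=other,
            alpha=self.alpha,
            seed=self.seed,
            config=self.config,
        )


def target_contrast(t, alpha: float):
    """Target Michelson contrast at frame ``t``: ``10 ** min(alpha*t - 3, 0)``.

    Accepts scalars or arrays; monotone nondecreasing in ``t`` and equal
    to 1 for every ``t >= 3 / alpha``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("frame index t must be nonnegative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out = 10.0 ** np.minimum(alpha * t - 3.0, 0.0)
    return out if out.ndim else float(out)


def generate_noise_field(config: StimulusConfig, seed) -> np.ndarray:
    """Draw one field of i.i.d. Gaussian bar noise, clipped to [-1, 1].

    Returns an ``(n_bars, n_frames)`` array with mean 0 and standard
    deviation ``config.noise_rms`` (clipping at +-1 is astronomically
    rare at noise_rms = 0.1 and never fires in practice).
    """
    rng = np.random.default_rng(seed)
    field_ = rng.normal(0.0, config.noise_rms, size=(config.n_bars, config.n_frames))
    return np.clip(field_, -1.0, 1.0)


def compose_trial_stimulus(config: StimulusConfig, target_side: Side, seed) -> StimulusMovie:
    """Build one trial: two independent noise fields plus the target ramp.

    The target increment ``target_contrast(t, alpha)`` is added to the
    ``config.target_bars`` of the designated field only, and the combined
    contrast is clipped to [-1, +1].  The noise-only record is retained
    unclipped and unchanged, so swapping ``target_side`` with the same
    seed leaves the noise identical and moves only the increment.
    """
    if target_side not in ("left", "right"):
        raise ValueError(f"target_side must be 'left' or 'right', got {target_side!r}")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, config.noise_rms, size=(2, config.n_bars, config.n_frames))
    np.clip(noise, -1.0, 1.0, out=noise)
    noise_left, noise_right = noise[0], noise[1]

    ramp = target_contrast(np.arange(config.n_frames), config.alpha)
    increment = np.zeros((config.n_bars, config.n_frames))
    increment[list(config.target_bars), :] = ramp

    contrast_left = noise_left.copy()
    contrast_right = noise_right.copy()
    if target_side == "left":
        contrast_left = np.clip(noise_left + increment, -1.0, 1.0)
    else:
        contrast_right = np.clip(noise_right + increment, -1.0, 1.0)

    seed_int = int(seed) if np.isscalar(seed) else -1
    return StimulusMovie(
        contrast_left=contrast_left,
        contrast_right=contrast_right,
        noise_left=noise_left,
        noise_right=noise_right,
        target_side=target_side,
        alpha=config.alpha,
        seed=seed_int,
        config=config,
    )


def bar_of_sample(i, config: StimulusConfig | None = None) -> np.ndarray:
    """Map pixel-sample index to bar index: ``floor(i / (n_samples / n_bars))``."""
    cfg = config or StimulusConfig()
    ratio = cfg.n_samples / cfg.n_bars  # 7.5 samples per bar at defaults
    return np.floor(np.asarray(i) / ratio).astype(int)


def rasterize_field(bar_field: np.ndarray, config: StimulusConfig | None = None) -> np.ndarray:
    """Expand an ``(n_bars, n_frames)`` bar matrix to pixel samples.

    Sample ``i`` takes the contrast of bar ``floor(i / 7.5)`` (alternating
    7/8-sample bar widths at the default geometry); averaging the samples
    within a bar returns the bar contrast exactly.
    """
    cfg = config or StimulusConfig()
    if bar_field.shape[0] != cfg.n_bars:
        raise ValueError(
            f"field has {bar_field.shape[0]} bars, config expects {cfg.n_bars}"
        )
    idx = bar_of_sample(np.arange(cfg.n_samples), cfg)
    return bar_field[idx, :]


def rasterize_to_samples(movie: StimulusMovie) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel-sample contrast matrices ``(left, right)``, each (n_samples, n_frames)."""
    cfg = movie.config
    return (
        rasterize_field(movie.contrast_left, cfg),
        rasterize_field(movie.contrast_right, cfg),
    )
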