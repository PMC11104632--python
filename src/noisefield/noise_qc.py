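"""Quantitative homogeneity and luminance QC of noise frame sequences.

Three layers of checks are provided, mirroring how a generated stimulus
is validated before clinical use:

* per-frame luminance histograms and moments (a valid five-tone frame
  has exactly five occupied bins and mean ~127.4, population SD ~90.1);
* sequence-level aggregation — per-frame means/SDs, per-level pixel
  counts, and a one-way ANOVA checking that the palette levels appear
  in equal numbers across frames;
* a stripe statistic on the temporally averaged image that detects the
  column/row banding produced by lattice-structured generators (LCGs)
  but not by xorshift.  Averaging emulates a long-exposure photograph
  of the running stimulus, which is how the artifact becomes visible —
  individual stills look random either way.

The module is agnostic to frame origin: any stack of equally sized
8-bit grayscale frames can be analysed, including captured analog
noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, InputError
from .stimulus import GrayPalette, NoiseFrame


@dataclass
class LuminanceHistogram:
    """256-bin gray-value histogram of one frame with its moments.

    ``mean``/``sd`` are population statistics over all pixels (the
    convention used by image-analysis tools for a single image).
    """

    counts: np.ndarray  # length 256
    n_pixels: int
    mean: float
    sd: float

    @property
    def occupied_levels(self) -> np.ndarray:
        return np.flatnonzero(self.counts)


@dataclass
class SequenceSummary:
    """Aggregate statistics of a frame sequence.

    ``sd_of_means`` uses the sample (n-1) convention, matching the
    "mean +/- SD over 60 images" style of reporting; within-frame SDs
    are population SDs.
    """

    per_frame_means: np.ndarray
    per_frame_sds: np.ndarray
    per_level_counts: np.ndarray  # (n_frames, n_levels)
    levels: Tuple[int, ...]
    n_pixels: int
    mean_of_means: float
    sd_of_means: float
    per_level_count_mean: np.ndarray
    per_level_count_sd: np.ndarray


def luminance_histogram(frame: NoiseFrame) -> LuminanceHistogram:
    """Exact 256-bin histogram plus population mean/SD of a frame."""
    pixels = frame.pixels
    if pixels.size == 0:
        raise InputError("cannot histogram an empty frame")
    counts = np.bincount(pixels.ravel(), minlength=256)
    return LuminanceHistogram(
        counts=counts,
        n_pixels=int(pixels.size),
        mean=float(pixels.mean()),
        sd=float(pixels.std(ddof=0)),
    )


def sequence_summary(frames: Sequence[NoiseFrame],
                     palette: GrayPalette) -> SequenceSummary:
    """Per-frame and across-frame luminance statistics of a sequence."""
    if len(frames) < 2:
        raise InputError("sequence_summary needs at least 2 frames")
    shape = frames[0].pixels.shape
    for f in frames:
        if f.pixels.shape != shape:
            raise InputError("frames differ in dimensions")
    levels = tuple(int(v) for v in palette.levels)
    means = np.array([f.pixels.mean() for f in frames])
    sds = np.array([f.pixels.std(ddof=0) for f in frames])
    counts = np.empty((len(frames), len(levels)), dtype=np.int64)
    for i, f in enumerate(frames):
        binned = np.bincount(f.pixels.ravel(), minlength=256)
        counts[i] = [binned[v] for v in levels]
    return SequenceSummary(
        per_frame_means=means,
        per_frame_sds=sds,
        per_level_counts=counts,
        levels=levels,
        n_pixels=int(frames[0].pixels.size),
        mean_of_means=float(means.mean()),
        sd_of_means=float(means.std(ddof=1)),
        per_level_count_mean=counts.mean(axis=0),
        per_level_count_sd=counts.std(axis=0, ddof=1),
    )


def level_balance_anova(per_level_counts: np.ndarray) -> Tuple[float, float]:
    """One-way ANOVA of per-frame pixel counts across palette levels.

    Levels are the groups, frames the replicates; a non-significant
    result indicates the levels are drawn in equal proportion.  Returns
    ``(F, p)``; an all-equal matrix yields ``(0.0, 1.0)``.
    """
    counts = np.asarray(per_level_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ConfigError("need >=2 frames and >=2 levels for the ANOVA")
    groups = [counts[:, j] for j in range(counts.shape[1])]
    grand = counts.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    if ss_between == 0.0:
        return 0.0, 1.0
    f_stat, p = sps.f_oneway(*groups)
    return float(f_stat), float(p)


def exposure_frames(shutter_s: float, fps: float) -> int:
    """Number of frames integrated by a camera exposure (rounded)."""
    if shutter_s <= 0 or fps <= 0:
        raise ConfigError("shutter and fps must be positive")
    return int(round(shutter_s * fps))


def temporal_average(frames: Sequence[NoiseFrame]) -> np.ndarray:
    """Per-pixel arithmetic mean over a frame stack (float image).

    A linear stand-in for a long-exposure photograph of the running
    stimulus; camera nonlinearity is ignored, which does not affect the
    stripe artifact the average is meant to reveal.
    """
    if len(frames) == 0:
        raise InputError("temporal_average needs at least one frame")
    stack = np.stack([f.pixels.astype(np.float64) for f in frames])
    return stack.mean(axis=0)


@dataclass
class StripeResult:
    """Outcome of the stripe permutation test.

    ``z``/``p`` refer to the more extreme of the column-wise and
    row-wise statistics; per-axis values are retained for inspection.
    """

    z: float
    p: float
    axis: str  # "columns" or "rows"
    z_columns: float
    z_rows: float
    p_columns: float
    p_rows: float
    statistic_columns: float
    statistic_rows: float


def _perm_z_p(observed: float, null: np.ndarray) -> Tuple[float, float]:
    mu = null.mean()
    sd = null.std(ddof=1)
    z = 0.0 if sd == 0 else (observed - mu) / sd
    # two-sided permutation p on absolute deviation from the null mean,
    # with the +1 correction so p is never 0
    dev = abs(observed - mu)
    extreme = int(np.sum(np.abs(null - mu) >= dev - 1e-12))
    p = (1 + extreme) / (1 + null.size)
    return float(z), float(p)


def stripe_score(avg_image: np.ndarray, dot_px: int,
                 n_permutations: int = 199, seed: int = 0) -> StripeResult:
    """Permutation test for dot-column (and dot-row) banding.

    The image is reduced to its dot-cell means (full cells only); the
    statistic is the variance of the per-column means of that cell
    matrix (and, symmetrically, per-row).  The null distribution comes
    from permuting the cell values, which preserves the marginal cell
    distribution while destroying any spatial arrangement.  The
    reported ``z``/``p`` belong to whichever axis is more extreme.
    """
    if n_permutations < 99:
        raise ConfigError("use at least 99 permutations")
    img = np.asarray(avg_image, dtype=np.float64)
    if img.ndim != 2:
        raise InputError("avg_image must be 2-D")
    d = int(dot_px)
    nr, nc = img.shape[0] // d, img.shape[1] // d
    if nr < 2 or nc < 2:
        raise ConfigError("image smaller than 2x2 dot cells")
    cells = img[: nr * d, : nc * d].reshape(nr, d, nc, d).mean(axis=(1, 3))

    def col_stat(m: np.ndarray) -> float:
        return float(m.mean(axis=0).var())

    def row_stat(m: np.ndarray) -> float:
        return float(m.mean(axis=1).var())

    obs_c, obs_r = col_stat(cells), row_stat(cells)
    rng = np.random.default_rng(seed)
    flat = cells.ravel().copy()
    null_c = np.empty(n_permutations)
    null_r = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(flat).reshape(nr, nc)
        null_c[i] = col_stat(perm)
        null_r[i] = row_stat(perm)
    z_c, p_c = _perm_z_p(obs_c, null_c)
    z_r, p_r = _perm_z_p(obs_r, null_r)
    if abs(z_c) >= abs(z_r):
        z, p, axis = z_c, p_c, "columns"
    else:
        z, p, axis = z_r, p_r, "rows"
    return StripeResult(z=z, p=p, axis=axis,
                        z_columns=z_c, z_rows=z_r,
                        p_columns=p_c, p_rows=p_r,
                        statistic_columns=obs_c, statistic_rows=obs_r)
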