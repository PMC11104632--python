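"""Random-dot stimulus rendering and display geometry.

A stimulus frame is a grid of square dots, each dot filled with one of a
small set of gray levels drawn uniformly at random.  Played back at the
configured frame rate the sequence forms a dynamic "noise" field: a
patient fixating its centre perceives field defects as non-flickering,
cloudy or dark patches.

The default profile matches a 1920x1200 monitor with 0.27 mm dot pitch
viewed at 30 cm: 7-pixel (1.89 mm) dots, five equiprobable tones, 60
frames per second.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np

from .errors import ConfigError, InputError
from .prng import RNGSpec


@dataclass(frozen=True)
class GrayPalette:
    """Gray tones available to the dot sampler.

    ``density_ratios`` are the nominal 0–1 color values used when the
    tones were designed; ``levels`` are the corresponding 8-bit gray
    values actually written to the frame buffer.  The levels are stored
    explicitly rather than derived by rounding ``ratio * 255`` because
    no single rounding rule yields the canonical set (0.25 -> 64 but
    0.5 -> 127); the measured level set is authoritative.
    """

    density_ratios: Tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.0)
    levels: Tuple[int, ...] = (255, 191, 127, 64, 0)

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise ConfigError("palette must contain at least one level")
        if len(self.levels) != len(self.density_ratios):
            raise ConfigError("palette ratios and levels differ in length")
        for lv in self.levels:
            if not 0 <= int(lv) <= 255:
                raise ConfigError(f"gray level out of 8-bit range: {lv}")
        for r in self.density_ratios:
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"density ratio outside [0, 1]: {r}")
        desc_r = all(a > b for a, b in zip(self.density_ratios, self.density_ratios[1:]))
        desc_l = all(a > b for a, b in zip(self.levels, self.levels[1:]))
        if desc_r and not desc_l:
            raise ConfigError("levels must be strictly descending when ratios are")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


#: Canonical five-tone palette: equiprobable gray values 0/64/127/191/255.
DEFAULT_PALETTE = GrayPalette()


@dataclass(frozen=True)
class StimulusConfig:
    """Full description of a stimulus run (geometry + palette + RNG)."""

    width_px: int = 1920
    height_px: int = 1200
    dot_px: int = 7
    palette: GrayPalette = field(default_factory=GrayPalette)
    n_frames: int = 60
    fps: float = 60.0
    rng: RNGSpec = field(default_factory=RNGSpec)
    dot_pitch_mm_per_px: float = 0.27

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigError("frame dimensions must be positive")
        if self.dot_px <= 0:
            raise ConfigError("dot size must be positive")
        if self.dot_px > min(self.width_px, self.height_px):
            raise ConfigError("dot size exceeds the frame")
        if self.n_frames <= 0:
            raise ConfigError("n_frames must be positive")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.dot_pitch_mm_per_px <= 0:
            raise ConfigError("dot pitch must be positive")

    @property
    def cells_shape(self) -> Tuple[int, int]:
        """(rows, cols) of the dot grid, counting clipped edge cells."""
        return (
            -(-self.height_px // self.dot_px),
            -(-self.width_px // self.dot_px),
        )

    @property
    def cells_per_frame(self) -> int:
        r, c = self.cells_shape
        return r * c

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.fps


@dataclass
class NoiseFrame:
    """One rendered still image (8-bit gray, dot-cell tiled)."""

    pixels: np.ndarray  # (height, width) uint8
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise InputError("NoiseFrame expects a 2-D gray image")

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.pixels.size


@dataclass(frozen=True)
class DisplayModel:
    """Physical display used for the examination."""

    width_cm: float = 51.84
    height_cm: float = 32.4
    viewing_distance_cm: float = 30.0
    max_luminance_cd_m2: float = 400.0
    gamma: float = 2.2

    def __post_init__(self) -> None:
        for name in ("width_cm", "height_cm", "viewing_distance_cm",
                     "max_luminance_cd_m2", "gamma"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


def render_frame(config: StimulusConfig, rng, frame_index: int = 0) -> NoiseFrame:
    """Render one frame, consuming exactly ``cells_per_frame`` index draws.

    Dots are placed row-major from the top-left corner; cells in the
    last row/column are clipped when the frame dimensions are not
    multiples of the dot size.
    """
    nrows, ncols = config.cells_shape
    idx = rng.index_block(config.palette.n_levels, nrows * ncols)
    levels = np.asarray(config.palette.levels, dtype=np.uint8)
    cells = levels[idx.reshape(nrows, ncols)]
    pixels = np.repeat(np.repeat(cells, config.dot_px, axis=0),
                       config.dot_px, axis=1)
    pixels = pixels[: config.height_px, : config.width_px]
    return NoiseFrame(pixels=pixels, frame_index=frame_index)


def render_sequence(config: StimulusConfig, rng=None) -> List[NoiseFrame]:
    """Render ``config.n_frames`` frames from one evolving RNG state.

    The whole sequence is determined by ``(config, seed)``; frame ``i``
    has nominal timestamp ``i / fps``.
    """
    if rng is None:
        rng = config.rng.make()
    return [render_frame(config, rng, frame_index=i)
            for i in range(config.n_frames)]


def frame_timestamps(config: StimulusConfig) -> np.ndarray:
    return np.arange(config.n_frames) / config.fps


# ---------------------------------------------------------------------------
# Display geometry
# ---------------------------------------------------------------------------

def eccentricity_deg(extent_cm: float, distance_cm: float) -> float:
    """Eccentricity (degrees) subtended by the half-extent of a screen
    dimension at the given viewing distance: ``atan((extent/2)/d)``.

    This is the convention under which a 51.84 cm wide screen at 30 cm
    spans "40.8 degrees": the angle from fixation to the screen edge.
    """
    if extent_cm < 0 or distance_cm <= 0:
        raise ConfigError("extent must be >= 0 and distance > 0")
    return math.degrees(math.atan((extent_cm / 2.0) / distance_cm))


def required_width_cm(ecc_deg: float, distance_cm: float) -> float:
    """Screen extent needed to reach ``ecc_deg`` on both sides of
    fixation at ``distance_cm`` — the inverse of :func:`eccentricity_deg`."""
    if not 0 <= ecc_deg < 90:
        raise ConfigError("eccentricity must lie in [0, 90)")
    if distance_cm <= 0:
        raise ConfigError("distance must be positive")
    return 2.0 * distance_cm * math.tan(math.radians(ecc_deg))


def dot_physical_mm(dot_px: int, pitch_mm_per_px: float) -> float:
    """Physical dot size: pixels times dot pitch (e.g. 7 px * 0.27 mm
    = 1.89 mm)."""
    if dot_px <= 0 or pitch_mm_per_px <= 0:
        raise ConfigError("dot size and pitch must be positive")
    return dot_px * pitch_mm_per_px


def predict_luminance(level: int, display: DisplayModel,
                      white_cd_m2: Optional[float] = None) -> float:
    """Approximate emitted luminance of an 8-bit gray level via the
    display gamma curve: ``white * (level/255) ** gamma``.

    This ignores the black-level offset, so it under-predicts dark
    levels slightly (a measured panel shows ~0.27 cd/m2 at level 0).
    """
    if not 0 <= level <= 255:
        raise InputError(f"gray level out of range: {level}")
    white = display.max_luminance_cd_m2 if white_cd_m2 is None else white_cd_m2
    return white * (level / 255.0) ** display.gamma


# ---------------------------------------------------------------------------
# Frame output
# ---------------------------------------------------------------------------

def write_pgm(frame: NoiseFrame, path) -> None:
    """Binary PGM (P5) writer for dependency-free round trips."""
    path = Path(path)
    header = f"P5\n{frame.width_px} {frame.height_px}\n255\n".encode("ascii")
    path.write_bytes(header + frame.pixels.tobytes())


def read_pgm(path) -> NoiseFrame:
    data = Path(path).read_bytes()
    fields: List[bytes] = []
    pos = 0
    while len(fields) < 4:
        while pos < len(data) and data[pos : pos + 1].isspace():
            pos += 1
        if data[pos : pos + 1] == b"#":
            while pos < len(data) and data[pos : pos + 1] != b"\n":
                pos += 1
            continue
        start = pos
        while pos < len(data) and not data[pos : pos + 1].isspace():
            pos += 1
        fields.append(data[start:pos])
    if fields[0] != b"P5":
        raise InputError(f"not a binary PGM file: {path}")
    width, height, maxval = (int(f) for f in fields[1:4])
    if maxval != 255:
        raise InputError("only 8-bit PGM is supported")
    pos += 1  # single whitespace after maxval
    raster = np.frombuffer(data, dtype=np.uint8, count=width * height, offset=pos)
    return NoiseFrame(pixels=raster.reshape(height, width))


def write_frames(frames: Sequence[NoiseFrame], outdir, config: StimulusConfig,
                 fmt: str = "png") -> Path:
    """Write numbered frames plus a JSON manifest; returns manifest path.

    The manifest records the configuration, seed and a SHA-256 checksum
    per frame so that a run can be verified bit-for-bit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for frame in frames:
        name = f"frame_{frame.frame_index:06d}.{fmt}"
        path = outdir / name
        if fmt == "png":
            iio.imwrite(path, frame.pixels)
        elif fmt == "pgm":
            write_pgm(frame, path)
        else:
            raise ConfigError(f"unsupported frame format: {fmt!r}")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entries.append({"file": name, "frame_index": frame.frame_index,
                        "sha256": digest})
    manifest = {
        "config": {
            "width_px": config.width_px,
            "height_px": config.height_px,
            "dot_px": config.dot_px,
            "levels": list(config.palette.levels),
            "density_ratios": list(config.palette.density_ratios),
            "n_frames": config.n_frames,
            "fps": config.fps,
            "dot_pitch_mm_per_px": config.dot_pitch_mm_per_px,
            "rng": {
                "algorithm": config.rng.algorithm,
                "seed": config.rng.seed,
                "lcg_params": list(config.rng.lcg_params)
                if config.rng.lcg_params else None,
            },
        },
        "frames": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_frames(paths: Sequence) -> List[NoiseFrame]:
    """Load a stack of grayscale frames (PNG/PGM) as NoiseFrames."""
    frames = []
    for i, p in enumerate(sorted(Path(p) for p in paths)):
        if p.suffix.lower() == ".pgm":
            frame = read_pgm(p)
        else:
            try:
                arr = iio.imread(p)
            except Exception as exc:  # noqa: BLE001 - surface as InputError
                raise InputError(f"cannot read image {p}: {exc}") from exc
            if arr.ndim == 3:
                arr = arr[..., 0]
            frame = NoiseFrame(pixels=arr)
        frame.frame_index = i
        frames.append(frame)
    return frames
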