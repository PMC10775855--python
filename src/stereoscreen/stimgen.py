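"""Anaglyphic random-dot-stereogram (RDS) stimulus synthesis.

Each stimulus is a field of square dots on a dark background, rendered
separately into a red and a green channel (one per eye through red-green
goggles). Inside a Snellen-E shaped target region the green-channel dots are
displaced horizontally by the stimulus disparity, so the letter is visible
only binocularly; outside the target the channels are identical. Dynamic
stimuli regenerate the dot field every frame (30 Hz) while the target region
and disparity persist. Monocular control stimuli carry a luminance-defined E
identical in both channels, visible through either filter alone — they check
that the child understands the task, not stereopsis.

Conditions follow the four-test battery: 8% static (SRDS 8), 1% dynamic
(DRDS 1), 0.7% dynamic (DRDS 0.7) and 1% dynamic with 0.5% binocularly
uncorrelated noise (DRDS 1 + noise). Dot size 420", disparity 840", target
size ~2 degrees.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .device import DeviceProfile, angle_to_pixels


class StimulusGeometryError(ValueError):
    """Stimulus does not fit the requested field."""


class Condition(str, enum.Enum):
    SRDS8 = "SRDS8"
    DRDS1 = "DRDS1"
    DRDS07 = "DRDS07"
    DRDS1N = "DRDS1N"
    MONO_CONTROL = "MONO_CONTROL"


STEREO_CONDITIONS = (Condition.SRDS8, Condition.DRDS1,
                     Condition.DRDS07, Condition.DRDS1N)


class Orientation(str, enum.Enum):
    """Direction the limbs of the Snellen E point."""
    UP = "UP"
    DOWN = "DOWN"
    LEFT = "LEFT"
    RIGHT = "RIGHT"


ORIENTATIONS = (Orientation.UP, Orientation.DOWN,
                Orientation.LEFT, Orientation.RIGHT)

#: number of 90-degree counter-clockwise rotations from the canonical
#: limbs-right glyph
_N_ROT90 = {Orientation.RIGHT: 0, Orientation.UP: 1,
            Orientation.LEFT: 2, Orientation.DOWN: 3}

# canonical 5x5 Snellen E, limbs pointing right
_E_GLYPH = np.array([
    [1, 1, 1, 1, 1],
    [1, 0, 0, 0, 0],
    [1, 1, 1, 1, 0],
    [1, 0, 0, 0, 0],
    [1, 1, 1, 1, 1],
], dtype=bool)


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of one RDS (or monocular control) stimulus."""

    condition: Condition
    density_fraction: float
    dynamic: bool = False
    frame_rate_hz: float = 30.0
    noise_fraction: float = 0.0
    dot_size_arcsec: float = 420.0
    disparity_arcsec: float = 840.0
    target_orientation: Orientation = Orientation.UP
    target_size_deg: float = 2.0
    n_frames: int = 1
    seed: int = 0
    # dot field extent; None means the full device screen
    field_width_px: int | None = None
    field_height_px: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.density_fraction <= 1.0:
            raise ValueError("density_fraction must be in (0, 1]")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must be in [0, 1)")
        if self.density_fraction + self.noise_fraction > 1.0:
            raise ValueError("density_fraction + noise_fraction must be <= 1")
        if not self.dynamic and self.n_frames != 1:
            raise ValueError("static stimuli have exactly one frame")
        if self.condition is Condition.MONO_CONTROL and self.disparity_arcsec != 0:
            raise ValueError("monocular controls carry zero disparity")

    def with_orientation(self, orientation: Orientation) -> "StimulusSpec":
        return replace(self, target_orientation=orientation)

    def with_seed(self, seed: int) -> "StimulusSpec":
        return replace(self, seed=seed)


#: default dynamic stimulus duration: 3 s at 30 Hz
DEFAULT_DYNAMIC_FRAMES = 90

_CONDITION_DEFAULTS = {
    Condition.SRDS8: dict(density_fraction=0.08, dynamic=False, n_frames=1),
    Condition.DRDS1: dict(density_fraction=0.01, dynamic=True,
                          n_frames=DEFAULT_DYNAMIC_FRAMES),
    Condition.DRDS07: dict(density_fraction=0.007, dynamic=True,
                           n_frames=DEFAULT_DYNAMIC_FRAMES),
    Condition.DRDS1N: dict(density_fraction=0.01, dynamic=True,
                           noise_fraction=0.005, n_frames=DEFAULT_DYNAMIC_FRAMES),
    Condition.MONO_CONTROL: dict(density_fraction=0.08, dynamic=False,
                                 n_frames=1, disparity_arcsec=0.0),
}


def spec_for_condition(condition: Condition, **overrides) -> StimulusSpec:
    """Build a :class:`StimulusSpec` with the study defaults for a condition."""
    kwargs = dict(_CONDITION_DEFAULTS[condition])
    kwargs.update(overrides)
    return StimulusSpec(condition=condition, **kwargs)


@dataclass
class AnaglyphFrame:
    """One rendered frame: binary dot masks for the red and green channels."""

    red_channel: np.ndarray
    green_channel: np.ndarray
    frame_index: int
    spec: StimulusSpec
    device: DeviceProfile
    seed: int

    @property
    def width_px(self) -> int:
        return self.red_channel.shape[1]

    @property
    def height_px(self) -> int:
        return self.red_channel.shape[0]

    def to_rgb(self) -> np.ndarray:
        """uint8 H x W x 3 image: pure red / pure green dots on black."""
        img = np.zeros(self.red_channel.shape + (3,), dtype=np.uint8)
        img[..., 0] = np.where(self.red_channel, 255, 0)
        img[..., 1] = np.where(self.green_channel, 255, 0)
        return img


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    # a (seed, frame) pair seeds the sequence so any frame is independently
    # re-renderable
    return np.random.default_rng([int(seed), int(frame_index)])


def _field_shape_px(spec: StimulusSpec, device: DeviceProfile) -> tuple[int, int]:
    w = spec.field_width_px or device.screen_width_px
    h = spec.field_height_px or device.screen_height_px
    return h, w


def target_cell_mask(spec: StimulusSpec, device: DeviceProfile,
                     n_rows: int, n_cols: int) -> np.ndarray:
    """Boolean mask over the dot grid marking the Snellen-E target region."""
    cell_px = angle_to_pixels(spec.dot_size_arcsec, device)
    target_px = angle_to_pixels(spec.target_size_deg * 3600.0, device)
    target_cells = max(5, target_px // max(cell_px, 1))
    # scale the 5x5 glyph to the nearest whole multiple of the target size,
    # then rotate to the orientation
    scale = max(1, round(target_cells / 5))
    glyph = np.kron(_E_GLYPH, np.ones((scale, scale), dtype=bool))
    glyph = np.rot90(glyph, _N_ROT90[spec.target_orientation])
    gh, gw = glyph.shape
    if gh > n_rows or gw > n_cols:
        raise StimulusGeometryError(
            f"target ({gh}x{gw} cells) exceeds the dot field ({n_rows}x{n_cols})")
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    r0 = (n_rows - gh) // 2
    c0 = (n_cols - gw) // 2
    mask[r0:r0 + gh, c0:c0 + gw] = glyph
    return mask


def _expand(cells: np.ndarray, cell_px: int, shape_px: tuple[int, int]) -> np.ndarray:
    px = np.kron(cells, np.ones((cell_px, cell_px), dtype=bool))
    return px[:shape_px[0], :shape_px[1]]


def _shift_right(img: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return img.copy()
    out = np.zeros_like(img)
    out[:, k:] = img[:, :-k]
    return out


def render_rds_frame(spec: StimulusSpec, device: DeviceProfile,
                     frame_index: int = 0) -> AnaglyphFrame:
    """Render one frame of a stereogram condition.

    The dot field lives on a grid of square cells of one dot size. Each cell
    holds a dot with probability ``density_fraction``, identically in both
    channels except inside the E target, where green-channel dots are shifted
    rightward by the disparity (crossed disparity, target in front). Cells
    vacated by the shift are refilled at the field density so the target has
    no monocular density signature. Uncorrelated noise dots are then added
    independently per channel. Deterministic given (spec.seed, frame_index).
    """
    if spec.condition is Condition.MONO_CONTROL:
        raise ValueError("use render_monocular_control for MONO_CONTROL")
    shape_px = _field_shape_px(spec, device)
    cell_px = angle_to_pixels(spec.dot_size_arcsec, device)
    if cell_px <= 0:
        raise StimulusGeometryError("dot size below one pixel on this device")
    disparity_px = angle_to_pixels(spec.disparity_arcsec, device)
    if disparity_px >= shape_px[1] or cell_px >= shape_px[1]:
        raise StimulusGeometryError("disparity or dot size exceeds image width")
    n_rows = -(-shape_px[0] // cell_px)
    n_cols = -(-shape_px[1] // cell_px)

    rng = _frame_rng(spec.seed, frame_index)
    base = rng.random((n_rows, n_cols)) < spec.density_fraction
    target = target_cell_mask(spec, device, n_rows, n_cols)

    red = _expand(base, cell_px, shape_px)
    target_px_mask = _expand(target, cell_px, shape_px)

    # green: background dots untouched, target dots shifted right
    green = _expand(base & ~target, cell_px, shape_px)
    green |= _shift_right(_expand(base & target, cell_px, shape_px), disparity_px)
    # refill the vacated strip (target pixels not covered after the shift)
    vacated_px = target_px_mask & ~_shift_right(target_px_mask, disparity_px)
    refill = rng.random((n_rows, n_cols)) < spec.density_fraction
    green |= _expand(refill, cell_px, shape_px) & vacated_px

    for channel in (red, green):
        if spec.noise_fraction > 0:
            noise = rng.random((n_rows, n_cols)) < spec.noise_fraction
            channel |= _expand(noise, cell_px, shape_px)

    return AnaglyphFrame(red_channel=red, green_channel=green,
                         frame_index=frame_index, spec=spec, device=device,
                         seed=spec.seed)


def render_monocular_control(spec: StimulusSpec,
                             device: DeviceProfile) -> AnaglyphFrame:
    """Render a zero-disparity control: a solid, luminance-defined E.

    The E region is fully filled with dots and the background carries dots at
    the field density, identically in both channels, so the letter is visible
    through either goggle filter alone.
    """
    if spec.condition is not Condition.MONO_CONTROL:
        raise ValueError("condition must be MONO_CONTROL")
    shape_px = _field_shape_px(spec, device)
    cell_px = angle_to_pixels(spec.dot_size_arcsec, device)
    if cell_px <= 0 or cell_px >= shape_px[1]:
        raise StimulusGeometryError("dot size invalid for this device")
    n_rows = -(-shape_px[0] // cell_px)
    n_cols = -(-shape_px[1] // cell_px)
    rng = _frame_rng(spec.seed, 0)
    base = rng.random((n_rows, n_cols)) < spec.density_fraction
    target = target_cell_mask(spec, device, n_rows, n_cols)
    cells = base | target
    px = _expand(cells, cell_px, shape_px)
    return AnaglyphFrame(red_channel=px, green_channel=px.copy(),
                         frame_index=0, spec=spec, device=device,
                         seed=spec.seed)


def render_stimulus(spec: StimulusSpec, device: DeviceProfile) -> list[AnaglyphFrame]:
    """All frames of a stimulus (one for static, n_frames for dynamic)."""
    if spec.condition is Condition.MONO_CONTROL:
        return [render_monocular_control(spec, device)]
    return [render_rds_frame(spec, device, i) for i in range(spec.n_frames)]


@dataclass
class SessionProtocol:
    """Ordered stimulus sequence of one testing session."""

    stimuli: list[StimulusSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def conditions(self) -> list[Condition]:
        return [s.condition for s in self.stimuli]

    @classmethod
    def default(cls, **overrides) -> "SessionProtocol":
        """The 24-stimulus session: one monocular control before each block
        of five identical-condition stereograms, in the order
        SRDS 8, DRDS 1, DRDS 0.7, DRDS 1 + noise.

        An ``n_frames`` override applies to dynamic stimuli only (static
        stimuli always have one frame)."""
        n_frames = overrides.pop("n_frames", None)
        stimuli: list[StimulusSpec] = []
        for cond in STEREO_CONDITIONS:
            stimuli.append(spec_for_condition(Condition.MONO_CONTROL, **overrides))
            extra = {} if n_frames is None or not _CONDITION_DEFAULTS[cond].get(
                "dynamic") else {"n_frames": n_frames}
            stimuli.extend(spec_for_condition(cond, **overrides, **extra)
                           for _ in range(5))
        return cls(stimuli=stimuli)


@dataclass
class RenderedStimulus:
    index: int
    spec: StimulusSpec
    orientation: Orientation
    seed: int
    frames: list[AnaglyphFrame]


def render_sequence(protocol: SessionProtocol, device: DeviceProfile,
                    seed: int) -> list[RenderedStimulus]:
    """Render a whole session: orientations drawn uniformly per stimulus,
    per-stimulus seeds derived as master seed + stimulus index."""
    if not protocol.stimuli:
        raise ValueError("protocol is empty")
    rng = np.random.default_rng(seed)
    out: list[RenderedStimulus] = []
    for i, spec in enumerate(protocol.stimuli):
        orientation = ORIENTATIONS[rng.integers(4)]
        s = spec.with_orientation(orientation).with_seed(seed + i)
        out.append(RenderedStimulus(index=i, spec=s, orientation=orientation,
                                    seed=seed + i,
                                    frames=render_stimulus(s, device)))
    return out


def export_session(rendered: Sequence[RenderedStimulus], out_dir: str | Path) -> Path:
    """Write per-frame PNGs, JSON sidecars and a manifest CSV for a session."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["stimulus_index,condition,orientation,seed,n_frames,path"]
    for stim in rendered:
        stim_dir = out_dir / f"stim_{stim.index:02d}_{stim.spec.condition.value}"
        stim_dir.mkdir(exist_ok=True)
        for frame in stim.frames:
            Image.fromarray(frame.to_rgb()).save(
                stim_dir / f"frame_{frame.frame_index:03d}.png")
        sidecar = {
            "condition": stim.spec.condition.value,
            "orientation": stim.orientation.value,
            "seed": stim.seed,
            "n_frames": len(stim.frames),
            "density_fraction": stim.spec.density_fraction,
            "noise_fraction": stim.spec.noise_fraction,
            "dot_size_arcsec": stim.spec.dot_size_arcsec,
            "disparity_arcsec": stim.spec.disparity_arcsec,
        }
        (stim_dir / "stimulus.json").write_text(json.dumps(sidecar, indent=2))
        rows.append(f"{stim.index},{stim.spec.condition.value},"
                    f"{stim.orientation.value},{stim.seed},"
                    f"{len(stim.frames)},{stim_dir.name}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
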