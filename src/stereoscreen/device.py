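"""Display geometry: device profiles and visual-angle / pixel conversion.

Disparities and dot sizes for random-dot stereograms are specified as visual
angles (arcseconds). To render them on a concrete display the angle must be
converted to a pixel count, which requires the physical pixel pitch and the
viewing distance. Both study tablets are 10.1-inch 1920x1200 panels
(pitch ~= 0.1132 mm/px) viewed at 25-30 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

ARCSEC_PER_DEG = 3600.0


class ConfigurationError(ValueError):
    """Invalid device or stimulus configuration."""


@dataclass(frozen=True)
class DeviceProfile:
    """Physical description of the display used for stimulus presentation.

    Parameters
    ----------
    screen_width_px, screen_height_px
        Panel resolution in pixels.
    pixel_pitch_mm
        Physical size of one pixel in millimetres.
    viewing_distance_cm
        Eye-to-screen distance in centimetres. Sanity range 10-100 cm
        (hand-held / desktop use).
    """

    screen_width_px: int
    screen_height_px: int
    pixel_pitch_mm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        for name in ("screen_width_px", "screen_height_px", "pixel_pitch_mm",
                     "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not 10.0 <= self.viewing_distance_cm <= 100.0:
            raise ConfigurationError(
                "viewing_distance_cm outside the sanity range [10, 100]")

    @property
    def viewing_distance_mm(self) -> float:
        return self.viewing_distance_cm * 10.0


def _round_half_away_from_zero(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def angle_to_pixels(angle_arcsec: float, device: DeviceProfile) -> int:
    """Convert a visual angle to a whole number of pixels on ``device``.

    Uses the exact tangent relation  extent = D * tan(angle)  with the
    viewing distance D, then rounds half away from zero. 420" at 25 cm on a
    0.1132 mm pitch panel is ~0.509 mm, i.e. 4 px; 840" is ~1.018 mm, 9 px.
    """
    if angle_arcsec < 0:
        raise ValueError("angle must be non-negative")
    extent_mm = device.viewing_distance_mm * math.tan(
        math.radians(angle_arcsec / ARCSEC_PER_DEG))
    return _round_half_away_from_zero(extent_mm / device.pixel_pitch_mm)


def _pitch_from_diagonal(diag_inch: float, width_px: int, height_px: int) -> float:
    diag_px = math.hypot(width_px, height_px)
    return diag_inch * 25.4 / diag_px


# 10.1" WUXGA tablets used in the study; identical panel geometry.
GALAXY_TAB_A_2016 = DeviceProfile(
    screen_width_px=1920, screen_height_px=1200,
    pixel_pitch_mm=_pitch_from_diagonal(10.1, 1920, 1200),
    viewing_distance_cm=25.0)
AQUARIS_M10 = DeviceProfile(
    screen_width_px=1920, screen_height_px=1200,
    pixel_pitch_mm=_pitch_from_diagonal(10.1, 1920, 1200),
    viewing_distance_cm=25.0)

DEVICE_PRESETS = {
    "galaxy_tab_a_2016": GALAXY_TAB_A_2016,
    "aquaris_m10": AQUARIS_M10,
}
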