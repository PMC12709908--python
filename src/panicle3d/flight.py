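"""UAV capture-planning calculators.

Closed-form arithmetic for planning low-altitude video flights over crop
plots: how much motion blur a given speed/shutter pair produces, how many
video frames a plot pass yields, and the ground sampling distance (GSD) of
the imagery.  These numbers decide whether a faster video-based protocol
can replace slow stop-and-capture still imaging for canopy reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CaptureConfig",
    "motion_blur_mm",
    "frame_count",
    "ground_sampling_distance",
]


@dataclass(frozen=True)
class CaptureConfig:
    """UAV camera/flight settings for one acquisition plan.

    Parameters
    ----------
    altitude_m : float
        Flight altitude above the canopy, metres.
    speed_mps : float
        Horizontal flight speed, metres per second (>= 0).
    shutter_s : float
        Exposure duration, seconds (e.g. ``1 / 8000``).
    fps : float
        Video frame rate, frames per second.
    image_width_px : int
        Horizontal image resolution in pixels.
    horizontal_fov_deg : float
        Horizontal field of view of the lens, degrees, in (0, 180).
    """

    altitude_m: float
    speed_mps: float
    shutter_s: float
    fps: float
    image_width_px: int
    horizontal_fov_deg: float

    def __post_init__(self) -> None:
        if self.altitude_m <= 0:
            raise ValueError(f"altitude_m must be > 0, got {self.altitude_m}")
        if self.speed_mps < 0:
            raise ValueError(f"speed_mps must be >= 0, got {self.speed_mps}")
        if self.shutter_s <= 0:
            raise ValueError(f"shutter_s must be > 0, got {self.shutter_s}")
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.image_width_px <= 0:
            raise ValueError(f"image_width_px must be > 0, got {self.image_width_px}")
        if not 0 < self.horizontal_fov_deg < 180:
            raise ValueError(
                f"horizontal_fov_deg must lie in (0, 180), got {self.horizontal_fov_deg}"
            )


def motion_blur_mm(speed_mps: float, shutter_s: float) -> float:
    """Ground-plane motion blur of one exposure, in millimetres.

    A camera moving at ``speed_mps`` smears each exposed frame by
    ``speed * shutter`` along-track; e.g. 2.5 m/s at 1/8000 s gives 0.3 mm,
    which is negligible against a sub-centimetre GSD.
    """
    if shutter_s <= 0:
        raise ValueError(f"shutter_s must be > 0, got {shutter_s}")
    if speed_mps < 0:
        raise ValueError(f"speed_mps must be >= 0, got {speed_mps}")
    return speed_mps * shutter_s * 1000.0


def frame_count(duration_s: float, fps: float) -> int:
    """Number of whole video frames captured in ``duration_s`` seconds.

    A partial frame is not captured, so the product is floored: 20 s of
    30 fps video yields 600 frames.
    """
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    if duration_s < 0:
        raise ValueError(f"duration_s must be >= 0, got {duration_s}")
    return int(math.floor(duration_s * fps))


def ground_sampling_distance(
    altitude_m: float, horizontal_fov_deg: float, image_width_px: int
) -> float:
    """Ground sampling distance in cm/pixel under a pinhole full-FOV model.

    Convention: the ground footprint of the image width is
    ``2 * altitude * tan(fov / 2)`` (nadir-looking pinhole camera, flat
    ground), divided by the pixel count.  Published GSD figures for a given
    sensor may differ from this convention because the effective focal
    length, sensor crop, or video downsampling mode is rarely stated; this
    calculator documents its convention rather than matching any particular
    datasheet.
    """
    if altitude_m < 0:
        raise ValueError(f"altitude_m must be >= 0, got {altitude_m}")
    if image_width_px <= 0:
        raise ValueError(f"image_width_px must be > 0, got {image_width_px}")
    if not 0 < horizontal_fov_deg < 180:
        raise ValueError(
            f"horizontal_fov_deg must lie in (0, 180), got {horizontal_fov_deg}"
        )
    footprint_m = 2.0 * altitude_m * math.tan(math.radians(horizontal_fov_deg) / 2.0)
    return footprint_m * 100.0 / image_width_px
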