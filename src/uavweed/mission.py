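"""Photogrammetric mission geometry for nadir UAV surveys.

Everything here follows from the pinhole-camera relation between flight
altitude and ground coverage: a sensor of width :math:`s_w` behind a lens of
focal length :math:`f`, flown at altitude :math:`h`, images a ground strip of
width :math:`h \\cdot s_w / f`, and each of its :math:`n_x` pixels covers
:math:`h \\cdot (s_w/n_x) / f` on the ground (the ground sampling distance,
GSD).  Waypoint grids, image counts and flight duration for a rectangular
field follow from the footprint and the requested forward/side overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CameraSpec",
    "FlightParams",
    "Footprint",
    "MissionPlan",
    "Kinematics",
    "ground_sampling_distance",
    "image_footprint",
    "altitude_for_gsd",
    "plan_grid",
    "images_per_hectare",
    "estimate_flight_time",
    "MULTISPECTRAL_CAMERA",
    "RGB_CAMERA",
]


class InvalidSpecError(ValueError):
    """A camera or flight specification violates its invariants."""


@dataclass(frozen=True)
class CameraSpec:
    """Optical/sensor geometry of one camera.

    Parameters
    ----------
    focal_length : float
        Lens focal length in mm.  ``effective_focal_length`` overrides it in
        all ground-geometry computations when the nominal value printed on
        the lens differs from the value the imagery implies (common with
        zoom lenses reported at one end of their range).
    sensor_width, sensor_height : float
        Physical sensor dimensions in mm; width is the long axis.
    pixels_x, pixels_y : int
        Pixel counts along width and height.
    bit_depth : int
        Radiometric resolution in bits.
    """

    name: str
    focal_length: float
    sensor_width: float
    sensor_height: float
    pixels_x: int
    pixels_y: int
    bit_depth: int = 8
    effective_focal_length: float | None = None

    def __post_init__(self) -> None:
        for fld in ("focal_length", "sensor_width", "sensor_height",
                    "pixels_x", "pixels_y", "bit_depth"):
            if getattr(self, fld) <= 0:
                raise InvalidSpecError(f"{fld} must be > 0, got {getattr(self, fld)}")
        px = self.sensor_width / self.pixels_x
        py = self.sensor_height / self.pixels_y
        if abs(px - py) > 0.1 * max(px, py):
            raise InvalidSpecError(
                f"anisotropic pixel pitch ({px:.4g} x {py:.4g} mm) beyond 10%"
            )
        if self.effective_focal_length is not None and self.effective_focal_length <= 0:
            raise InvalidSpecError("effective_focal_length must be > 0")

    @property
    def focal(self) -> float:
        """Focal length (mm) used for ground geometry."""
        return self.effective_focal_length or self.focal_length

    @property
    def pixel_pitch(self) -> float:
        """Horizontal pixel pitch in mm (sensor_width / pixels_x)."""
        return self.sensor_width / self.pixels_x


#: Six-band multispectral camera (2x3 lens array, 9.6 mm lenses,
#: 6.66 x 5.32 mm CMOS, 1280 x 1024 px, 10-bit capable).
MULTISPECTRAL_CAMERA = CameraSpec(
    name="multispectral",
    focal_length=9.6,
    sensor_width=6.66,
    sensor_height=5.32,
    pixels_x=1280,
    pixels_y=1024,
    bit_depth=10,
)

#: 12-Mpx still RGB camera with a 14-42 mm zoom (nominal wide end used).
RGB_CAMERA = CameraSpec(
    name="rgb",
    focal_length=14.0,
    sensor_width=17.3,
    sensor_height=13.0,
    pixels_x=4032,
    pixels_y=3024,
    bit_depth=8,
)


@dataclass(frozen=True)
class FlightParams:
    """Mission parameters for a rectangular field survey."""

    altitude: float
    field_width: float = 100.0
    field_length: float = 100.0
    direction_angle: float = 65.0
    forward_overlap: float = 0.60
    side_overlap: float = 0.30
    dwell: float = 5.0
    images_per_waypoint: int = 1

    def __post_init__(self) -> None:
        if self.altitude <= 0:
            raise InvalidSpecError("altitude must be > 0")
        if self.field_width <= 0 or self.field_length <= 0:
            raise InvalidSpecError("field dimensions must be > 0")
        for ov in (self.forward_overlap, self.side_overlap):
            if not (0 <= ov < 1):
                raise InvalidSpecError(f"overlap must be in [0, 1), got {ov}")

    @property
    def field_area_ha(self) -> float:
        return self.field_width * self.field_length / 1e4


@dataclass(frozen=True)
class Footprint:
    """Ground rectangle imaged by one frame."""

    width: float   # m, long image dimension on ground
    height: float  # m, short dimension
    gsd: float     # cm per pixel
    area: float    # ha


@dataclass(frozen=True)
class Kinematics:
    """Flight performance used for duration estimates."""

    cruise_speed: float = 15.0  # m/s
    climb_rate: float = 7.5     # m/s

    def __post_init__(self) -> None:
        if self.cruise_speed <= 0 or self.climb_rate <= 0:
            raise InvalidSpecError("speeds must be > 0")


@dataclass(frozen=True)
class MissionPlan:
    """Serpentine waypoint grid covering a rectangular field.

    Waypoints are expressed in a local field frame: origin at a field
    corner, x-axis along the flight-line direction (``direction_angle``
    clockwise from north), y across track.  Each waypoint sits at the
    centre of its coverage cell so the union of footprints covers the
    field.
    """

    n_lines: int
    images_per_line: int
    line_spacing: float   # m, across-track
    along_spacing: float  # m, along-track
    altitude: float
    footprint: Footprint
    waypoints: tuple[tuple[float, float, float], ...] = field(repr=False)
    duration: float | None = None  # min, filled by estimate_flight_time

    @property
    def total_images(self) -> int:
        return self.n_lines * self.images_per_line


def ground_sampling_distance(camera: CameraSpec, altitude: float) -> float:
    """Ground size of one pixel, in cm, at the given altitude (m).

    GSD = altitude * pixel_pitch / focal_length, using the horizontal
    pitch.  Exactly linear in altitude.  Display convention: two decimals.
    """
    if altitude < 0:
        raise ValueError(f"altitude must be >= 0, got {altitude}")
    return altitude * camera.pixel_pitch / camera.focal * 100.0


def image_footprint(camera: CameraSpec, altitude: float) -> Footprint:
    """Ground rectangle imaged by a single frame at the given altitude (m)."""
    if altitude < 0:
        raise ValueError(f"altitude must be >= 0, got {altitude}")
    w = altitude * camera.sensor_width / camera.focal
    h = altitude * camera.sensor_height / camera.focal
    return Footprint(width=w, height=h,
                     gsd=ground_sampling_distance(camera, altitude),
                     area=w * h / 1e4)


def altitude_for_gsd(camera: CameraSpec, target_gsd: float) -> int:
    """Lowest whole-metre altitude whose GSD reaches ``target_gsd`` (cm).

    Inverts the pinhole GSD relation and rounds up, so the returned
    altitude's exact GSD may slightly exceed the target (by <1 m worth
    of GSD).
    """
    if target_gsd <= 0:
        raise ValueError(f"target_gsd must be > 0, got {target_gsd}")
    exact = target_gsd / 100.0 * camera.focal / camera.pixel_pitch
    return math.ceil(round(exact, 9))


def plan_grid(camera: CameraSpec, flight: FlightParams) -> MissionPlan:
    """Lay out the serpentine waypoint grid covering the field.

    Flight lines run along the field width (the direction-angle axis);
    side-lap spaces lines across the field length.  Forward-lap applies to
    the long footprint dimension (the sensor's long axis points along
    track), side-lap to the short one.  Both counts round up so coverage
    is guaranteed.
    """
    fp = image_footprint(camera, flight.altitude)
    if fp.width <= 0 or fp.height <= 0:
        raise InvalidSpecError("footprint must be strictly positive")
    along = (1.0 - flight.forward_overlap) * fp.width
    across = (1.0 - flight.side_overlap) * fp.height
    images_per_line = math.ceil(round(flight.field_width / along, 9))
    n_lines = math.ceil(round(flight.field_length / across, 9))

    wps: list[tuple[float, float, float]] = []
    for i in range(n_lines):
        y = (i + 0.5) * across
        xs = [(j + 0.5) * along for j in range(images_per_line)]
        if i % 2 == 1:  # serpentine: alternate line direction
            xs.reverse()
        wps.extend((x, y, flight.altitude) for x in xs)

    return MissionPlan(
        n_lines=n_lines,
        images_per_line=images_per_line,
        line_spacing=across,
        along_spacing=along,
        altitude=flight.altitude,
        footprint=fp,
        waypoints=tuple(wps),
    )


def images_per_hectare(plan: MissionPlan, flight: FlightParams) -> float:
    """Image density: total planned images per hectare of field."""
    area = flight.field_area_ha
    if area <= 0:
        raise ValueError("field area must be > 0")
    return plan.total_images / area


def estimate_flight_time(plan: MissionPlan, kin: Kinematics = Kinematics(),
                         dwell: float = 5.0, images_per_waypoint: int = 1) -> float:
    """Mission duration in minutes: climb + descent, serpentine cruise, dwell.

    duration = 2*altitude/climb_rate + path_length/cruise_speed
             + total_images * dwell * images_per_waypoint

    This is a deliberately simple constant-speed model; commercial flight
    planners use unpublished acceleration profiles, so absolute agreement
    with any particular ground station is not expected.
    """
    climb = 2.0 * plan.altitude / kin.climb_rate
    path = 0.0
    for (x0, y0, _), (x1, y1, _) in zip(plan.waypoints, plan.waypoints[1:]):
        path += math.hypot(x1 - x0, y1 - y0)
    hold = len(plan.waypoints) * dwell * images_per_waypoint
    return (climb + path / kin.cruise_speed + hold) / 60.0
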