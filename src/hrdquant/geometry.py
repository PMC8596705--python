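"""Physical/pixel coordinate frame of an en-face OCT slab.

An en-face ("C-scan") slab is acquired over a rectangular field expressed in
degrees of visual angle and carried here together with the conversion factors
needed to move between degrees, micrometres and pixels.  The axial offset of
the slab below the ellipsoid zone is retained as metadata only; no axial
computation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class FieldGeometry:
    """Coordinate frame of a rectangular en-face slab.

    Parameters
    ----------
    width_deg, height_deg :
        Field extent in degrees of visual angle (x = width, y = height).
    um_per_deg :
        Retinal magnification factor.  Defaults to 288 um/degree, the
        conventional emmetropic schematic-eye value.
    um_per_px :
        Transverse pixel pitch of the sampled slab.
    slab_offset_um :
        Depth of the slab below the ellipsoid zone; metadata only.
    """

    width_deg: float = 10.0
    height_deg: float = 5.0
    um_per_deg: float = 288.0
    um_per_px: float = 3.0
    slab_offset_um: float = 14.0

    def __post_init__(self) -> None:
        for name in ("width_deg", "height_deg", "um_per_deg", "um_per_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def width_um(self) -> float:
        return self.width_deg * self.um_per_deg

    @property
    def height_um(self) -> float:
        return self.height_deg * self.um_per_deg

    @property
    def shape(self) -> tuple[int, int]:
        """Pixel grid shape as (rows, cols) = (height, width)."""
        return (
            int(round(self.height_um / self.um_per_px)),
            int(round(self.width_um / self.um_per_px)),
        )

    def um_to_px(self, um: float) -> float:
        return um / self.um_per_px

    def px_to_um(self, px: float) -> float:
        return px * self.um_per_px

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FieldGeometry":
        return cls(**d)


DEFAULT_GEOMETRY = FieldGeometry()
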