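"""Default anthropomorphic torso phantom and its design tables.

A simplified digital torso: elliptical-cylinder body, ellipsoidal liver and
lungs, spherical bladder and tubular ureters, with compartment volumes within
10 % of the physical phantom's.  Anatomical realism beyond volumes and
concentrations is deliberately out of scope.

Concentrations come from a patient-derived design: background (pelvis and
thorax soft tissue) 1.8 kBq/mL, liver 9.9 (5.5:1), lungs 0.67 (0.37:1, a
uniform stand-in for bead-filled lungs), bladder 176.3 (98:1), ureters
2.85 and 6.5 kBq/mL.  Lesions are cast at 7.2 / 28.8 / 57.6 kBq/mL to give
4:1, 16:1 and 32:1 lesion-to-background ratios against the 1.8 kBq/mL
background.
"""

from __future__ import annotations

import math

import numpy as np

from .grid import DEFAULT_SPACING, VoxelGrid
from .isotopes import F18, NA22
from .phantom import (
    Box,
    CompartmentSpec,
    Cylinder,
    Ellipsoid,
    LesionSpec,
    PhantomSpec,
    Sphere,
    TubePath,
    sphere_volume_ml,
)

__all__ = [
    "COMPARTMENT_TABLE",
    "LESION_CONCENTRATIONS",
    "LESION_DIAMETERS_MM",
    "BACKGROUND_KBQ_ML",
    "SCAN1_PROTOCOL",
    "probe_iq_pelvis",
    "lesion_ring",
]

#: Background (soft-tissue) activity concentration at reference time, kBq/mL.
BACKGROUND_KBQ_ML = 1.8

#: Target compartment design: name -> (volume mL, concentration kBq/mL,
#: printed relative concentration).
COMPARTMENT_TABLE = {
    "bladder": (440.0, 176.3, 98.0),
    "liver": (1025.0, 9.9, 5.5),
    "lung_left": (875.0, 0.67, 0.37),
    "lung_right": (1152.0, 0.67, 0.37),
    "pelvis": (9000.0, 1.8, 1.0),
    "thorax": (17300.0, 1.8, 1.0),
    "ureter_left": (109.0, 2.85, 1.6),
    "ureter_right": (106.0, 6.5, 3.7),
}

#: Lesion cast concentrations (kBq/mL) -> nominal ratio vs 1.8 kBq/mL background.
LESION_CONCENTRATIONS = {7.2: 4.0, 28.8: 16.0, 57.6: 32.0}

#: Cast sphere diameters (mm).
LESION_DIAMETERS_MM = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 12.0, 14.0, 16.0)

#: First dynamic scan protocol: (frame duration s, background kBq/mL,
#: printed lesion-to-background ratio).  The 57.6 kBq/mL lesions are
#: effectively constant while the ¹⁸F background decays.
SCAN1_PROTOCOL = (
    (60.0, 4.41, 13.2),
    (72.0, 3.6, 16.1),
    (87.0, 2.9, 19.6),
    (105.0, 2.4, 24.0),
    (127.0, 2.0, 29.3),
    (153.0, 1.6, 36.0),
    (185.0, 1.3, 44.2),
    (223.0, 1.1, 54.6),
    (270.0, 0.85, 67.7),
    (326.0, 0.68, 84.5),
    (394.0, 0.54, 106.0),
    (476.0, 0.43, 134.1),
    (575.0, 0.34, 171.3),
    (695.0, 0.26, 221.4),
    (839.0, 0.20, 290.0),
)


def lesion_ring(
    diameters=LESION_DIAMETERS_MM,
    concentration: float = 57.6,
    ring_radius: float = 50.0,
    z: float = 0.0,
    prefix: str = "les",
) -> list[LesionSpec]:
    """Co-planar lesions evenly spaced on a circle of given radius (mm)."""
    n = len(diameters)
    lesions = []
    for k, d in enumerate(diameters):
        phi = 2.0 * math.pi * k / n
        center = (ring_radius * math.cos(phi), ring_radius * math.sin(phi), z)
        lesions.append(
            LesionSpec(
                id=f"{prefix}_{d:g}mm",
                center=center,
                diameter=float(d),
                concentration=concentration,
                isotope=NA22,
            )
        )
    return lesions


def _ureter_path(x: float, z_top: float, z_bottom: float, radius: float, volume_ml: float):
    """L-shaped tube of the requested volume: vertical drop then medial run.

    The tubing is fatter than real ureters so the design volume fits inside
    the body outline; only volume and concentration matter downstream.
    """
    caps_ml = 4.0 / 3.0 * math.pi * radius**3 / 1000.0
    total_len = (volume_ml - caps_ml) * 1000.0 / (math.pi * radius**2)
    drop = min(z_top - z_bottom, total_len - 20.0)
    run = max(total_len - drop, 20.0)
    sign = 1.0 if x >= 0 else -1.0
    points = (
        (x, 0.0, z_top),
        (x, 0.0, z_top - drop),
        (x - sign * run, 0.0, z_top - drop),
    )
    return TubePath(points=points, radius=radius)


def probe_iq_pelvis(
    spacing=DEFAULT_SPACING,
    lesions: list[LesionSpec] | None = None,
    background: float = BACKGROUND_KBQ_ML,
    texture_sigma: float = 0.0,
) -> PhantomSpec:
    """Digital pelvis section: 9000-mL body, 440-mL bladder, two ureters.

    Lesion layout defaults to the nine cast diameters at 57.6 kBq/mL on a
    50-mm ring in the central plane (bladder and ureters are placed in the
    upper half, away from the ring plane).
    """
    # Body: elliptical cylinder, volume incl. organs ≈ 9000 + 440 + 215 mL
    rx, ry = 160.0, 110.0
    organ_ml = (
        COMPARTMENT_TABLE["bladder"][0]
        + COMPARTMENT_TABLE["ureter_left"][0]
        + COMPARTMENT_TABLE["ureter_right"][0]
    )
    body_ml = COMPARTMENT_TABLE["pelvis"][0] + organ_ml
    height = body_ml * 1000.0 / (math.pi * rx * ry)  # ≈ 174 mm

    bladder_r = (3.0 * COMPARTMENT_TABLE["bladder"][0] * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    z_top = height / 2.0 - 12.0
    bladder_center = (0.0, 55.0, z_top - bladder_r)

    compartments = [
        CompartmentSpec(
            name="pelvis",
            geometry=Cylinder(center=(0.0, 0.0, 0.0), radii=(rx, ry), height=height),
            concentration=background,
            isotope=F18,
        ),
        CompartmentSpec(
            name="bladder",
            geometry=Sphere(center=bladder_center, diameter=2.0 * bladder_r),
            concentration=COMPARTMENT_TABLE["bladder"][1],
            isotope=F18,
        ),
        CompartmentSpec(
            name="ureter_left",
            geometry=_ureter_path(-120.0, z_top, z_top - 110.0, 14.0,
                                  COMPARTMENT_TABLE["ureter_left"][0]),
            concentration=COMPARTMENT_TABLE["ureter_left"][1],
            isotope=F18,
        ),
        CompartmentSpec(
            name="ureter_right",
            geometry=_ureter_path(120.0, z_top, z_top - 110.0, 14.0,
                                  COMPARTMENT_TABLE["ureter_right"][0]),
            concentration=COMPARTMENT_TABLE["ureter_right"][1],
            isotope=F18,
        ),
    ]

    if lesions is None:
        lesions = lesion_ring(z=-height / 4.0)

    nx = int(math.ceil(2.0 * (rx + 5.0) / spacing[0]))
    ny = int(math.ceil(2.0 * (ry + 5.0) / spacing[1]))
    nz = int(math.ceil((height + 5.0) / spacing[2]))
    grid = VoxelGrid.centered((nx, ny, nz), spacing)
    return PhantomSpec(
        grid=grid,
        compartments=compartments,
        lesions=lesions,
        reference_time=0.0,
        texture_sigma=texture_sigma,
    )


def liver_lung_section(
    spacing=DEFAULT_SPACING,
    background: float = BACKGROUND_KBQ_ML,
) -> PhantomSpec:
    """Thorax section with liver and lungs at the design concentrations.

    Volumes match the design table within 10 %; geometry is a schematic
    ellipsoid arrangement inside an elliptical-cylinder body.
    """
    rx, ry = 180.0, 115.0
    organ_ml = (
        COMPARTMENT_TABLE["liver"][0]
        + COMPARTMENT_TABLE["lung_left"][0]
        + COMPARTMENT_TABLE["lung_right"][0]
    )
    body_ml = COMPARTMENT_TABLE["thorax"][0] + organ_ml
    height = body_ml * 1000.0 / (math.pi * rx * ry)

    def _ellipsoid_for(volume_ml, a, b, center):
        c = volume_ml * 1000.0 * 3.0 / (4.0 * math.pi * a * b)
        return Ellipsoid(center=center, semiaxes=(a, b, c))

    compartments = [
        CompartmentSpec(
            name="thorax",
            geometry=Cylinder(center=(0.0, 0.0, 0.0), radii=(rx, ry), height=height),
            concentration=background,
            isotope=F18,
        ),
        CompartmentSpec(
            name="liver",
            geometry=_ellipsoid_for(COMPARTMENT_TABLE["liver"][0], 100.0, 70.0,
                                    (60.0, 10.0, -height / 4.0)),
            concentration=COMPARTMENT_TABLE["liver"][1],
            isotope=F18,
        ),
        CompartmentSpec(
            name="lung_left",
            geometry=_ellipsoid_for(COMPARTMENT_TABLE["lung_left"][0], 55.0, 45.0,
                                    (-75.0, -10.0, height / 5.0)),
            concentration=COMPARTMENT_TABLE["lung_left"][1],
            isotope=F18,
        ),
        CompartmentSpec(
            name="lung_right",
            geometry=_ellipsoid_for(COMPARTMENT_TABLE["lung_right"][0], 60.0, 48.0,
                                    (75.0, -10.0, height / 5.0)),
            concentration=COMPARTMENT_TABLE["lung_right"][1],
            isotope=F18,
        ),
    ]
    nx = int(math.ceil(2.0 * (rx + 5.0) / spacing[0]))
    ny = int(math.ceil(2.0 * (ry + 5.0) / spacing[1]))
    nz = int(math.ceil((height + 5.0) / spacing[2]))
    grid = VoxelGrid.centered((nx, ny, nz), spacing)
    return PhantomSpec(grid=grid, compartments=compartments, lesions=[])
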