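import dataclasses

import pytest
from hypothesis import settings

import limbstruct as ls

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")

#: A diverse grid of hollow-ellipse specs: circular/elongated outer contours,
#: solid, concentric, eccentric canals, and in-plane rotations. pixel_size is
#: a placeholder; tests substitute the resolution they need.
ELLIPSE_GRID = [
    ls.EllipseSectionSpec(15, 10, 9, 6, pixel_size=1),
    ls.EllipseSectionSpec(10, 10, 0, 0, pixel_size=1),
    ls.EllipseSectionSpec(10, 10, 6, 6, dy=1, pixel_size=1),
    ls.EllipseSectionSpec(12, 9, 6, 4, dx=1.5, dy=-1, pixel_size=1),
    ls.EllipseSectionSpec(14, 9, 8, 5, rotation_deg=30, pixel_size=1),
    ls.EllipseSectionSpec(14, 9, 8, 5, dx=2, dy=1, rotation_deg=-55, pixel_size=1),
    ls.EllipseSectionSpec(8, 13, 4, 8, rotation_deg=75, pixel_size=1),
    ls.EllipseSectionSpec(9, 9, 5, 5, dx=-1.5, dy=0.5, rotation_deg=10, pixel_size=1),
    ls.EllipseSectionSpec(16, 7, 10, 3, rotation_deg=-20, pixel_size=1),
    ls.EllipseSectionSpec(11, 11, 7, 4, dx=0.5, dy=-2, rotation_deg=40, pixel_size=1),
]

PROPERTY_KEYS = ("TA", "CA", "Ix", "Iy", "Imax", "Imin", "J", "Zx", "Zy", "Zp")


def at_resolution(spec, pixel_size):
    return dataclasses.replace(spec, pixel_size=pixel_size)


@pytest.fixture(scope="session")
def hollow_ellipse_mask():
    """The reference hollow ellipse (15x10 / 9x6 mm) at 0.05 mm pixels."""
    return ls.render_section(ls.EllipseSectionSpec(15, 10, 9, 6, pixel_size=0.05))
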