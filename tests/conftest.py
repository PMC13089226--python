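import numpy as np
import pytest

from plesiomass.ribcage_geometry import SectionKind, SectionSpec, build_cross_section


@pytest.fixture
def circle_contour():
    """Unit circle (1024-gon), bottom-anchored at y = 0."""
    return build_cross_section(
        SectionSpec(kind=SectionKind.skull, total_width=2.0,
                    dorsal_height=1.0, ventral_height=1.0,
                    dorsal_exponent=2.0, ventral_exponent=2.0),
        1024,
    )


def make_circle(r: float, n: int = 1024):
    """Circle of radius r with its ventral point at y = 0."""
    return build_cross_section(
        SectionSpec(kind=SectionKind.skull, total_width=2.0 * r,
                    dorsal_height=r, ventral_height=r,
                    dorsal_exponent=2.0, ventral_exponent=2.0),
        n,
    )


def make_ellipse(a: float, b: float, n: int = 1024):
    """Ellipse with semi-axes (a, b), ventral point at y = 0."""
    return build_cross_section(
        SectionSpec(kind=SectionKind.skull, total_width=2.0 * a,
                    dorsal_height=b, ventral_height=b,
                    dorsal_exponent=2.0, ventral_exponent=2.0),
        n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
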