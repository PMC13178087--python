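import numpy as np
import pytest

from mitomorph import (
    AnnotationScene,
    MembraneSet,
    Polygon,
    Polyline,
)


def square(x0, y0, side, label=None):
    return Polygon(
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)],
        label=label,
    )


def random_convex_polygon(rng, n_points=12, radius=10.0, center=(0.0, 0.0)):
    """Random convex polygon via the convex hull of random points."""
    from scipy.spatial import ConvexHull

    pts = rng.uniform(-radius, radius, (n_points, 2)) + np.asarray(center)
    hull = ConvexHull(pts)
    return Polygon(pts[hull.vertices])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def taim_scene():
    """10x10 interfibrillar region containing two disjoint 5x5 mitochondria
    -> TAIM exactly 50%."""
    return AnnotationScene(
        micrograph_id="m1",
        magnification=5000,
        interfibrillar_regions=[square(0, 0, 10, "region")],
        mitochondria=[square(0, 0, 5, "mito1"), square(5, 5, 5, "mito2")],
    )


@pytest.fixture
def membrane_31():
    """Outer square of perimeter 40 with one straight inner trace of length
    4000/31 -> OIMR exactly 31%."""
    inner_len = 4000.0 / 31.0
    return MembraneSet(
        mitochondrion_id="m1",
        outer=square(0, 0, 10, "outer"),
        inner_traces=[Polyline([(0, 0), (inner_len, 0)], label="inner")],
    )


def membrane_with_oimr(oimr_pct, side=10.0, mid="m"):
    inner_len = 100.0 * 4 * side / oimr_pct
    return MembraneSet(
        mitochondrion_id=mid,
        outer=square(0, 0, side),
        inner_traces=[Polyline([(0, 0), (inner_len, 0)])],
    )


def membrane_scene(oimr_values, micrograph_id="s"):
    return AnnotationScene(
        micrograph_id=micrograph_id,
        magnification=15000,
        membrane_sets=[
            membrane_with_oimr(v, mid=f"{micrograph_id}_m{i}")
            for i, v in enumerate(oimr_values)
        ],
    )
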