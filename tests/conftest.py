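import numpy as np
import pytest

from anchor3d import (QuadMesh, SiteConfig, build_final_model, layout_strip,
                      reference_template)
from anchor3d.template import NORMAL, Template2D


@pytest.fixture(scope="session")
def cube():
    """Unit cube as a closed, outward-oriented quad mesh."""
    v = np.array([[0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
                  [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    f = [(0, 1, 2, 3), (7, 6, 5, 4), (1, 0, 4, 5),
         (2, 1, 5, 6), (3, 2, 6, 7), (0, 3, 7, 4)]
    return QuadMesh(v, f)


@pytest.fixture(scope="session")
def template():
    return reference_template()


@pytest.fixture(scope="session")
def model(template):
    """Final generic model built with the packaged per-site counts."""
    return build_final_model(template)


@pytest.fixture(scope="session")
def normal_model(template):
    """Model with every site at the basic 4-primitive count."""
    return build_final_model(template, SiteConfig({NORMAL: 4}))


def rectangle_template(length=10.0, width=2.0, n_side=12):
    """Straight all-normal band: a minimal valid template for layout tests."""
    xs = np.linspace(0.0, length, n_side)
    bot = np.stack([xs, np.zeros(n_side)], axis=1)
    top = np.stack([xs[::-1], np.full(n_side, width)], axis=1)
    outline = np.vstack([bot, top])
    medial = np.stack([np.linspace(0.2, length - 0.2, 20),
                       np.full(20, width / 2)], axis=1)
    return Template2D("rectangle", outline, medial)


@pytest.fixture()
def rect_template():
    return rectangle_template()
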