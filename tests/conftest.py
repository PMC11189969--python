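import numpy as np
import pytest

import footmorph as fm


@pytest.fixture(scope="session")
def template():
    """Default synthetic template bundle (642-vertex surface)."""
    return fm.make_template(fm.FixtureSpec())


@pytest.fixture(scope="session")
def benchmark_field():
    """Ground-truth deformation: mild anisotropic affine + one 5 mm arch bump."""
    affine = fm.AffineTransform(np.diag([1.06, 1.03, 0.97, 1.0]))
    return fm.DeformationField(affine=affine,
                               bumps=(((10.0, -20.0, 15.0), 40.0, (0.0, 0.0, 5.0)),))


@pytest.fixture(scope="session")
def benchmark(template, benchmark_field):
    """(template, deformed target bundle, true surface displacements)."""
    target, disp = fm.deform(template, benchmark_field)
    return template, target, disp


@pytest.fixture(scope="session")
def fine_benchmark(benchmark_field):
    """Higher-resolution benchmark (2562 vertices) for 1000-sample RBFST runs."""
    tpl = fm.make_template(fm.FixtureSpec(subdivisions=4))
    target, disp = fm.deform(tpl, benchmark_field)
    return tpl, target, disp
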