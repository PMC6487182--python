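import numpy as np
import pytest

from diatomid import synthetic


@pytest.fixture(scope="session")
def catalog8():
    return synthetic.make_catalog(8, seed=1)


@pytest.fixture(scope="session")
def ellipse_params():
    return synthetic.SpeciesParams(
        class_id=0,
        shape_family=synthetic.ShapeFamily.ELLIPSE,
        base_length=240.0,
        base_width=80.0,
        striae_period=8.0,
        striae_contrast=0.25,
    )


@pytest.fixture(scope="session")
def clean_ellipse_sample(ellipse_params):
    """Noise-free ellipse valve: axes 240 x 80 px, striae period 8 px."""
    return synthetic.render_valve(
        ellipse_params, noise_sigma=0.0, illum_gradient=0.0, seed=0
    )


@pytest.fixture(scope="session")
def noisy_ellipse_sample(ellipse_params):
    """Ellipse valve with 3% additive noise and default illumination ramp."""
    return synthetic.render_valve(
        ellipse_params, noise_sigma=0.03, illum_gradient=0.10, seed=7
    )


def disc_mask(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n] - (radius + pad)
    return (xx ** 2 + yy ** 2) <= radius ** 2
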