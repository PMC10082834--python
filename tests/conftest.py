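import hypothesis
import numpy as np
import pytest

from petquant import Lesion, PhantomSpec, make_phantom

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("deterministic")

#: standard coarse user box for the 64^3 fixtures (lesion centered at 16 mm)
BBOX64 = ((8, 56), (8, 56), (8, 56))


def sphere_spec(radius_mm, *, psf=0.0, background=0.0, suv=1.0, noise="none",
                noise_param=0.0, seed=0, shape=(64, 64, 64)):
    center = tuple(0.5 * n / 2 for n in shape)
    return PhantomSpec(
        lesions=(Lesion(center, radius_mm, suv),),
        shape=shape,
        background_suv=background,
        psf_sigma_mm=psf,
        noise_model=noise,
        noise_param=noise_param,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def crisp_sphere():
    """Unblurred, noiseless 4 mm-radius sphere (SUV 1 on 0) plus truth."""
    img, truth = make_phantom(sphere_spec(4.0))
    return img, truth


@pytest.fixture(scope="session")
def blurred_sphere():
    """Same sphere degraded by the default 0.8 mm PSF."""
    img, truth = make_phantom(sphere_spec(4.0, psf=0.8))
    return img, truth
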