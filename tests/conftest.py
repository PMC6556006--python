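import numpy as np
import pytest

from npq import ROIPolygon, StainModel, deconvolve, rgb_to_od, stain_to_intensity
from npq.simulate import ImageSimParams, render_ihc_image


@pytest.fixture(scope="session")
def stain_model():
    return StainModel()


def dab_intensity_of(image):
    """Full deconvolution pipeline: RGB image → DAB pseudo-intensity map."""
    return stain_to_intensity(deconvolve(rgb_to_od(image)).channel("dab"))


def full_frame_roi(shape):
    return ROIPolygon.rectangle(0, 0, shape[1], shape[0])


@pytest.fixture()
def rendered_three_disks():
    """Three well-separated planted disks (50 µm², DAB intensity ≈ 150)."""
    from npq.simulate import PlantedObject

    centers = [(60.0, 60.0), (180.0, 60.0), (120.0, 180.0)]
    objs = tuple(PlantedObject(c, "disk", 50.0, 0.2304) for c in centers)
    params = ImageSimParams(seed=11, shape=(240, 240), objects=objs)
    image, truth = render_ihc_image(params)
    return image, truth
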