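import numpy as np
import pytest

from annoret.core import AnnotationSet, RoiTag, SphericalROI
from annoret.synth import PhantomParams


def make_set(annotator_id, rois):
    """AnnotationSet from (case_id, centroid, diameter) tuples."""
    out = AnnotationSet(annotator_id=annotator_id)
    for case_id, centroid, diameter in rois:
        out.add(
            SphericalROI(
                case_id=case_id,
                centroid=centroid,
                diameter=diameter,
                annotator_id=annotator_id,
                tag=RoiTag.UNKNOWN,
            )
        )
    return out


@pytest.fixture
def chest_params():
    return PhantomParams.for_task("chest")


@pytest.fixture
def brain_params():
    return PhantomParams.for_task("brain")


@pytest.fixture
def small_chest_params():
    return PhantomParams.for_task("chest", grid_size=(48, 48, 48))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
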