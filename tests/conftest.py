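import numpy as np
import pandas as pd
import pytest

import capdyn as cd

#: Reduced study used throughout the suite: 8 subjects, three 40-frame
#: blocks, ~320 gray-matter voxels, five latent states (one edge artifact).
SMALL = dict(n_subjects=8, frames_per_block=40, grid=(11, 11, 9))


@pytest.fixture(scope="session")
def small_study():
    return cd.simulate_study(cd.StudyConfig(seed=1, **SMALL))


@pytest.fixture(scope="session")
def small_frames(small_study):
    return cd.extract_blocks(small_study.images, small_study.timing,
                             small_study.mask_img)


def metrics_from_sequence(labels, k, subject="sub-001", condition="RUM"):
    """Run temporal_metrics on a bare label sequence."""
    labels = np.asarray(labels)
    index = pd.DataFrame({"subject": subject, "condition": condition,
                          "position": np.arange(labels.size)})
    return cd.temporal_metrics(labels, index, k)
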