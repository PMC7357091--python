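import dataclasses

import numpy as np
import pytest

from discmri import phantom


def uniform_tables(t2=133.9, t2w_si=368.0, water_pct=88.1, sd=0.0):
    """Parameter tables whose whole-disc group cells are all identical."""
    return dataclasses.replace(
        phantom.default_parameter_tables(),
        whole_by_group={
            "t2": ((t2,) * 4, (sd,) * 4),
            "t2w": ((t2w_si,) * 4, (sd,) * 4),
            "dixon": ((water_pct,) * 4, (sd,) * 4),
        },
    )


def single_disc(t2=133.9, t2w_si=368.0, water_pct=88.1, seed=0):
    """One uniform-parameter disc with its label volume and ROI."""
    cfg = phantom.CohortConfig(
        subjects_per_group=(1, 0, 0, 0),
        levels=("L4/L5",),
        uniform_discs=True,
        parameter_tables=uniform_tables(t2, t2w_si, water_pct),
        seed=seed,
    )
    discs = phantom.build_cohort(cfg)
    params = phantom.multiecho_params()
    labels = phantom.rasterize_subject(discs, params)
    roi = phantom.make_disc_rois(discs)[0]
    return discs, labels, roi, params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_disc_phantom():
    return single_disc()
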