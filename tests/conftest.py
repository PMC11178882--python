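"""Shared fixtures: small synthetic movies generated at test time."""

import numpy as np
import pytest

from scanvolt.synthetic import (AcquisitionConfig, CellModel,
                                IlluminationSpec, make_protocol, render_movie)


@pytest.fixture(scope="session")
def acq_100hz():
    return AcquisitionConfig(frame_rate_hz=100.0, pixel_size_um=0.5,
                             roi_shape=(64, 64))


@pytest.fixture(scope="session")
def single_cell():
    return CellModel(centroid_um=(16.0, 16.0), soma_diameter_um=14.0,
                     expression_F0=100.0)


@pytest.fixture(scope="session")
def p1_movie(acq_100hz, single_cell):
    """Protocol-1 movie (three 100 mV steps, 3 s continuous light)."""
    movie, truth = render_movie([single_cell], make_protocol(1),
                                IlluminationSpec(), acq_100hz, seed=1)
    return movie, truth


@pytest.fixture(scope="session")
def p1_movie_clean(acq_100hz, single_cell):
    """Protocol-1 movie without background autofluorescence."""
    movie, truth = render_movie([single_cell], make_protocol(1),
                                IlluminationSpec(), acq_100hz, seed=1,
                                background=0.0)
    return movie, truth


@pytest.fixture(scope="session")
def p5_movie(single_cell):
    """Short protocol-5 movie (random APs, continuous light) at 500 Hz."""
    acq = AcquisitionConfig(frame_rate_hz=500.0, pixel_size_um=0.5,
                            roi_shape=(64, 64))
    protocol = make_protocol(5, seed=4, duration_ms=6000.0)
    cell = CellModel(centroid_um=(16.0, 16.0), soma_diameter_um=14.0,
                     expression_F0=150.0)
    movie, truth = render_movie([cell], protocol, IlluminationSpec(),
                                acq, seed=5)
    return movie, truth
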