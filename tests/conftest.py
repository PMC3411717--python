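import warnings

import numpy as np
import pandas as pd
import pytest

from exonsplice.arraymodel import (
    EventType,
    IntensityMatrix,
    ProbeAnnotation,
    ProbeSetAnnotation,
    SampleDesign,
)
from exonsplice.simulate import balanced_noiseless_cassette, make_design

# PLIER's iteration-cap warning is informational; keep test output clean
warnings.filterwarnings(
    "ignore", message="PLIER fit did not converge", category=UserWarning
)


@pytest.fixture
def design():
    return make_design()


@pytest.fixture
def tiny_annotation():
    """Two transcript clusters (3 + 2 probe sets), plus two background probes."""
    probesets = [
        ProbeSetAnnotation("ps1", "tc1", 1, 3, 1, 1, False),
        ProbeSetAnnotation("ps2", "tc1", 2, 3, 1, 1, True),
        ProbeSetAnnotation("ps3", "tc1", 3, 3, 1, 1, False),
        ProbeSetAnnotation("ps4", "tc2", 1, 2, 1, 2, False),
        ProbeSetAnnotation("ps5", "tc2", 1, 2, 2, 2, False,
                           known_event=EventType.CASSETTE),
    ]
    probes = []
    for ps in probesets:
        for j in (1, 2):
            probes.append(
                ProbeAnnotation(f"{ps.probeset_id}_p{j}", ps.probeset_id, 12, False)
            )
    probes.append(ProbeAnnotation("bg1", None, 10, True))
    probes.append(ProbeAnnotation("bg2", None, 14, True))
    return probes, probesets


@pytest.fixture
def tiny_intensities(tiny_annotation, design):
    probes, _ = tiny_annotation
    rng = np.random.default_rng(42)
    vals = rng.uniform(50, 500, size=(len(probes), len(design)))
    return IntensityMatrix(
        pd.DataFrame(
            vals,
            index=[p.probe_id for p in probes],
            columns=[d.sample_id for d in design],
        )
    )


@pytest.fixture(scope="session")
def balanced_fixture():
    """Shared noiseless exact fixture: (probes, probesets, design, mat, truth)."""
    return balanced_noiseless_cassette(n_pairs=2, n_null_tcs=8, n_de_pairs=2)
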