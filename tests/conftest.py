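import math

import numpy as np
import pytest

from csmt import (
    MeasurementSet,
    get_preset,
    signal_bssfp,
    signal_spgr,
)

PAPER_SPGR_DEG = (6, 8, 10, 12, 14, 16)
PAPER_BSSFP_DEG = (15, 25, 35, 45, 55, 65, 25, 55)
PAPER_BSSFP_PHI = (math.pi,) * 6 + (0.0, 0.0)


@pytest.fixture(scope="session")
def wm():
    """White-matter 2-pool preset used throughout the numerical studies."""
    return get_preset("gloor_wm")


def single_pool_measurements(
    m0=1.0,
    t1=0.387,
    t2=0.0813,
    dw0=0.0,
    tr=7e-3,
    m0_phase=0.0,
) -> MeasurementSet:
    """Noiseless single-pool signals on the reference protocol geometry."""
    records = []
    for a in PAPER_SPGR_DEG:
        fl = math.radians(a)
        records.append(("SPGR", fl, tr, 0.0, complex(signal_spgr(m0, t1, fl, tr))))
    m0c = m0 * np.exp(1j * m0_phase)
    for a, phi in zip(PAPER_BSSFP_DEG, PAPER_BSSFP_PHI):
        fl = math.radians(a)
        records.append(
            ("bSSFP", fl, tr, phi, signal_bssfp(m0c, t1, t2, dw0, fl, tr, phi))
        )
    return MeasurementSet.from_records(records)
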