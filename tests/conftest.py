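import numpy as np
import pytest

from qcmd_adhesion import FluidProperties, OvertoneShiftSet, SensorParams


@pytest.fixture
def sensor():
    return SensorParams()


@pytest.fixture
def fluid():
    return FluidProperties()


def make_shifts(df_eq, dd_eq=None, df_sd=0.0, dd_sd=0.0,
                overtones=(3, 5, 7, 9, 11, 13)):
    """Build an OvertoneShiftSet from plain sequences/scalars."""
    df_eq = np.asarray(df_eq, dtype=float)
    k = len(overtones)
    dd = np.zeros(k) if dd_eq is None else np.asarray(dd_eq, dtype=float)
    return OvertoneShiftSet(
        overtones=overtones,
        df_eq=df_eq,
        dd_eq=dd,
        df_sd=np.broadcast_to(np.asarray(df_sd, dtype=float), (k,)).copy(),
        dd_sd=np.broadcast_to(np.asarray(dd_sd, dtype=float), (k,)).copy(),
    )
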