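import numpy as np
import pytest

from tcsleep.numerics import SimGrid
from tcsleep.thalamus import ThalamicParams, simulate_thalamus
from tcsleep.cortex.transfer import build_transfer_table


@pytest.fixture(scope="session")
def transfer_table():
    """Default transfer table (disk-cached after the first build)."""
    return build_transfer_table()


@pytest.fixture(scope="session")
def region1_run():
    """Noise-free thalamic run in spindling region I (65 s, 5 s transient)."""
    out = simulate_thalamus(ThalamicParams(), SimGrid(duration=65000.0))
    post = out["t"] > 5000.0
    return {"r_TCR": out["r_TCR"][post], "r_TRN": out["r_TRN"][post],
            "fs": 100.0, "full": out}


@pytest.fixture(scope="session")
def fig10_loop_run():
    """120 s full-loop run in the UP-dominant (short UP states) regime."""
    from tcsleep.cortex.model import CorticalParams
    from tcsleep.network import LoopConfig, simulate_loop
    cx = CorticalParams(mu_E_drift=0.61, mu_I_drift=0.4,
                        sigma_E=0.05, sigma_I=0.05)
    th = ThalamicParams(g_LK=0.033)
    loop = LoopConfig(N_ctx_thal=1.2, N_thal_ctx=0.12, sigma_TCR=0.005)
    out = simulate_loop(cx, th, loop, SimGrid(duration=120000.0, seed=42))
    post = out["t"] > 5000.0
    return {"r_E": out["r_E"][post], "r_TCR": out["r_TCR"][post], "fs": 100.0}
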