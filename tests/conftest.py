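from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from outgrowth.curves import ODCurve

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def exp_curve():
    """Factory for noise-free exponential curves: od = x0 * 2**(t/delta)."""

    def _make(
        delta: float = 1.5,
        x0: float = 0.05,
        background: float = 0.0,
        step: float = 0.5,
        duration: float = 24.0,
        lag: float = 0.0,
    ) -> ODCurve:
        t = np.arange(0.0, duration + step / 2, step)
        od = x0 * 2.0 ** ((t - lag) / delta)
        return ODCurve(times=t, od_raw=od + background, background=background)

    return _make


def run_csv(n_times: int = 49, n_wells: int = 3, header: bool = True) -> str:
    """Minimal run-file text on a 30-minute grid with distinct OD values."""
    lines = []
    if header:
        lines.append("Time," + ",".join(f"Well {j+1}" for j in range(n_wells)))
    for i in range(n_times):
        total = i * 1800
        h, rem = divmod(total, 3600)
        stamp = f"{h:02d}:{rem // 60:02d}:{rem % 60:02d}"
        ods = ",".join(f"{0.1 + 0.01 * i + 0.001 * j:.4f}" for j in range(n_wells))
        lines.append(f"{stamp},{ods}")
    return "\n".join(lines) + "\n"
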