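"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from iconqa import GatingConfig, MotionTrace, make_component_table


@pytest.fixture(scope="session")
def paper_components():
    return make_component_table("paper_table2")


@pytest.fixture
def gating():
    return GatingConfig()


def random_piecewise_trace(rng: np.random.Generator, n: int = 30,
                           radial_scale: float = 3.0) -> MotionTrace:
    """A random irregular piecewise-linear trace with mixed treating state."""
    t = np.cumsum(rng.uniform(0.1, 30.0, n))
    treating = rng.random(n) < 0.8
    treating[0] = True  # guarantee at least one treating interval
    return MotionTrace(
        t_s=t,
        xyz_mm=rng.normal(0.0, 1.0, (n, 3)),
        radial_mm=rng.uniform(0.0, radial_scale, n),
        treating=treating,
    )


def oracle_auc_radial(trace: MotionTrace, gating: GatingConfig) -> tuple[float, float]:
    """Brute-force truncated AUC of the radial curve: refine each treating
    interval's grid (inserting the exact threshold crossing), clip pointwise,
    and integrate with ``np.trapezoid``.  Independent of the closed-form
    per-interval implementation.  Returns (mean_radial, treating_duration)."""
    thr = gating.threshold_mm
    t, r = trace.t_s, trace.radial_mm
    area = 0.0
    duration = 0.0
    for i in range(len(trace) - 1):
        if not trace.treating[i]:
            continue
        t0, t1, r0, r1 = t[i], t[i + 1], r[i], r[i + 1]
        grid = list(np.linspace(t0, t1, 64))
        if (r0 - thr) * (r1 - thr) < 0:  # insert exact crossing
            grid.append(t0 + (thr - r0) / (r1 - r0) * (t1 - t0))
        grid = np.array(sorted(grid))
        vals = np.minimum(np.interp(grid, [t0, t1], [r0, r1]), thr)
        area += float(np.trapezoid(vals, grid))
        duration += float(t1 - t0)
    if duration == 0:
        raise ValueError("no treating time")
    return area / duration, duration
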