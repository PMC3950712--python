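"""Synthetic UV-melting datasets with the statistical structure the analysis assumes.

The generator emulates the optical-melting experiment the thermodynamic
tables derive from: nine total-strand concentrations log-spaced over
10⁻⁶–10⁻³ M, absorbance read every 1 °C from 0 to 90 °C (1 °C/min ramp),
two-state curves with linear baselines (~20% hyperchromicity on a
normalized absorbance scale) and additive, seed-controlled Gaussian
absorbance noise.  What it does *not* model: instrument drift, baseline
curvature, heat-capacity effects, or the two-transition melt of the
non-two-state outlier duplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .melt import Baselines, MeltCurve, MeltingDataset, TwoStateParams, simulate_curve

#: default baselines: ds below ss with ~20% hyperchromicity on a unit scale
DEFAULT_BASELINES = Baselines(m_ds=3e-4, b_ds=1.0, m_ss=5e-4, b_ss=1.22)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic nine-concentration melting experiment."""

    params: TwoStateParams = TwoStateParams(-80.0, -220.0)
    n_concentrations: int = 9
    ct_range: tuple[float, float] = (1e-6, 1e-3)
    grid_c: tuple[float, float, float] = (0.0, 90.0, 1.0)  # start, stop, step (°C)
    baselines: Baselines = DEFAULT_BASELINES
    noise_sd: float = 0.002  # absorbance units, on the ~unit-amplitude scale
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_concentrations < 3:
            raise ValueError("need at least 3 concentrations")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0 < self.ct_range[0] < self.ct_range[1]):
            raise ValueError("invalid concentration range")

    def with_(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


def concentration_series(spec: SyntheticSpec) -> np.ndarray:
    return np.geomspace(spec.ct_range[0], spec.ct_range[1], spec.n_concentrations)


def temperature_grid(spec: SyntheticSpec) -> np.ndarray:
    start, stop, step = spec.grid_c
    return np.arange(start, stop + 0.5 * step, step)


def generate_dataset(spec: SyntheticSpec) -> MeltingDataset:
    """One noisy :class:`MeltCurve` per concentration; same seed, same bytes."""
    rng = np.random.default_rng(spec.seed)
    grid = temperature_grid(spec)
    curves = []
    for i, ct in enumerate(concentration_series(spec)):
        clean = simulate_curve(spec.params, ct, spec.baselines, grid, curve_id=f"c{i:02d}")
        noisy = clean.absorbances + rng.normal(0.0, spec.noise_sd, size=grid.shape) \
            if spec.noise_sd > 0 else clean.absorbances
        curves.append(
            MeltCurve(grid.copy(), noisy, ct, curve_id=f"c{i:02d}", baselines=spec.baselines)
        )
    return MeltingDataset(curves, name=f"synthetic(seed={spec.seed})")
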