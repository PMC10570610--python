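import numpy as np
import pandas as pd
import pytest

from thermoscreen.scan import CameraModel, ScanProtocol, TemperatureCurve
from thermoscreen.simulate import TissueThermalParams, thermal_response


@pytest.fixture
def protocol():
    return ScanProtocol()  # 10 s heat, 40 s cool, 10 Hz, 5 baseline frames


@pytest.fixture
def short_protocol():
    """Fast protocol for rendering-heavy tests (3 s scan, 35 frames)."""
    return ScanProtocol(heat_duration=1.0, cool_duration=2.0, frame_rate=10.0, baseline_frames=5)


@pytest.fixture
def small_camera():
    return CameraModel(height=30, width=40, noise_sd=0.05)


def exp_cooling_curve(
    protocol: ScanProtocol,
    baseline: float = 30.0,
    amplitude: float = 2.0,
    cool_rate: float = 0.1,
    heat_rate: float = 0.35,
) -> TemperatureCurve:
    """Noiseless curve whose cooling excess is exactly amplitude*exp(-k*t)."""
    gain = amplitude / (1.0 - np.exp(-heat_rate * protocol.heat_duration))
    params = TissueThermalParams(baseline, gain, heat_rate, cool_rate)
    return thermal_response(params, protocol)


def synthetic_feature_table(
    n: int,
    seed: int,
    n_noise: int = 8,
    effect: float = 0.08,
    signal_sd: float = 0.03,
    noise_sd: float = 1.0,
    prevalence: float = 0.25,
    signal_name: str = "cool_rate_diff",
) -> pd.DataFrame:
    """Feature table where only one column carries class signal.

    Built directly in feature space (no curve simulation) so classifier
    behaviour can be probed quickly at any n.
    """
    rng = np.random.default_rng(seed)
    n_pos = max(1, int(round(prevalence * n)))
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(y)
    data = {signal_name: y * effect + rng.normal(0.0, signal_sd, n)}
    for i in range(n_noise):
        data[f"noise_{i:02d}"] = rng.normal(0.0, noise_sd, n)
    df = pd.DataFrame(data, index=[f"L{i:04d}" for i in range(n)])
    df["diagnosis"] = np.where(y == 1, "malignant", "benign")
    df["dog_id"] = [f"D{i // 2:03d}" for i in range(n)]
    df["tumor_type"] = np.where(y == 1, "Mast cell tumor", "Lipoma")
    return df
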