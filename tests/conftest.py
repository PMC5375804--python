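import numpy as np
import pytest

from pulsetherm import (
    AcquisitionProtocol,
    DatasetConfig,
    MaterialThermalParams,
    ThermalVideo,
)


@pytest.fixture
def default_protocol():
    return AcquisitionProtocol()  # 1/5/10/1 s at 30 fps


@pytest.fixture
def toy_protocol():
    """Tiny protocol (1/5/10/1 s at 1 fps -> 17 frames) for fast unit tests."""
    return AcquisitionProtocol(fps=1.0)


@pytest.fixture
def quiet_params():
    """Deterministic material: no jitter, no edge effect, no sample spread."""
    return MaterialThermalParams(
        ambient_temp=25.0, equilibrium_gain=50.0, tau_heat=2.0, tau_cool=4.0
    )


@pytest.fixture
def small_video(default_protocol):
    """A 6-frame constant-plus-gradient video with protocol metadata."""
    frames = np.linspace(20.0, 25.0, 6 * 4 * 5, dtype=np.float32).reshape(6, 4, 5)
    return ThermalVideo(
        frames=frames, fps=30.0,
        metadata={"class": "cotton", "protocol": default_protocol.to_dict()},
    )


def make_video(frames, protocol, **meta):
    return ThermalVideo(
        frames=np.asarray(frames, dtype=np.float32),
        fps=protocol.fps,
        metadata={"protocol": protocol.to_dict(), **meta},
    )


@pytest.fixture
def tiny_dataset_config(toy_protocol):
    """Two small, well-separated classes on 24x24 frames."""
    from pulsetherm import ClassSpec

    hot = MaterialThermalParams(
        equilibrium_gain=40.0, tau_heat=1.5, tau_cool=3.0,
        pixel_jitter_cv=0.03, sample_gain_cv=0.05, sample_tau_cv=0.05,
    )
    cold = MaterialThermalParams(
        equilibrium_gain=10.0, tau_heat=3.0, tau_cool=8.0,
        pixel_jitter_cv=0.03, sample_gain_cv=0.05, sample_tau_cv=0.05,
    )
    return DatasetConfig(
        class_specs=(
            ClassSpec("brown_leaves", "broad_leaf", (8, 12), hot),
            ClassSpec("seed_coats", "blob", (5, 8), cold),
        ),
        samples_per_class=3,
        protocol=AcquisitionProtocol(fps=2.0),
        frame_height=24,
        frame_width=24,
        noise_sd=0.045,
        seed=7,
    )
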