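import numpy as np
import pytest

from ivnirf import Kinematics, run_calibration
from ivnirf import simulate
from ivnirf.containers import LABEL_GUIDEWIRE, LABEL_TISSUE
from ivnirf.simulate import PhantomScene, TargetSpec


@pytest.fixture(scope="session")
def water_calibration():
    """Calibration fitted on the default noiseless water phantom
    (coefficients at their printed per-mm values)."""
    scene = simulate.calibration_scene()
    return run_calibration(simulate.simulate_calibration_phantom(scene))


@pytest.fixture(scope="session")
def water_calibration_um():
    """Same calibration under the per-um coefficient reading (x1000)."""
    scene = simulate.calibration_scene(unit_scale=1000.0)
    return run_calibration(simulate.simulate_calibration_phantom(scene))


def make_single_frame_scene(
    d_gw: float = 0.7,
    d_t: float = 0.3,
    cb: float = 3.4,
    cw: float = 0.9,
    tissue_concentration: float = 38.0,
) -> PhantomScene:
    """One-frame artery-like scene with fixed guidewire/tissue distances."""
    kin = Kinematics(length_mm=0.25, pullback_speed_mm_s=0.25, rpm=60.0)
    one = np.ones(1)
    gw = TargetSpec("GW", LABEL_GUIDEWIRE, (16, 16), d_gw * one, 50.0 * one)
    tissue = TargetSpec("T", LABEL_TISSUE, (128, 32), d_t * one,
                        tissue_concentration * one)
    return PhantomScene(
        kind="artery",
        targets=[gw, tissue],
        medium="blood",
        cw_true=cw,
        cb_true=cb,
        kinematics=kin,
    ).validate()
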