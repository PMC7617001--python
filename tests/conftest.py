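import numpy as np
import pytest
from hypothesis import settings

from pwmtms.neurons import default_bank
from pwmtms.waveforms import (
    DeviceConfig,
    PWMConfig,
    coil_current_from_voltage,
    synth_magstim_monophasic,
    synth_pwm_pulse,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def device_config():
    return DeviceConfig()


@pytest.fixture(scope="session")
def pwm_config():
    return PWMConfig()


@pytest.fixture(scope="session")
def magstim_waves(device_config):
    """Full-output monophasic pulse: (voltage, current)."""
    return synth_magstim_monophasic(device_config)


@pytest.fixture(scope="session")
def matched_pulses(device_config, pwm_config, magstim_waves):
    """Waveforms at matched peak coil voltage (1600 V): a dict with the
    conventional target, the PWM approximation and both coil currents."""
    v_full, _ = magstim_waves
    target = v_full.scaled(1600.0 / v_full.samples.max())
    plan, v_pwm = synth_pwm_pulse(target, pwm_config)
    return {
        "target": target,
        "plan": plan,
        "pwm_voltage": v_pwm,
        "magstim_current": coil_current_from_voltage(target, device_config),
        "ptms_current": coil_current_from_voltage(v_pwm, device_config),
    }


@pytest.fixture(scope="session")
def bank():
    return default_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
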