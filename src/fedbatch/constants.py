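"""Physical constants used by the temperature dependence of the kinetic rates.

These are fixed module-level constants, never fitted.
"""

BOLTZMANN_KB = 1.380649e-23  # J/K
PLANCK_H = 6.62607015e-34  # J*s
GAS_CONSTANT_R = 8.314462618  # J/(mol*K)

SECONDS_PER_HOUR = 3600.0

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(T_celsius):
    return T_celsius + CELSIUS_OFFSET
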