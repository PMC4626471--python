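"""Physical constants (SI)."""

import math

#: vacuum magnetic permeability, N/A^2
MU0 = 4.0e-7 * math.pi

#: Boltzmann constant, J/K (SI-exact)
KB = 1.380649e-23

#: default absolute temperature, K (body temperature)
BODY_TEMPERATURE = 310.0
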