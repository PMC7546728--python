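"""Hounsfield-unit conversions.

HU = 1000 * (mu - mu_water) / mu_water, with mu in 1/mm. The default water
attenuation corresponds to a monochromatic effective energy in the 50-60 keV
range used by the simulated system.
"""

from __future__ import annotations

import numpy as np

#: default water attenuation coefficient, 1/mm
MU_WATER = 0.02


def hu_to_mu(hu, mu_water: float = MU_WATER):
    """Convert Hounsfield units to linear attenuation (1/mm)."""
    return mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def mu_to_hu(mu, mu_water: float = MU_WATER):
    """Convert linear attenuation (1/mm) to Hounsfield units."""
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_water) / mu_water
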