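"""Print the calibrated background fixture.

Inverts the Thompson precision formula to find the Poisson background
rate at which a 350-photon localization (PSF sigma 102 nm, 160 nm
pixels) has exactly 32 nm precision, and verifies the round trip.

Usage: python scripts/calibrate_background.py
"""

import numpy as np

from rumposcope.localize import calibrate_background_rate, thompson_precision

rate = calibrate_background_rate(target_precision=32.0, photons=350.0,
                                 s=102.0, a=160.0)
check = thompson_precision(350.0, 102.0, 160.0, np.sqrt(rate))
print(f"background rate: {rate:.4f} photons/pixel/frame")
print(f"background noise (sqrt): {np.sqrt(rate):.4f} photons/pixel")
print(f"Thompson precision at 350 photons: {check:.6f} nm")
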