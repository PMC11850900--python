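"""The angular earth mover's distance between weighted peak sets.

The EMD normalizes each set's amplitudes to unit mass and moves mass
between orientations at cost arccos(|u.v|) in degrees; the value is the
total angular work separating two fODF peak configurations (0 = same
orientations, up to 90 = orthogonal everywhere).
"""

import numpy as np

from fodfsr.metrics import PeakSet, angular_emd

z = np.array([0.0, 0.0, 1.0])
x = np.array([1.0, 0.0, 0.0])
tilt30 = np.array([0.0, np.sin(np.radians(30)), np.cos(np.radians(30))])

one_z = PeakSet(z[None], np.array([1.0]))
one_tilt = PeakSet(tilt30[None], np.array([2.0]))
pair = PeakSet(np.stack([z, x]), np.array([1.0, 1.0]))
empty = PeakSet(np.empty((0, 3)), np.empty(0))

print(f"same peak vs itself:             {angular_emd(one_z, one_z):6.2f} deg")
print(f"single peaks 30 deg apart:       {angular_emd(one_z, one_tilt):6.2f} deg")
print(f"z/x pair vs single z peak:       {angular_emd(pair, one_z):6.2f} deg "
      "(half the mass travels 90 deg)")
print(f"antipodal flip is free:          "
      f"{angular_emd(PeakSet(-z[None], np.array([1.0])), one_z):6.2f} deg")
print(f"empty vs nonempty (convention):  {angular_emd(empty, one_z):6.2f} deg")
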