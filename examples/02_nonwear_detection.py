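"""Detect accelerometer non-wear on a constructed minute-count stream.

The Choi rule marks runs of >= 90 zero-count minutes as non-wear, tolerating
up to 2 consecutive non-zero minutes when each side shows >= 30 zero minutes
(the stream frame).
"""

import numpy as np

from sbpatterns import choi_nonwear

# two hours of activity | 100 zeros | 1 spurious spike | 100 zeros | activity
minutes = np.concatenate([
    np.full(120, 300),
    np.zeros(100, int), [55], np.zeros(100, int),
    np.full(120, 300),
])
nonwear = choi_nonwear(minutes)

runs = np.flatnonzero(np.diff(np.concatenate([[0], nonwear.astype(int), [0]])))
print(f"stream length: {minutes.size} min, non-wear minutes: {nonwear.sum()}")
for start, stop in zip(runs[::2], runs[1::2]):
    print(f"  non-wear interval: minute {start}..{stop - 1} ({stop - start} min)")

# The 1-minute spike at minute 220 is flanked by long zero runs, so the
# whole 201-minute span counts as a single device-off episode.
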