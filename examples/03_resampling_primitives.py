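"""The two single-label primitives behind the hybrid resampler.

SMOTE interpolation places a synthetic point uniformly on the segment
between a seed and one of its nearest neighbours; a Tomek link is a
cross-class pair of mutual nearest neighbours, whose members are noise or
borderline points. The printed link for the 1-D example is the pair
(0.0, 0.9): they are each other's nearest neighbours and carry different
classes.
"""

import numpy as np

from mltlsmote import smote_interpolate, tomek_links

rng = np.random.default_rng(0)
seed_vec = np.array([0.0, 0.0])
neighbor = np.array([1.0, 2.0])
for _ in range(3):
    x = smote_interpolate(seed_vec, neighbor, rng)
    print(f"interpolated point: ({x[0]:.3f}, {x[1]:.3f})  "
          "(always on the segment seed->neighbour)")

features = np.array([[0.0], [0.9], [2.0], [3.5]])
classes = np.array([0, 1, 0, 0])
links = tomek_links(features, classes)
for pair in links:
    print(f"Tomek link: instances {pair.i} and {pair.j} "
          f"at distance {pair.distance:.2f}")
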