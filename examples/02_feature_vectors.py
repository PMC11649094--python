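"""Extract the 225-dimensional LBP block-histogram feature vector.

Every pixel of the standardized 100x100 section is coded by how many of its
8 neighbors are >= the center (0..8); the image is split into 25 blocks of
20x20 and each block contributes a 9-bin code histogram.
"""

import numpy as np

from hypercut import CaptureParams, extract_capture_features, make_subject, render_capture

model = make_subject(subject_seed=7, shape=(128, 128), wavelengths_nm=np.arange(400, 1001, 5))
cube, landmarks = render_capture(model, CaptureParams(seed=1))

fv, img8 = extract_capture_features(cube, landmarks)
print(f"feature vector length: {len(fv)} = {fv.blocks[0]}x{fv.blocks[1]} blocks x {fv.bins} bins")
per_block = fv.values.reshape(-1, fv.bins)
print(f"each block histogram sums to its pixel count: {sorted(set(int(s) for s in per_block.sum(axis=1)))}")
print(f"total mass equals the image size: {int(fv.values.sum())} = 100*100")
print(f"first block histogram: {per_block[0].astype(int)}")
print("bins count pixels by number of brighter-or-equal neighbors; smooth areas "
      "concentrate in high bins, textured areas spread across the middle")
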