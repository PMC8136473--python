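"""Generate a small synthetic AB phantom and inspect its ground truth.

The phantom mimics a lung micro-CT fragment: bright beaded capsules
(asbestos bodies) with log-normal lengths, a soft-tissue background, a dark
air space and bright particulate distractors, plus Gaussian grey noise.
"""

import numpy as np

from abtomo import PhantomSpec, generate_phantom, true_density

spec = PhantomSpec(shape=(128, 128, 128), n_fibres=20, seed=1)
volume, records = generate_phantom(spec)

print(f"volume: {volume.shape} voxels at {volume.voxel_size} um "
      f"({volume.physical_volume_cm3:.3e} cm^3)")
lengths = [r.length_um for r in records]
widths = [r.width_um for r in records]
print(f"{len(records)} fibres, lengths {min(lengths):.1f}-{max(lengths):.1f} um "
      f"(mean {np.mean(lengths):.1f}), widths mean {np.mean(widths):.2f} um")
print(f"true density: {true_density(records, volume):.3e} AB/cm^3")
print("Each record carries centroid, orientation, length, width and the "
      "rendered voxel volume - the exact truth a detector must recover.")
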