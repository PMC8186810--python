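"""The sequential-MNIST transforms, shown on a synthetic digit-like image.

No MNIST download is needed here: a random [0, 1] image stands in.  The
transforms are what matter — a fixed pixel permutation shared by the whole
dataset, line-by-line feeding, black-line padding that creates a forgetting
period, and a marker line that tells the network when to classify.
"""

import numpy as np

from bistablernn import (make_permutation, permute_pixels,
                         sample_variable_padding, to_line_sequence)

rng = np.random.default_rng(0)
image = rng.random((28, 28))  # synthetic stand-in for one MNIST digit

shuffled = permute_pixels(image, seed=42)
perm = make_permutation(42)
restored = shuffled.reshape(-1)[np.argsort(perm)].reshape(28, 28)
print("permutation bijective:", np.array_equal(restored, image))

for n_black in (72, 472):
    seq = to_line_sequence(shuffled, n_black=n_black)
    print(f"{n_black} black lines -> sequence of {seq.shape[0]} lines "
          f"of dim {seq.shape[1]}")

pads = sample_variable_padding(X=472, seed=7, n=5)
print("variable padding draws (uniform on {0..472}):", pads)
seq = to_line_sequence(shuffled, n_black=int(pads[0]), marker=2.0)
print(f"with marker line: {seq.shape[0]} lines, last line value "
      f"{seq[-1, 0]} (> 1.0, the white pixel, so never part of an image)")
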