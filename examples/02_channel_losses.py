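"""The channel-tailored losses on small hand-built inputs.

Shows the segmentation weight mask routing extra weight to misclassified
pixels, the gradient loss ignoring constant offsets but punishing edge
mismatches, and the two analytic raLSGAN identities.
"""

import numpy as np

from virtustain.losses import (
    gradient_loss,
    ralsgan_discriminator_loss,
    ralsgan_generator_loss,
    segmentation_weight_mask,
    weighted_l1,
)

# SWM: the segmentation decoder misses the bottom-right nucleus pixel
prob = np.array([[0.9, 0.1], [0.2, 0.3]])
gt = np.array([[1, 0], [0, 1]])
swm = segmentation_weight_mask(prob, gt)
print("SWM weights (eta=2 on the misclassified pixel):")
print(swm.weights)

pred = np.array([[0.5, 0.0], [0.0, 0.5]])
target = np.array([[1.0, 0.0], [0.0, 1.0]])
print(f"weighted L1 = {float(weighted_l1(pred, target, swm)):.3f} "
      f"(plain L1 would be {float(weighted_l1(pred, target)):.3f})")

# gradient loss: a constant offset costs nothing, a moved edge does
flat = np.full((4, 4), 0.2)
edge = np.zeros((4, 4)); edge[:, 2:] = 1.0
print(f"gradient loss, offset-only error: {float(gradient_loss(flat + 0.3, flat)):.3f}")
print(f"gradient loss, edge mismatch:     {float(gradient_loss(flat, edge)):.3f}")

# raLSGAN identities: an uninformative critic scores exactly 2 for both sides
c = np.full(4, 0.7)
print(f"raLSGAN with constant scores: L_G = {float(ralsgan_generator_loss(c, c)):.1f}, "
      f"L_D = {float(ralsgan_discriminator_loss(c, c)):.1f}")
d_real, d_fake = np.array([1.0, 1.0]), np.array([0.0, 0.0])
print(f"perfectly separated scores:   L_G = "
      f"{float(ralsgan_generator_loss(d_real, d_fake)):.1f}, "
      f"L_D = {float(ralsgan_discriminator_loss(d_real, d_fake)):.1f}")
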