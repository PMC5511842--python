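"""Build the three attenuation-map variants and compare them.

Shows the segmented-transmission, Dixon and bilinear-CT maps for the same
head, demonstrates the Dixon tissue-inversion artifact and its correction,
and prints soft-tissue/bone relative differences between the maps.
"""

import numpy as np

import petacbias as pb

subj = pb.build_head_phantom(pb.PhantomSpec())
rng = np.random.default_rng(0)

# Transmission arm: measured mu + noise, segmented into fixed classes.
measured = np.clip(subj.mu_true + rng.normal(0, 0.005, subj.mu_true.shape), 0, None)
mu_tx = pb.segment_tx_mu_map(measured)

# Dixon arm with a vendor tissue inversion: detect it, then correct it by
# recomputing fat/water from the in-phase/opposed-phase images.
pair = pb.synth_dixon_pair(subj, inverted=True, noise_sd=0.02, seed=1)
candidate = pb.dixon_standard_mu(pair)
inverted = pb.detect_tissue_inversion(pair, candidate)
print(f"tissue inversion detected: {inverted}")
mu_dixon = pb.dixon_correct_inversion(pair) if inverted else candidate

mu_ct = pb.ct_to_mu(subj.hu_map)

soft = subj.label_map == pb.Tissue.GRAY
bone = subj.label_map == pb.Tissue.BONE
for name, mu in [("DIXON", mu_dixon), ("CT", mu_ct)]:
    diff, valid = pb.relative_difference_map(mu.mu, mu_tx.mu, subj.head_mask)
    print(f"{name} vs Tx: soft-tissue {np.nanmean(diff[soft & valid]):+.1f}%, "
          f"bone {np.nanmean(diff[bone & valid]):+.1f}%")
# Dixon raises soft-tissue mu by ~5% over the Tx class value but treats bone
# as air (-100%); CT restores the full bone coefficient the Tx segmentation
# underestimates (+40% over the 0.125 cm^-1 class value).
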