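"""Size profiles and peak-cluster AUC statistics.

Plasma eccDNA shows two size clusters (summits near 202 and 338 bp).
Nuclease (DNASE1L3) loss shifts mass from the first cluster to the
second, which the AUC ratio (second/first) summarises in one number.
"""

import numpy as np

from eccircle.simulate import SizeLaw
from eccircle.size import cluster_auc, size_profile_from_sizes

rng = np.random.default_rng(7)
laws = {
    "wild type   ": SizeLaw(w1=0.78),   # first cluster dominates
    "Dnase1l3 -/-": SizeLaw(w1=0.30),   # mass moved to the second cluster
}

for name, law in laws.items():
    sizes = law.sample(20_000, rng)
    profile = size_profile_from_sizes(sizes)
    auc = cluster_auc(profile)  # windows [150,250] and [300,450] bp
    mode = profile.sizes[np.argmax(profile.counts)]
    print(f"{name}: modal size {mode} bp | "
          f"AUC1 {auc.auc1:.1f}% AUC2 {auc.auc2:.1f}% "
          f"ratio {auc.auc_ratio:.2f}")

print("-> a higher AUC ratio means longer circles overall; the knockout "
      "profile is dominated by the 300-450 bp cluster")

# the ratio depends only on profile shape, not on how many molecules
small = cluster_auc(size_profile_from_sizes(laws["wild type   "].sample(500, rng)))
print(f"subsampled wild type (n=500): ratio {small.auc_ratio:.2f} "
      "(same shape, noisier)")
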