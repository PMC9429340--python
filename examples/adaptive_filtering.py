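"""Shannon-adaptive removal of low-abundance false positives.

A profiler's false positives are mostly rare species.  A fixed 1% cutoff
removes them but can also destroy genuinely diverse communities; the
adaptive rule picks the cutoff from the sample's own Shannon diversity
(non-gut: 1% / 0.1% / none over H' bands 0-2.5 / 2.5-4.5 / > 4.5).
"""

import numpy as np

from taxbench import (
    confusion_counts,
    filter_adaptive,
    filter_fixed,
    normalize,
    precision_recall_f1,
    shannon_index,
)
from taxbench.profiles import Profile

rng = np.random.default_rng(1)

# diverse gold community: 150 species, uniform -> H' = ln 150 ~ 5.0
gold = Profile("diverse", {"species": {i: 1 / 150 for i in range(150)}},
               normalized=True)
# prediction: every true species, plus 10 false positives below 0.1%
predicted = {i: 1 / 150 for i in range(150)}
predicted.update({1000 + i: 5e-6 for i in range(10)})
pred = normalize(Profile("diverse", {"species": predicted}))

h = shannon_index(pred)
print(f"predicted Shannon index H' = {h:.2f} (> 4.5: adaptive threshold none)")
for label, filtered in [
    ("unfiltered", pred),
    ("fixed 1%", filter_fixed(pred, 0.01)),
    ("adaptive (non-gut)", filter_adaptive(pred, "non_gut")),
]:
    p, r, f1 = precision_recall_f1(confusion_counts(filtered, gold, "species"))
    print(f"{label:<20} precision {p:.3f}  recall {r:.3f}  F1 {f1:.3f}")
print(
    "\nThe 1% cutoff removes the whole uniform community (every species sits"
    "\nat 0.67%), while the adaptive rule leaves the diverse sample intact."
)
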