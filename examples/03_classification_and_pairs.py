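"""The TF classification grid and the eight meaningful regulator-target pairs.

A TF's class combines where its peaks are enriched (uDEG / dDEG promoters /
both) with whether its own coding gene is up, down or unchanged. Only four
classes carry an interpretable sign; only eight of the 16 ordered class
pairs are mechanistically consistent.
"""

import itertools

from tfrn.classification import NETWORK_CLASSES, classify_tf
from tfrn.network import is_meaningful_pair, link_sign

print("classification grid (enrichment pattern x own-gene direction):")
for e_up, e_down, label in [(True, False, "uDEG promoters"),
                            (False, True, "dDEG promoters"),
                            (True, True, "both directions")]:
    for gd in ("up", "down", "none"):
        cls = classify_tf(e_up, e_down, gd)
        print(f"  enriched in {label:16s} gene={gd:5s} -> {cls}")

print("\nmeaningful (regulator -> target) pairs and link signs:")
for reg, tgt in itertools.product(NETWORK_CLASSES, repeat=2):
    ok = is_meaningful_pair(reg, tgt)
    mark = link_sign(reg) if ok else "--"
    print(f"  {reg} -> {tgt}: {'meaningful (' + mark + ')' if ok else 'inconsistent'}")
n = sum(is_meaningful_pair(r, t) for r, t in itertools.product(NETWORK_CLASSES, repeat=2))
print(f"\n{n} of 16 ordered pairs admitted")
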