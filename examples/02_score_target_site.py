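"""Score a miRNA against a candidate cleavage site.

The site is compared anti-parallel to the miRNA (position 1 pairs the
site's 3'-most base). Penalties: mismatch 1.0, G:U wobble 0.5, 1-nt gap
1.0, doubled at miRNA positions 2-13; alignments above 7 or imperfect at
positions 10/11 (the bases flanking the scissile bond) are rejected.
"""

from mirslice.degradome_targeting import score_alignment
from mirslice.seq_io import revcomp

mirna = "TGAGGTAGTAGGTTGTATAGT"  # 21 nt, 5'->3'

perfect = revcomp(mirna)
site = list(perfect)
site[1] = "A"   # mismatch opposite miRNA position 20 (outside the core): +1.0
site[16] = "T"  # wobble or mismatch opposite position 5 (doubled core)
site = "".join(site)

for label, s in [("perfect site", perfect), ("two defects", site)]:
    res = score_alignment(mirna, s)
    if res is None:
        print(f"{label}: rejected")
        continue
    score, states, _ = res
    print(f"{label}: score {score}  (accepted, threshold 7.0)")
    print("  miRNA 5'->3':", mirna)
    print("  states      :", "".join({"match": "|", "wobble": "o", "mismatch": "x", "gap": "-"}[s] for s in states))
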