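"""Promoter cis-element scanning with the packaged motif library.

Scans a short promoter containing an ABRE, a G-box (palindromic, reported
once) and a MYC element, then prints per-class shares.
"""

from collections import Counter

from asterfam import default_motif_library, scan
from asterfam.models import PromoterSeq
from asterfam.promoters import class_proportions

promoter = PromoterSeq("gene1", "TTTACGTGTTTTCACGTGTTTTCATTTGTTT", truncated=False)
hits = scan(promoter, default_motif_library())
for h in hits:
    print(f"{h.element_name:10s} {h.functional_class:8s} at {h.start:3d} ({h.strand})")

counts = Counter(h.functional_class for h in hits)
print("class shares (%):", class_proportions(counts, sum(counts.values())))
# ABRE (ACGTG) also sits inside the planted G-box window (CACGTG), so the
# same bases legitimately yield hits for both elements; the palindromic
# G-box itself is deduplicated to a single plus-strand hit.
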