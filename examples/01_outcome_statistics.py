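"""Derive the six editing-outcome statistics from repair-event records.

Builds a tiny per-target event table (as CIGAR strings with read counts),
computes the outcome profile, and prints it.  The six numbers are fractions
of indel-bearing reads: 1 bp insertion, 1 bp deletion, any deletion, and
frameshifts of 1, 2, or either.
"""

from editnas import compute_profile, parse_cigar
from editnas.outcomes import TASK_NAMES

events = [
    parse_cigar("30M1I29M", count=120),   # 1 bp insertion
    parse_cigar("28M1D31M", count=60),    # 1 bp deletion
    parse_cigar("25M5D30M", count=40),    # 5 bp deletion (frameshift of 2)
    parse_cigar("27M3D30M", count=30),    # 3 bp in-frame deletion
    parse_cigar("60M", count=200),        # unedited reads: excluded
]

profile = compute_profile(events)
print("editing-outcome profile over 250 indel reads:")
for name, value in zip(TASK_NAMES, profile.as_array()):
    print(f"  {name:>8s} = {value:.3f}")
print("fs_total = fs1 + fs2 and the unedited 200 reads never enter the "
      "denominator; e.g. ins1 = 120/250.")
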