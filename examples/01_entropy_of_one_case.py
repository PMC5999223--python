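"""Entropy of a single case, step by step.

Six slides of one thymectomy specimen carry follicle counts; we bin them
into 10 levels of 5 follicles each, form the empirical level frequencies,
and evaluate the per-point entropy sum.  The printed reference maximum is
what a case of the same size would score if every point carried an
equiprobable level.
"""

from thymentropy import (
    assign_level,
    entropy_pointsum,
    entropy_shannon,
    follicle_count_scheme,
    level_distribution,
    max_entropy_reference,
)

follicle_counts = [2, 7, 7, 31, 12, 44]
scheme = follicle_count_scheme()
levels = [assign_level(v, scheme) for v in follicle_counts]
dist = level_distribution(levels)

print(f"follicle counts : {follicle_counts}")
print(f"levels (width 5): {levels}")
print(f"frequencies     : {dist.probs}")
print(f"point-sum entropy H        = {entropy_pointsum(levels):.3f} bit")
print(f"Shannon entropy (levels)   = {entropy_shannon(levels):.3f} bit")
print(f"reference maximum Hmax     = {max_entropy_reference(dist.m, scheme.n_levels):.3f} bit")
print()
print("A case with six identical counts would score exactly 0 bit:",
      entropy_pointsum([assign_level(7, scheme)] * 6))
# Higher entropy = the follicle burden is spread unevenly across the
# specimen; 0 = perfectly homogeneous.
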