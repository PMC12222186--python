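"""Robust per-bin outlier exclusion with the Hampel filter.

Within each bin x setting cell, points farther than k (scaled) median
absolute deviations from the cell median are excluded before any test.
"""

from saltmeta import hampel_filter

values = [1, 2, 3, 4, 100]
retained, excluded = hampel_filter(values, k=3.0, scale=1.4826)
print("input    :", values)
print("retained :", retained)
print("excluded :", excluded)
print("median 3, MAD 1 -> threshold 3 x 1.4826 x 1 = 4.45; only 100 is out")

# with the literal "3 MADs" reading (scale=1.0) the rule is stricter
retained, excluded = hampel_filter([10, 11, 12, 13, 20, 30], k=3.0, scale=1.0)
print("literal-scale retained:", retained, "excluded:", excluded)
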