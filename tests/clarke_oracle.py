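"""Independent scalar re-implementation of the Clarke zone boundaries.

Deliberately coded as a plain if/elif chain (vs the package's vectorized
np.select) so grid agreement is a genuine dual-implementation check.
"""


def clarke_zone_oracle(r: float, p: float) -> str:
    if (r <= 70 and p <= 70) or (0.8 * r <= p <= 1.2 * r):
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= 1.4 * r - 182):
        return "C"
    if (r >= 240 and 70 <= p <= 180) or (r <= 175 / 3 and 70 <= p <= 180) \
            or (175 / 3 <= r <= 70 and p >= 1.2 * r):
        return "D"
    return "B"
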