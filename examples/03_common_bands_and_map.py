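"""Discover cross-cultivar common bands and render the pattern map.

Pools the peak positions of all 26 cultivars and splits them into contiguous
bands (gap threshold 8 cm^-1). Bands supported by many cultivars mark shared
chemistry — the 731-734 cm^-1 band is present in every cultivar. Also writes
the color-block pattern map (one row per cultivar, violet = weak, red =
strongest).
"""

from chrysoraman import find_common_bands, reference_library, render_pattern_map

library = reference_library()
clusters = find_common_bands(library, gap_threshold=8)

print(f"{'band (cm^-1)':>14}  {'support':>7}")
for cluster in clusters:
    print(f"{cluster.lower:6.0f}-{cluster.upper:<6.0f}  {cluster.support:7d}")

out = render_pattern_map(library, "pattern_map.png")
print(f"\npattern map written to {out}")
print("Support = number of cultivars with a peak in the band; the support-26")
print("band (731-734) is the universal strongest peak shared by all cultivars.")
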