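"""Measure vessel calibre along the centreline of known-width bars.

Rasterizes oriented bars of known perpendicular width, extracts the
centreline, finds the orientation at each centreline pixel with the 3×3
window family, and measures the width along the perpendicular profile.
"""

import numpy as np

import retseg

print(f"{len(retseg.enumerate_window_configs())} valid 3x3 orientation windows")
print(f"{'width':>6} {'angle':>6} {'measured':>9} {'n':>4}")
for width in (3, 5, 7, 9, 11):
    for angle in (0, 45, 90):
        mask, _ = retseg.generate_bar(width, angle, 40, (64, 64))
        recs = [r for r in retseg.profile_vessel(mask) if not r.clipped]
        mean_w = np.mean([r.width for r in recs])
        print(f"{width:>6} {angle:>6} {mean_w:>9.2f} {len(recs):>4}")
print("Measured width is the Euclidean edge-to-edge distance plus one pixel")
print("extent; axis-aligned bars are exact, diagonal profiles sample on a")
print("sqrt(2) grid and may be up to ~1.5 px off, matching the method's")
print("reported pixel-scale bias.")
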