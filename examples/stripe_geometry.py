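"""Retinal size of the arena stripes as a function of fly position.

The two black stripes are 313 mm tall and sit on a diffuser 147.5 mm
from the arena centre.  Their angular size on the fly's eye depends on
where the fly stands on the 117 mm platform.
"""

from buridan import retinal_height_deg, retinal_width_deg

center = 147.5          # distance from platform centre, mm
near = 147.5 - 58.5     # fly at the rim, closest approach
far = 147.5 + 58.5      # fly at the rim, opposite side

print("stripe height 313 mm:")
for label, d in [("center", center), ("nearest rim", near), ("farthest rim", far)]:
    print(f"  from {label:>12} ({d:5.1f} mm): {retinal_height_deg(313, d):5.1f} deg")

print("narrow stripe (30 mm wide):")
for label, d in [("center", center), ("nearest rim", near), ("farthest rim", far)]:
    print(f"  from {label:>12} ({d:5.1f} mm): {retinal_width_deg(30, d):5.1f} deg")

print("wide stripe (50 mm wide):")
print(f"  from       center (147.5 mm): {retinal_width_deg(50, center):5.1f} deg")

# A stripe subtends ~65 deg of visual height from the platform centre and
# grows/shrinks as the fly walks toward/away from it; the width figures
# show why 30 mm and 50 mm stripes are called "narrow" (~12 deg) and
# "wide" (~20 deg).
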