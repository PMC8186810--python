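"""Fixed points and the pitchfork bifurcation of the scalar cell map.

Builds the map h <- c*h + (1-c)*tanh(a*h) at c = 0.5, locates its fixed
points on both sides of the critical feedback gain, and sweeps a over [0, 2]
to find where the origin loses stability.
"""

from bistablernn import (ScalarMapParams, bifurcation_diagram,
                         find_fixed_points, pitchfork_conditions)

for a in (0.5, 1.5):
    fps = find_fixed_points(ScalarMapParams(a=a, c=0.5))
    print(f"a = {a}:")
    for p in fps.points:
        print(f"  h* = {p.h:+.6f}  {p.stability:9s}  F'(h*) = {p.derivative:.4f}")

bd = bifurcation_diagram(c=0.5, steps=81)
print(f"\ncritical feedback gain (origin loses stability): a = {bd.critical_a:.4f}")
# Below 1 the cell forgets (unique stable state at 0); above 1 it can latch
# onto one of two signed states: cellular memory that never fades.

r = pitchfork_conditions(c=0.5)
print("pitchfork zero-conditions:", [f"{v:.1e}" for v in r.zero_conditions])
print(f"cubic term 2(1-c) = {r.d3G_dh3:.3f} > 0, "
      f"mixed term c-1 = {r.d2G_dhda:.3f} < 0 -> supercritical pitchfork")
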