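"""Evaluate the ligament tensile law and the compliant contact law directly.

The ligament force is piecewise: slack below the zero-load length, a
quadratic toe up to twice the linear strain limit (0.03), then linear with
stiffness k.  Contact force follows kc * depth**tau (5000 N/mm, tau 2.2)
plus a damping term that is inactive in quasi-static analysis.
"""

import numpy as np

from kneesim import ContactParams, ContactPatch, contact_force
from kneesim.ligaments import strain, tensile_force, zero_load_length

# A default-MCL-like bundle: k = 400 N, reference strain 0.04 at 52 mm
L0 = zero_load_length(Lr=52.0, eps_r=0.04)
print(f"zero-load length of a 52 mm bundle at reference strain 0.04: {L0:.1f} mm")
for L in (48.0, 50.0, 51.5, 53.0, 57.0):
    eps = strain(L, L0)
    f = tensile_force(eps, k=400.0)
    branch = "slack" if eps < 0 else ("toe" if eps <= 0.06 else "linear")
    print(f"  L = {L:5.1f} mm  strain = {eps:+.3f}  force = {f:6.2f} N  ({branch})")

print("\ncompliant contact at increasing penetration (zero rate):")
for depth in (0.1, 0.5, 1.0):
    patch = ContactPatch(("femur", "tibia"), depth, 0.0, np.array([0.0, 0.0, 1.0]), np.zeros(3))
    f, _ = contact_force(patch, ContactParams())
    print(f"  depth = {depth:4.1f} mm  force = {np.linalg.norm(f):8.2f} N")
print("At 1 mm the force equals the contact stiffness (1**2.2 = 1).")
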