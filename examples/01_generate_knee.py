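"""Generate the synthetic post-TKA knee and inspect what it contains.

Builds the default parametric right knee: femur/tibia/patella meshes, a
posterior-stabilized implant (two condyles + cam on the femoral component,
two dished facets + post on the insert) and the full soft-tissue set.
Writes the model to ./knee_model/ as STL meshes plus model.json.
"""

from kneesim import generate_synthetic_knee, save_model

model = generate_synthetic_knee()

print("bodies:")
for name, body in model.bodies.items():
    print(f"  {name:8s}  {len(body.mesh.faces):5d} triangles, "
          f"{len(body.attachment_sites)} attachment sites, watertight={body.mesh.is_watertight}")
print("implant components:", ", ".join(model.implant.components()))
print("passive bundles:")
for b in model.bundles:
    print(f"  {b.name:9s} ({b.ligament:4s})  k={b.k:7.0f} N  eps_r={b.eps_r:+.2f}")
print("actuators:", ", ".join(f"{a.name} ({a.kind})" for a in model.actuators))

files = save_model(model, "knee_model")
print(f"\nwrote {len(files)} files to knee_model/")
print("The bundle stiffnesses k (N) and reference strains eps_r are the "
      "literature defaults the squat simulation starts from.")
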