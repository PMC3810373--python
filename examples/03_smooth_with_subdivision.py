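"""Smooth the angular block model with Catmull-Clark subdivision.

One level turns every quad into four and pulls vertices toward the limit
surface; all weights are convex, so the smoothed surface stays inside the
convex hull of the control cage.
"""

from anchor3d import (build_final_model, catmull_clark, limit_check,
                      reference_template, validate_mesh)

model = build_final_model(reference_template())
mesh = model.control_mesh
print(f"level 0: V={mesh.n_vertices} F={mesh.n_faces}")
for level in (1, 2):
    sub = catmull_clark(mesh, level)
    rep = validate_mesh(sub)
    print(f"level {level}: V={rep.V} F={rep.F} E={rep.E} euler={rep.euler} "
          f"area={sub.face_areas().sum():.2f} "
          f"inside_hull={limit_check(mesh, sub)}")
# Counts follow V' = V+E+F, F' = 4F, E' = 2E+4F per level; the surface
# area shrinks as angular corners round off toward the limit surface.
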