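"""Generate the idealized sidewall-aneurysm meshes and write them to disk.

Case R: a half-torus parent vessel (4 mm diameter, inlet and outlet on the
plane y = 0) carrying a spherical bulge centred at y = 10 mm, with a 0.25 mm
arterial wall.  The fluid lumen is meshed with a graded near-wall layer; the
wall shell is extruded from the fluid interface triangulation, so the two
meshes match vertex-for-vertex across the fluid-structure interface.
"""

import numpy as np

from aneufsi import (DESK_MESH, build_case_r, mesh_fluid, mesh_solid,
                     tag_regions, write_mesh, write_vtu)
from aneufsi.mesh import REGION_TAGS

model = build_case_r()
fluid = mesh_fluid(model, DESK_MESH, seed=0)
solid = mesh_solid(model, DESK_MESH, fluid_mesh=fluid)

print(f"fluid mesh : {fluid.num_vertices} vertices, {fluid.num_cells} tets")
print(f"solid mesh : {solid.num_vertices} vertices, {solid.num_cells} tets")
n_bulge = (solid.region_tags == REGION_TAGS['bulge-wall']).sum()
print(f"bulge-wall cells (y > 8 mm, 10x softer tissue): {n_bulge}")

iface_f = fluid.vertex_set("interface")
iface_s = solid.vertex_set("interface")
gap = np.abs(np.sort(fluid.vertices[iface_f], axis=0)
             - np.sort(solid.vertices[iface_s], axis=0)).max()
print(f"interface conformity (coordinate mismatch): {gap:.1e} mm")

write_mesh(fluid, "case_r_fluid.msh")
write_mesh(solid, "case_r_solid.msh")
write_vtu("case_r_fluid.vtu", fluid.vertices, fluid.cells)
print("wrote case_r_fluid.msh / case_r_solid.msh / case_r_fluid.vtu")

# The desk profile is a coarse version of the published sizing (whose core
# element size of 0.17 mm yields about a million fluid elements); swap in
# MeshParams() for the full-resolution meshes if you have the time and RAM.
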