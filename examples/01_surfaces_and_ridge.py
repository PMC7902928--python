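"""Build TIN surfaces from a synthetic ridged field and estimate ridge height.

Generates a small two-plot field (ridges 0.90 m apart, true ridge height
0.20 m), triangulates the bare-soil furrow cloud into the soil topography
TIN, estimates the average ridge height from crest-line samples, and
raises the topography into the soil reference surface.
"""

import tincanopy as tc
from tincanopy.surfaces import build_soil_reference, build_tin, estimate_ridge_height

scenario = tc.FieldScenario(n_plots=2, point_density=2000, noise_sd_z=0.01,
                            outlier_fraction=0.0, seed=42)
field = tc.generate_field(scenario)
print(f"canopy cloud: {len(field.canopy)} points, "
      f"bare-soil cloud: {len(field.bare_soil)} points")

soil_topo = build_tin(field.bare_soil, kind="soil_topo")
ridge = estimate_ridge_height(field.canopy, soil_topo, field.crest_lines)
print(f"estimated ridge height: {ridge:.3f} m (generator truth: "
      f"{scenario.ridge_height:.2f} m)")

soil_ref = build_soil_reference(field.bare_soil, ridge, soil_topo=soil_topo)
x, y = field.plots[0].polygon.centroid.coords[0]
print(f"soil topography at plot centre: {soil_topo.elevation_at(x, y):.3f} m")
print(f"soil reference  at plot centre: {soil_ref.elevation_at(x, y):.3f} m")
print("the reference sits one ridge height above the furrow topography, at the")
print("level where the plants actually emerge from the ridge")
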