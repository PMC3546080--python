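"""Quantify a synthetic nerve-plexus phantom and check it against truth.

Generates one binary phantom mask (8 near-parallel fibres with mild
tortuosity and occasional branch twigs, 384x384 px over a 400x400 µm
field), runs the full two-stage pipeline on it, and prints the
measured parameter vector next to the generator's analytic ground
truth.
"""

from sbpquant import PhantomSpec, compute_metrics, generate_phantom

img, truth = generate_phantom(PhantomSpec(seed=42))
m = compute_metrics(img)

print(f"field: {img.width_px}x{img.height_px} px, {img.image_area_mm2:.2f} mm^2")
print(f"component pixels     : {m.component_pixels:6.0f}")
print(f"component ratio      : {m.component_ratio:6.2f} %")
print(f"components           : {m.n_components:6.0f}")
print(f"skeleton pixels      : {m.skeleton_pixels:6.0f}")
print(f"single nerve fibres  : {m.single_nerve_fibres:6.0f}   (truth {truth.true_n_fibres})")
print(f"branches             : {m.n_branches:6.0f}   (truth {truth.true_n_branches})")
print(f"endpoints            : {m.n_endpoints:6.0f}   (truth {truth.true_n_endpoints})")
print(f"connectivity points  : {m.n_connectivity_points:6.0f}   (truth {truth.true_n_border_crossings})")
print(f"total fibre length   : {m.total_fibre_length_um:8.1f} µm (truth {truth.true_total_length_um:.1f})")
print(f"fibre density        : {m.fibre_density:8.5f} µm/µm²")

err = abs(m.total_fibre_length_um - truth.true_total_length_um) / truth.true_total_length_um
print(f"\nlength recovery error: {100 * err:.2f} %  "
      "(chain-code measurement of a smooth curve overestimates slightly)")
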