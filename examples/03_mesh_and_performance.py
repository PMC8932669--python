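"""Mesh one jaw and measure speed and strength under uncertainty.

Triangulates a unit-area jaw, finds the joint/bite landmarks from the
near-vertical-normal rule, and runs 500 randomized boundary-condition
replicates: rotational efficiency (RE, speed proxy) with joint/bite slid
along the outline, and median von Mises stress (VMS, inverse strength
proxy) with the muscle force node and direction perturbed.
"""

from jawscape import (
    SyntheticJawParams,
    generate_jaw_outline,
    identify_landmarks,
    monte_carlo_performance,
    rotational_efficiency,
    standardize_area,
    triangulate,
)

jaw = standardize_area(
    generate_jaw_outline(SyntheticJawParams(4.0, 0.1, 0.3, 0.005), seed=5)
)
mesh = triangulate(jaw, target_elements=2500)
print(f"mesh: {mesh.n_elements} elements, min angle {mesh.min_angle_deg():.1f} deg")

joint, bite = identify_landmarks(mesh)
print(f"joint at {mesh.nodes[joint].round(3)}, bite at {mesh.nodes[bite].round(3)}")
print(f"baseline RE = {rotational_efficiency(mesh, joint, bite):.4f} "
      "(bite-point speed per unit rotational energy, relative units)")

rec = monte_carlo_performance(mesh, n_replicates=500, seed=42)
print(f"RE  mean {rec.re_mean:.4f}  [5th, 95th] = [{rec.re_p5:.4f}, {rec.re_p95:.4f}]")
print(f"VMS mean {rec.vms_mean:.4f}  [5th, 95th] = [{rec.vms_p5:.4f}, {rec.vms_p95:.4f}]")
print("(narrow percentile bands mean performance is robust to where exactly "
      "the jaw articulates, bites and is loaded)")
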