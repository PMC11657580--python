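"""Extrinsic sensitivity of shape-difference descriptors.

Builds the sphere-dome interpolation series: S_0 is a sphere, S_1 the same
sphere with its dome mirrored at the plane z = 0.5, and S_t the linear
interpolation. Members S_t and S_{1-t} are exactly isometric (identical
intrinsic geometry) but embedded differently. The script computes
Log-Euclidean distances between area-based shape-difference descriptors at
several blending weights omega and prints how the isometric pair (S_0.125,
S_0.875) separates as omega grows.
"""

import numpy as np

from shapegrade import (metric_operators, eigenbasis, all_pairs_fmaps,
                        consistent_zoomout, compute_descriptor)
from shapegrade.network import ShapeBundle, prune_network
from shapegrade.descriptors import descriptor_distance_matrix
from shapegrade.synthetic import sphere_dome_series


def main():
    series = sphere_dome_series(n_t=9, subdivisions=1, plane_height=0.5)
    bundles = []
    for i, mesh in enumerate(series.meshes):
        mesh.subject_id = f"t{i}"
        ops = metric_operators(mesh, 0.0)
        bundles.append(ShapeBundle(f"t{i}", mesh, eigenbasis(ops, 30), ops))

    network = prune_network(all_pairs_fmaps(
        bundles, n_landmarks=60, k0=10, zoomout_steps=8, seed=0,
        registration="none"))
    clb = consistent_zoomout(network, bundles, init_dim=6, steps=8)
    print(f"latent basis: {clb.m} functions, residual {clb.residual:.2e}")

    print(f"{'omega':>8}  {'d(S_t, S_1-t)':>14}  {'series max':>11}  ratio")
    for omega in (0.0, 0.005, 0.01, 0.03):
        descs = []
        for i, b in enumerate(bundles):
            ops_w = b.ops if omega == 0 else metric_operators(b.mesh, omega)
            descs.append(compute_descriptor(clb.Y[f"t{i}"], b.basis, ops_w))
        D = descriptor_distance_matrix(descs, kinds=("area",))
        print(f"{omega:8.3f}  {D[1, 7]:14.5f}  {D.max():11.5f}"
              f"  {D[1, 7] / D.max():8.5f}")
    print("\nAt omega = 0 the isometric pair is indistinguishable (ratio"
          " ~1e-4);\nfor omega > 0 the third fundamental form enters the"
          " metric and the\npair separates, growing with omega.")


if __name__ == "__main__":
    main()
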