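"""Functional maps from scratch: correspondence without landmarks on disk.

Takes a bumpy sphere and a vertex-permuted copy (ground-truth
correspondence known by construction), estimates a functional map from
automatically generated landmarks, refines it with ZoomOut, and converts
it back to a pointwise map. Prints the fraction of vertices recovered and
the 2-cycle consistency of the forward/backward map pair.
"""

import numpy as np

from shapegrade import (metric_operators, eigenbasis, initial_landmarks,
                        fmap_from_landmarks, zoomout_refine,
                        pointwise_from_fmap, cycle_consistency)
from shapegrade.meshes import TriangleMesh
from shapegrade.synthetic import uv_sphere


def main():
    base = uv_sphere(12, 18, ring_z=0.5)
    r = 1 + 0.05 * np.sin(3 * base.vertices[:, 0]) \
        * np.cos(2 * base.vertices[:, 2])
    mesh = TriangleMesh(base.vertices * r[:, None], base.faces,
                        subject_id="M")
    perm = np.random.default_rng(0).permutation(mesh.n_vertices)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    mesh2 = TriangleMesh(mesh.vertices[perm], inv[mesh.faces],
                         subject_id="N")

    bundles = {}
    for m in (mesh, mesh2):
        ops = metric_operators(m, 0.0)
        bundles[m.subject_id] = (m, eigenbasis(ops, 24), ops)

    maps = {}
    for src, tgt in (("M", "N"), ("N", "M")):
        (ms, bs, _), (mt, bt, ot) = bundles[src], bundles[tgt]
        lm = initial_landmarks(ms, mt, 60, seed=5)
        f0 = fmap_from_landmarks(bs, bt, lm, k0=10)
        maps[(src, tgt)] = zoomout_refine(f0, bs, bt, ot, steps=6)

    vmap = pointwise_from_fmap(maps[("M", "N")], bundles["M"][1],
                               bundles["N"][1])
    recovered = np.mean(vmap.assignment == perm)
    cyc = cycle_consistency(maps[("M", "N")], maps[("N", "M")])
    print(f"vertices recovered: {recovered:.1%}")
    print(f"2-cycle consistency |C_NM C_MN - I|_F = {cyc:.2e}")
    print("\nA perfect correspondence recovers 100% of the permutation and"
          "\nhas near-zero cycle inconsistency; bad maps score far higher"
          "\nand are pruned from the map network.")


if __name__ == "__main__":
    main()
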