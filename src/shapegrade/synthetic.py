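"""Synthetic test data: the sphere-dome interpolation series and a labeled
two-class cohort of closed surfaces with phenotypes.

The sphere-dome series probes the extrinsic sensitivity of the descriptors:
``S_0`` is a sphere, ``S_1`` the same sphere with its dome above the cutting
plane ``z = c`` mirrored at that plane, and ``S_t`` the linear vertex
interpolation between them (shared connectivity). The sphere mesh carries a
vertex ring exactly on the cutting plane, so no edge straddles it and the
reflection is an exact Euclidean isometry: ``S_t`` and ``S_{1-t}`` have
identical edge lengths by construction, hence identical intrinsic geometry,
while their embeddings (and third fundamental forms) differ.

The cohort generator emulates a two-class anatomical study: per-subject
ellipsoidal blobs with smooth band-limited spherical-harmonic noise, a
class-dependent deformation (``bump`` = localized atrophy altering intrinsic
and extrinsic geometry; ``bend`` = dome mirroring, a near-isometric purely
extrinsic change), an optional fraction of genus-1 meshes via a stitched
handle (mimicking segmentation artifacts), and class-correlated ApoE
frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

from .meshes import TriangleMesh, validate_mesh


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Base meshes

def uv_sphere(n_rings: int = 16, n_lon: int = 24,
              ring_z: float | None = None) -> TriangleMesh:
    """Unit latitude/longitude sphere; optionally force a ring at ``z``.

    If ``ring_z`` is given, the interior ring closest to that height is
    snapped onto it exactly, so a cutting plane at that height intersects
    the mesh only along vertices.
    """
    if n_rings < 3 or n_lon < 3:
        raise SyntheticError("need at least 3 rings and 3 longitudes")
    theta = np.linspace(0.0, np.pi, n_rings + 2)[1:-1]
    z = np.cos(theta)
    if ring_z is not None:
        if not -1.0 < ring_z < 1.0:
            raise SyntheticError("ring_z must lie strictly between the poles")
        z[np.argmin(np.abs(z - ring_z))] = ring_z
    phi = 2.0 * np.pi * np.arange(n_lon) / n_lon
    verts = [np.array([[0.0, 0.0, 1.0]])]
    for zi in z:
        r = np.sqrt(max(1.0 - zi * zi, 0.0))
        verts.append(np.column_stack([r * np.cos(phi), r * np.sin(phi),
                                      np.full(n_lon, zi)]))
    verts.append(np.array([[0.0, 0.0, -1.0]]))
    V = np.vstack(verts)
    north, south = 0, len(V) - 1

    def ring(i, j):
        return 1 + i * n_lon + (j % n_lon)

    faces = []
    for j in range(n_lon):
        faces.append([north, ring(0, j), ring(0, j + 1)])
    for i in range(n_rings - 1):
        for j in range(n_lon):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j + 1), ring(i + 1, j)
            faces.append([a, d, c])
            faces.append([a, c, b])
    for j in range(n_lon):
        faces.append([south, ring(n_rings - 1, j + 1), ring(n_rings - 1, j)])
    return TriangleMesh(V, np.array(faces, dtype=np.int64))


def mirror_dome(vertices: np.ndarray, plane_height: float) -> np.ndarray:
    """Reflect all vertices above ``z = c`` at that plane."""
    out = vertices.copy()
    above = out[:, 2] > plane_height
    out[above, 2] = 2.0 * plane_height - out[above, 2]
    return out


@dataclass
class SphereDomeSeries:
    t_values: np.ndarray
    meshes: list
    plane_height: float


def sphere_dome_series(n_t: int = 9, subdivisions: int = 2,
                       plane_height: float = 0.5) -> SphereDomeSeries:
    """Linear interpolation series between a sphere and its dome-mirrored
    counterpart, with t sampled uniformly on [0, 1].

    ``subdivisions`` controls mesh resolution (rings and longitudes double
    per level). All members share connectivity; members ``S_t`` and
    ``S_{1-t}`` are exactly isometric.
    """
    if n_t < 2:
        raise SyntheticError("need n_t >= 2")
    if not 0.0 < plane_height < 1.0:
        raise SyntheticError("cutting plane must lie strictly below the pole")
    n_rings = 8 * 2 ** subdivisions
    n_lon = 12 * 2 ** subdivisions
    base = uv_sphere(n_rings, n_lon, ring_z=plane_height)
    V0 = base.vertices
    V1 = mirror_dome(V0, plane_height)
    ts = np.linspace(0.0, 1.0, n_t)
    meshes = []
    for t in ts:
        m = TriangleMesh((1.0 - t) * V0 + t * V1, base.faces.copy(),
                         subject_id=f"S_{t:.3f}")
        meshes.append(m)
    return SphereDomeSeries(t_values=ts, meshes=meshes,
                            plane_height=plane_height)


# ---------------------------------------------------------------------------
# Cohort generation

def _real_sph_harm(l: int, m: int, theta: np.ndarray,
                   phi: np.ndarray) -> np.ndarray:
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.real
    if m < 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.imag
    return y.real


def _band_limited_noise(directions: np.ndarray, rng: np.random.Generator,
                        amplitude: float, l_min: int = 2,
                        l_max: int = 4) -> np.ndarray:
    """Smooth random scalar field on the sphere (normalized to the requested
    RMS amplitude)."""
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    field = np.zeros(len(directions))
    for l in range(l_min, l_max + 1):
        for m in range(-l, l + 1):
            field += rng.normal(0.0, 1.0 / (1 + l)) \
                * _real_sph_harm(l, m, theta, phi)
    rms = np.sqrt(np.mean(field ** 2))
    if rms > 0:
        field *= amplitude / rms
    return field


def _mesh_vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fn = np.cross(vertices[faces[:, 1]] - vertices[faces[:, 0]],
                  vertices[faces[:, 2]] - vertices[faces[:, 0]])
    normals = np.zeros_like(vertices)
    for c in range(3):
        np.add.at(normals, faces[:, c], fn)
    nrm = np.linalg.norm(normals, axis=1)
    nrm[nrm == 0] = 1.0
    return normals / nrm[:, None]


def _tube_faces(loop1: np.ndarray, loop2: np.ndarray) -> np.ndarray:
    """Six triangles of a triangular tube traversing loop1 forward and
    loop2 as given."""
    out = []
    for i in range(3):
        a, b = loop1[i], loop1[(i + 1) % 3]
        qa, qb = loop2[(-i) % 3], loop2[(-i - 1) % 3]
        out.append([a, b, qb])
        out.append([a, qb, qa])
    return np.array(out, dtype=np.int64)


def _oriented_manifold(faces: np.ndarray) -> bool:
    """True iff every directed edge appears exactly once."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    _, counts = np.unique(e, axis=0, return_counts=True)
    return bool(np.all(counts == 1))


def add_handle(mesh: TriangleMesh, region_direction=(0.0, 0.0, -1.0),
               ) -> TriangleMesh:
    """Attach a thin handle (genus +1) by removing two nearby faces and
    stitching their boundary triangles with a six-triangle tube.

    The two faces are chosen in the region pointed to by
    ``region_direction`` and must not share vertices. Orientation of the
    tube is resolved by trying the cyclic/reflected pairings and keeping
    the one that restores an oriented manifold.
    """
    v, f = mesh.vertices, mesh.faces
    centers = v[f].mean(axis=1)
    d = np.asarray(region_direction, float)
    d = d / np.linalg.norm(d)
    score = centers @ d
    order = np.argsort(-score)
    f1 = order[0]
    # vertices adjacent to the first face (tube edges must all be new)
    f1_verts = set(f[f1])
    blocked = set(f1_verts)
    for face in f:
        if f1_verts & set(face):
            blocked |= set(face)
    f2 = None
    for cand in order[1:]:
        if not blocked & set(f[cand]):
            f2 = cand
            break
    if f2 is None:
        raise SyntheticError("no disjoint face pair found for the handle")
    keep = np.ones(len(f), dtype=bool)
    keep[[f1, f2]] = False
    base = f[keep]
    loop1, loop2 = f[f1], f[f2]
    for variant in range(6):
        rot, flip = variant % 3, variant // 3
        l2 = np.roll(loop2, rot)
        if flip:
            l2 = l2[::-1]
        candidate = np.vstack([base, _tube_faces(loop1, l2)])
        if _oriented_manifold(candidate):
            out = TriangleMesh(v.copy(), candidate, mesh.subject_id,
                               mesh.side, dict(mesh.metadata))
            return out
    raise SyntheticError("could not stitch an oriented handle")


@dataclass
class SyntheticCohort:
    meshes: dict                      # (subject_id, side) -> TriangleMesh
    labels: np.ndarray                # 0 = CN, 1 = AD per subject
    label_names: list
    phenotypes: pd.DataFrame
    subject_ids: list
    sides: list
    effect_kind: str
    effect_size: float
    genus1_fraction: float
    seed: int
    extra: dict = field(default_factory=dict)


_ELLIPSOID_AXES = np.array([1.0, 0.85, 0.75])
_BUMP_DIRECTION = np.array([0.0, 0.0, 1.0])
_BUMP_WIDTH = 0.55          # radians, angular std of the atrophy profile
_NOISE_AMPLITUDE = 0.015    # RMS radial noise relative to unit radius


def _make_subject_mesh(rng: np.random.Generator, label: int, side: str,
                       effect_kind: str, effect_size: float,
                       with_handle: bool, n_rings: int, n_lon: int,
                       bend_plane: float) -> TriangleMesh:
    base = uv_sphere(n_rings, n_lon, ring_z=bend_plane)
    V = base.vertices.copy()
    dirs = base.vertices  # unit sphere directions, shared across subjects
    if label == 1 and effect_kind == "bend" and effect_size > 0:
        V = mirror_dome(V, bend_plane)
    if label == 1 and effect_kind == "bump" and effect_size > 0:
        angle = np.arccos(np.clip(dirs @ _BUMP_DIRECTION, -1.0, 1.0))
        profile = np.exp(-0.5 * (angle / _BUMP_WIDTH) ** 2)
        V = V * (1.0 - effect_size * profile)[:, None]
    # smooth subject-specific noise along the current normals, sampled at
    # the shared unit-sphere directions so both classes see the same field
    # statistics
    noise = _band_limited_noise(dirs, rng, _NOISE_AMPLITUDE)
    V = V + noise[:, None] * _mesh_vertex_normals(V, base.faces)
    V = V * _ELLIPSOID_AXES
    faces = base.faces.copy()
    if side == "left":
        V = V * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, [0, 2, 1]]
    mesh = TriangleMesh(V, faces, side=side)
    if with_handle:
        mesh = add_handle(mesh, region_direction=(0.3, 0.2, -0.95))
    return mesh


def synthetic_cohort(n: int, effect_kind: str = "bump",
                     effect_size: float = 0.15,
                     genus1_fraction: float = 0.0,
                     sides: str = "right", seed: int = 0,
                     n_rings: int = 12, n_lon: int = 18,
                     class_fraction: float = 0.5,
                     apoe_risk_association: float = 0.5) -> SyntheticCohort:
    """Generate a labeled two-class cohort of closed surfaces.

    Class 1 subjects carry the requested deformation; a ``genus1_fraction``
    of subjects (rounded per side) receives a thin handle away from the
    effect region. Regeneration with the same seed is bitwise identical.
    """
    if n < 4:
        raise SyntheticError("need at least 4 subjects")
    if effect_kind not in ("bump", "bend"):
        raise SyntheticError(f"unknown effect kind {effect_kind!r}")
    if effect_size < 0:
        raise SyntheticError("effect_size must be nonnegative")
    side_list = {"left": ["left"], "right": ["right"],
                 "both": ["left", "right"]}[sides]
    n_class1 = int(round(n * class_fraction))
    labels = np.array([0] * (n - n_class1) + [1] * n_class1, dtype=np.int64)
    master = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    labels = labels[master.permutation(n)]
    n_handles = int(round(n * genus1_fraction))
    handle_subjects = set(master.choice(n, size=n_handles, replace=False)
                          .tolist()) if n_handles else set()
    bend_plane = max(1.0 - 2.0 * effect_size, 0.2) if effect_kind == "bend" \
        else 0.5
    subject_ids = [f"subj{str(i).zfill(3)}" for i in range(n)]
    meshes = {}
    for i, sid in enumerate(subject_ids):
        for side in side_list:
            sub = 0
            while True:
                side_code = {"left": 1, "right": 2, "none": 3}[side]
                rng = np.random.default_rng(np.random.SeedSequence(
                    [seed, 1 + i, side_code, sub]))
                mesh = _make_subject_mesh(
                    rng, int(labels[i]), side, effect_kind, effect_size,
                    i in handle_subjects, n_rings, n_lon, bend_plane)
                mesh.subject_id = sid
                areas = _face_areas(mesh)
                if areas.min() > 1e-12:
                    break
                sub += 1
                warnings.warn(f"degenerate faces for {sid}/{side}; "
                              f"regenerating with sub-seed {sub}",
                              stacklevel=2)
            meshes[(sid, side)] = mesh
    phenotypes = synthetic_phenotypes(labels, apoe_risk_association,
                                      seed=seed + 1)
    phenotypes.insert(0, "subject_id", subject_ids)
    return SyntheticCohort(meshes=meshes, labels=labels,
                           label_names=["CN", "AD"], phenotypes=phenotypes,
                           subject_ids=subject_ids, sides=side_list,
                           effect_kind=effect_kind, effect_size=effect_size,
                           genus1_fraction=genus1_fraction, seed=seed)


def _face_areas(mesh: TriangleMesh) -> np.ndarray:
    v, f = mesh.vertices, mesh.faces
    return 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1)


_APOE_BASE = {"E2": 0.1, "E3": 0.6, "E4": 0.3}


def synthetic_phenotypes(labels: np.ndarray, apoe_risk_association: float = 0.5,
                         seed: int = 0) -> pd.DataFrame:
    """Random sex and class-conditional ApoE genotypes.

    Controls draw from the base frequencies (E2 10%, E3 60%, E4 30%); in
    the diseased class the E4 probability is raised to
    ``0.3 + association * 0.7`` with the E2:E3 ratio preserved, so
    ``association = 0`` gives identical class-conditional distributions and
    ``association = 1`` makes every diseased subject an E4 carrier.
    """
    if not 0.0 <= apoe_risk_association <= 1.0:
        raise SyntheticError("association must lie in [0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 42]))
    n = len(labels)
    sex = rng.choice(["F", "M"], size=n)
    p4 = _APOE_BASE["E4"] + apoe_risk_association * (1.0 - _APOE_BASE["E4"])
    rest = 1.0 - p4
    p_case = np.array([rest / 7.0, 6.0 * rest / 7.0, p4])
    p_ctrl = np.array([_APOE_BASE["E2"], _APOE_BASE["E3"], _APOE_BASE["E4"]])
    genotypes = np.array(["E2", "E3", "E4"])
    apoe = np.where(labels == 1,
                    rng.choice(genotypes, size=n, p=p_case),
                    rng.choice(genotypes, size=n, p=p_ctrl))
    return pd.DataFrame({"sex": sex, "apoe": apoe,
                         "label": np.where(labels == 1, "AD", "CN")})


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write PLY meshes, pheno.csv and truth.json for a generated cohort."""
    import json
    from pathlib import Path
    from .meshes import write_mesh

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (sid, side), mesh in cohort.meshes.items():
        write_mesh(mesh, out / f"{sid}_{side}.ply")
    for i, sid in enumerate(cohort.subject_ids):
        rec = cohort.phenotypes.iloc[i]
        for side in cohort.sides:
            rows.append({"subject_id": sid, "side": side,
                         "sex": rec["sex"], "apoe": rec["apoe"],
                         "label": rec["label"]})
    pd.DataFrame(rows).to_csv(out / "pheno.csv", index=False)
    truth = {"labels": {sid: int(l) for sid, l in
                        zip(cohort.subject_ids, cohort.labels)},
             "effect_kind": cohort.effect_kind,
             "effect_size": cohort.effect_size,
             "seed": cohort.seed}
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
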