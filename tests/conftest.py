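"""Shared fixtures: analytic toy meshes and small knee models."""
import numpy as np
import pytest

from tkrsim.geometry import ImplantParams, SurfaceMesh


def make_sphere_mesh(radius=20.0, centre=(0.0, 0.0, 0.0), subdivisions=3):
    """Icosphere with the exact sphere signed-depth field attached."""
    import trimesh
    c = np.asarray(centre, dtype=float)
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    tm.apply_translation(c)

    def sdf(points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return radius - np.linalg.norm(p - c, axis=1)

    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       articular=np.ones(len(tm.faces), bool),
                       compartment=np.ones(len(tm.faces), dtype=int),
                       distance_field=sdf,
                       metadata={"kind": "sphere", "radius": radius,
                                 "centre": c})


def _grid_surface(xs, zs, height_fn):
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    Y = height_fn(X, Z)
    verts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    nx, nz = len(xs) - 1, len(zs) - 1
    idx = np.arange((nx + 1) * (nz + 1)).reshape(nx + 1, nz + 1)
    a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
    c, d = idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()
    faces = np.concatenate([np.stack([a, b, c], axis=1),
                            np.stack([a, c, d], axis=1)])
    # orient upwards
    v = verts[faces]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    flip = n[:, 1] < 0
    faces[flip] = faces[flip][:, ::-1]
    return verts, faces


def make_plane_mesh(half_extent=6.0, edge=0.25, y0=0.0):
    """Flat foundation surface in the x-z plane, normals +y."""
    n = int(np.ceil(2 * half_extent / edge))
    xs = np.linspace(-half_extent, half_extent, n + 1)
    verts, faces = _grid_surface(xs, xs, lambda X, Z: np.full_like(X, y0))
    comp = np.where(verts[faces].mean(axis=1)[:, 2] >= 0, 1, -1)
    return SurfaceMesh(verts, faces, articular=np.ones(len(faces), bool),
                       compartment=comp, metadata={"kind": "plane"})


def make_spherical_dish_mesh(dish_radius=30.0, half_extent=6.0, edge=0.25):
    """Concave spherical dish opening upwards, floor at the origin."""
    n = int(np.ceil(2 * half_extent / edge))
    xs = np.linspace(-half_extent, half_extent, n + 1)

    def height(X, Z):
        r2 = X ** 2 + Z ** 2
        return dish_radius - np.sqrt(dish_radius ** 2 - r2)

    verts, faces = _grid_surface(xs, xs, height)
    comp = np.ones(len(faces), dtype=int)
    return SurfaceMesh(verts, faces, articular=np.ones(len(faces), bool),
                       compartment=comp,
                       metadata={"kind": "dish", "dish_radius": dish_radius})


@pytest.fixture(scope="session")
def implant_params():
    return ImplantParams()


@pytest.fixture(scope="session")
def femoral_mesh(implant_params):
    from tkrsim.geometry import make_femoral_component
    return make_femoral_component(implant_params)


@pytest.fixture(scope="session")
def insert_mesh(implant_params):
    from tkrsim.geometry import make_tibial_insert
    return make_tibial_insert(implant_params)


@pytest.fixture(scope="session")
def default_model():
    import tkrsim
    return tkrsim.build_model()


@pytest.fixture()
def sphere_plane():
    """Rigid 20 mm sphere pressed 0.1 mm into an elastic-foundation plane."""
    sphere = make_sphere_mesh(radius=20.0, centre=(0.0, 19.9, 0.0))
    plane = make_plane_mesh(half_extent=6.0, edge=0.25)
    return sphere, plane
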