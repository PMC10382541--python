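"""Samplers: membership equations, determinism, distributional sanity."""

import numpy as np
import pytest

from persig.samplers import (MODEL_NAMES, ModelSpec, PointCloud, delay_embed,
                             linkage_vertices, read_series, sample,
                             sample_eight, sample_mesh)

ALL_MODELS = list(MODEL_NAMES)


@pytest.mark.parametrize("model", ALL_MODELS)
def test_sampling_is_deterministic_and_finite(model):
    a = sample(model, 40, seed=123)
    b = sample(model, 40, seed=123)
    c = sample(model, 40, seed=124)
    assert np.array_equal(a.points, b.points)
    assert not np.array_equal(a.points, c.points)
    assert np.all(np.isfinite(a.points))
    assert a.n == 40


def test_pointcloud_validation():
    with pytest.raises(ValueError):
        PointCloud(np.array([[np.nan, 0.0]]))
    with pytest.raises(ValueError):
        PointCloud(np.empty((0, 2)))
    pc = PointCloud(np.ones((3, 2)))
    assert pc.n == 3 and pc.dim == 2


def test_model_spec_rejects_bad_parameters():
    with pytest.raises(ValueError):
        ModelSpec("does-not-exist")
    with pytest.raises(ValueError):
        ModelSpec("torus", params={"R1": 1.0, "R2": 2.0})
    with pytest.raises(ValueError):
        ModelSpec("annulus", params={"r_in": 1.0, "r_out": 0.5})
    with pytest.raises(ValueError):
        ModelSpec("torus", dim=5)          # fixed ambient dimension
    with pytest.raises(ValueError):
        ModelSpec("box", params={"bogus": 1.0})


def test_torus_membership():
    pc = sample("torus", 300, seed=0)
    x, y, z = pc.points.T
    resid = (np.hypot(x, y) - 2.0) ** 2 + z ** 2 - 1.0
    assert np.max(np.abs(resid)) < 1e-9


def test_sphere_membership_and_centering():
    pc = sample("sphere", 4000, seed=1, d=2)
    norms = np.linalg.norm(pc.points, axis=1)
    assert np.max(np.abs(norms - 1.0)) < 1e-9
    # mean vector is 0 within 3 sigma (each coordinate has variance 1/3)
    se = np.sqrt(1.0 / 3.0 / 4000)
    assert np.all(np.abs(pc.points.mean(axis=0)) < 3 * se)


def test_klein_membership():
    pc = sample("klein", 500, seed=2)
    x1, x2, x3, x4 = pc.points.T
    r = np.hypot(x1, x2)                   # = 1 + cos(theta)
    resid = (x3 ** 2 + x4 ** 2) - (1.0 - (r - 1.0) ** 2)
    assert np.max(np.abs(resid)) < 1e-9


def test_projective_membership():
    pc = sample("projective", 500, seed=3)
    x1, x2, x3, x4 = pc.points.T
    s = np.sqrt(x3 ** 2 + x4 ** 2)         # = 1 - u^2
    resid = x1 ** 2 + x2 ** 2 - (1.0 - s) * s
    assert np.max(np.abs(resid)) < 1e-9


def test_annulus_radii_and_box_mean():
    pc = sample("annulus", 2000, seed=4, d=3)
    r = np.linalg.norm(pc.points, axis=1)
    assert np.all((r >= 0.5) & (r <= 1.0))
    box = sample("box", 5000, seed=5, d=2)
    se = np.sqrt(1.0 / 12.0 / 5000)
    assert np.all(np.abs(box.points.mean(axis=0) - 0.5) < 3 * se)


def test_stratified_plane_fraction():
    pc = sample("stratified", 4000, seed=6, p=0.3)
    frac = np.mean(pc.points[:, 2] == 0.0)
    se = np.sqrt(0.3 * 0.7 / 4000)
    assert abs(frac - 0.3) < 3 * se


def test_brownian_is_partial_sum_with_unit_increments():
    pc = sample("brownian", 5000, seed=7, d=2)
    inc = np.diff(pc.points, axis=0)
    # unit variance per coordinate, 3 sigma of the sampling error of var
    assert np.all(np.abs(inc.var(axis=0) - 1.0) < 3 * np.sqrt(2 / 4999))
    assert np.all(np.abs(inc.mean(axis=0)) < 3 / np.sqrt(4999))
    # first row is the first increment itself
    rng = np.random.default_rng(7)
    z = rng.standard_normal((5000, 2))
    assert np.allclose(pc.points[0], z[0])


def test_lorenz_matches_manual_rk4_step():
    # one integrator substep checked against hand-rolled RK4
    pc = sample("lorenz", 3, seed=8, dt=0.001, substeps=1)
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 1, 3)
    assert np.allclose(pc.points[0], x)

    def rhs(v):
        return np.array([45.0 * (v[1] - v[0]),
                         v[0] * (54.0 - v[2]) - v[1],
                         v[0] * v[1] - 10.0 * v[2]])

    h = 0.001
    k1 = rhs(x)
    k2 = rhs(x + h / 2 * k1)
    k3 = rhs(x + h / 2 * k2)
    k4 = rhs(x + h * k3)
    step = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    assert np.allclose(pc.points[1], step, rtol=1e-12)
    euler = sample("lorenz", 3, seed=8, dt=0.001, substeps=1,
                   method="euler")
    assert np.allclose(euler.points[1], x + h * rhs(x), rtol=1e-12)
    # the default trajectory stays on the attractor (bounded)
    traj = sample("lorenz", 200, seed=8)
    assert np.all(np.isfinite(traj.points))
    assert np.max(np.abs(traj.points)) < 500


def test_linkage_unit_edges_and_example():
    # worked example: phi = theta = pi/2 with the positive branch
    p3, p4, p5 = linkage_vertices(np.pi / 2, np.pi / 2, +1)
    assert np.allclose(p5, [0, 1]) and np.allclose(p3, [1, 1])
    assert np.allclose(p4, [0.5, 1 - np.sqrt(0.75)])
    # brute-force check: p4 lies on both unit circles about p3 and p5
    for s in (+1, -1):
        _, p4s, _ = linkage_vertices(np.pi / 2, np.pi / 2, s)
        assert abs(np.linalg.norm(p4s - p3) - 1) < 1e-12
        assert abs(np.linalg.norm(p4s - p5) - 1) < 1e-12
    with pytest.raises(ValueError):
        linkage_vertices(np.pi, 0.0, 1)    # |p3 - p5| = 3 > 2


def test_linkage_samples_close_up_and_balance_branches():
    pc = sample("linkage", 2000, seed=9)
    p3, p4, p5 = pc.points[:, :2], pc.points[:, 2:4], pc.points[:, 4:6]
    p2 = np.array([1.0, 0.0])
    lengths = [np.linalg.norm(p3 - p2, axis=1),
               np.linalg.norm(p4 - p3, axis=1),
               np.linalg.norm(p5 - p4, axis=1),
               np.linalg.norm(p5, axis=1)]          # p5 - p1, p1 = origin
    for d in lengths:
        assert np.max(np.abs(d - 1.0)) < 1e-9
    # both circle-intersection branches occur about equally often
    q = 0.5 * (p3 + p5)
    perp = np.column_stack([q[:, 1] - p5[:, 1], p5[:, 0] - q[:, 0]])
    side = np.sign(np.einsum("ij,ij->i", p4 - q, perp))
    frac = np.mean(side > 0)
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 2000)


def test_delay_embed_examples():
    rows = delay_embed([1, 2, 3, 4, 5, 6], 2, stride=1, lag=1, n=3).points
    assert np.array_equal(rows, [[1, 2], [2, 3], [3, 4]])
    col = delay_embed(np.arange(10.0), 1, stride=2, lag=1).points
    assert col.shape == (5, 1) and np.array_equal(col.ravel(), [0, 2, 4, 6, 8])
    # length 100, defaults stride=3 lag=7, embed_dim=3: max n is 29
    full = delay_embed(np.arange(100.0), 3)
    assert full.n == 29
    with pytest.raises(ValueError):
        delay_embed(np.arange(100.0), 3, n=30)
    with pytest.raises(ValueError):
        delay_embed([1.0, 2.0], 5)


def test_read_series_text_and_wav(tmp_path):
    txt = tmp_path / "sig.txt"
    np.savetxt(txt, np.arange(8.0))
    assert np.array_equal(read_series(txt), np.arange(8.0))
    from scipy.io import wavfile
    wav = tmp_path / "sig.wav"
    data = (np.sin(np.linspace(0, 1, 50)) * 30000).astype(np.int16)
    wavfile.write(wav, 8000, data)
    assert np.array_equal(read_series(wav), data.astype(float))


def test_eight_on_curve_membership_and_neck_gap():
    pc = sample_eight(400, neck_width=1e-9, noise_sigma=0.0, seed=0)
    d_left = np.linalg.norm(pc.points - [-1, 0], axis=1)
    d_right = np.linalg.norm(pc.points - [1, 0], axis=1)
    assert np.max(np.abs(np.minimum(d_left, d_right) - 1.0)) < 1e-9
    pc = sample_eight(2000, neck_width=0.4, noise_sigma=0.0, seed=1)
    r0 = np.linalg.norm(pc.points, axis=1)
    assert np.all(r0 >= 0.2)
    # the retained arcs start right at the deletion ball of radius W/2
    assert r0.min() < 0.2 + 0.05
    with pytest.raises(ValueError):
        sample_eight(10, neck_width=2.5)


def test_mesh_sampling_single_triangle(right_triangle_off):
    pc = sample_mesh(right_triangle_off, 500, seed=0)
    x, y = pc.points[:, 0], pc.points[:, 1]
    assert np.all(pc.points[:, 2] == 0.0)
    assert np.all((x >= 0) & (y >= 0) & (x + y <= 1 + 1e-12))


def test_mesh_sampling_area_weighting(tmp_path):
    # two coplanar triangles with areas 1/2 and 3/2 (ratio 1:3)
    off = tmp_path / "two.off"
    off.write_text(
        "OFF\n5 2 0\n"
        "0 0 0\n1 0 0\n0 1 0\n"
        "2 0 0\n2 3 0\n"
        "3 0 1 2\n3 1 3 4\n")
    pc = sample_mesh(off, 10000, seed=3)
    in_first = pc.points[:, 0] <= 1.0
    frac = in_first.mean()
    se = np.sqrt(0.25 * 0.75 / 10000)
    assert abs(frac - 0.25) < 3 * se


def test_mesh_sampling_on_cube_surface():
    import trimesh
    mesh = trimesh.creation.box(extents=(1, 1, 1))
    pc = sample_mesh(mesh, 300, seed=4)
    face_dist = np.min(np.abs(0.5 - np.abs(pc.points)), axis=1)
    assert np.max(face_dist) < 1e-12
    assert np.max(np.abs(pc.points)) <= 0.5 + 1e-12


def test_mesh_empty_errors():
    import trimesh
    degenerate = trimesh.Trimesh(vertices=np.zeros((3, 3)),
                                 faces=[[0, 1, 2]], process=False)
    with pytest.raises(ValueError):
        sample_mesh(degenerate, 5, seed=0)
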