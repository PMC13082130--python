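import numpy as np
import pytest

from splatmri.autodiff import Tensor
from splatmri.gaussians import (FrozenVoxelizer, GaussianCloud,
                                init_mbc_clouds, init_reference_cloud,
                                quat_to_rot, voxelize, voxelize_array)
from splatmri.grids import VoxelGrid

from conftest import numeric_gradient


def random_cloud(rng, m=10, channels=2, grad=True):
    cloud = GaussianCloud(
        positions=Tensor(rng.uniform(-5, 5, (m, 3)), requires_grad=grad),
        log_scales=Tensor(rng.uniform(0.2, 0.9, (m, 3)), requires_grad=grad),
        quaternions=Tensor(rng.normal(size=(m, 4)), requires_grad=grad),
        densities=Tensor(rng.normal(size=(m, channels)), requires_grad=grad),
        channel_kind="complex" if channels == 2 else "real")
    return cloud


def dense_oracle(cloud, grid):
    """Untruncated double-loop evaluation."""
    coords = grid.dense_coords()
    sigma = cloud.covariances()
    out = np.zeros((cloud.n_channels, coords.shape[0]))
    for i in range(cloud.n_kernels):
        d = coords - cloud.positions.data[i]
        a = np.linalg.inv(sigma[i])
        q = np.einsum("nj,jk,nk->n", d, a, d)
        g = np.exp(-0.5 * q)
        for c in range(cloud.n_channels):
            out[c] += cloud.densities.data[i, c] * g
    return out.reshape((cloud.n_channels,) + grid.shape)


def test_empty_cloud_gives_zero_field(small_grid):
    cloud = GaussianCloud.isotropic(np.zeros((0, 3)), 1.0,
                                    np.zeros((0, 1)), "real")
    assert np.all(voxelize(cloud, small_grid).data == 0)


def test_single_kernel_peak_value_one(small_grid):
    # kernel centered on a grid node with unit density -> field value 1
    node = small_grid.index_to_world(np.array([4, 4, 4]))
    cloud = GaussianCloud.isotropic(node[None], 2.0, np.array([[1.0]]), "real")
    field = voxelize(cloud, small_grid).data[0]
    assert field[4, 4, 4] == pytest.approx(1.0, abs=1e-12)


def test_voxelize_matches_dense_oracle(rng, small_grid):
    cloud = random_cloud(rng, m=10, grad=False)
    field = voxelize(cloud, small_grid, truncation_sigmas=8.0).data
    oracle = dense_oracle(cloud, small_grid)
    assert np.abs(field - oracle).max() < 1e-6


def test_truncation_error_bound(rng, small_grid):
    cloud = random_cloud(rng, m=6, channels=1, grad=False)
    trunc = 3.0
    truncated = voxelize(cloud, small_grid, truncation_sigmas=trunc).data
    dense = dense_oracle(cloud, small_grid)
    bound = np.abs(cloud.densities.data).sum() * np.exp(-trunc ** 2 / 2.0)
    assert np.abs(truncated - dense).max() <= bound + 1e-12


def test_voxelize_linear_in_densities(rng, small_grid):
    cloud = random_cloud(rng, m=5, channels=1, grad=False)
    da = rng.normal(size=(5, 1))
    db = rng.normal(size=(5, 1))
    f = {}
    for name, d in (("a", da), ("b", db), ("ab", da + db)):
        cloud.densities.data[...] = d
        f[name] = voxelize(cloud, small_grid).data
    assert np.allclose(f["ab"], f["a"] + f["b"], atol=1e-10)


def test_translation_equivariance(rng):
    grid = VoxelGrid((12, 12, 12), (2.0, 2.0, 2.0))
    cloud = random_cloud(rng, m=4, channels=1, grad=False)
    base = voxelize(cloud, grid, truncation_sigmas=6.0).data[0]
    cloud.positions.data[:, 0] += grid.spacing[0]
    shifted = voxelize(cloud, grid, truncation_sigmas=6.0).data[0]
    assert np.allclose(shifted[2:-1], base[1:-2], atol=1e-6)


def test_voxelize_gradients_match_finite_differences(rng):
    grid = VoxelGrid((6, 5, 4), (1.0, 1.2, 0.9))
    cloud = random_cloud(rng, m=3, channels=2)
    w = rng.normal(size=(2,) + grid.shape)

    def loss():
        return (voxelize(cloud, grid, truncation_sigmas=8.0) * Tensor(w)).sum()

    loss().backward()
    for p in cloud.parameters():
        num = numeric_gradient(loss, p)
        rel = np.abs(p.grad - num).max() / (np.abs(num).max() + 1e-12)
        assert rel < 1e-4


def test_non_finite_shape_parameters_rejected(small_grid, rng):
    cloud = random_cloud(rng, m=2, channels=1, grad=False)
    cloud.log_scales.data[0, 0] = np.nan
    with pytest.raises(ValueError):
        voxelize(cloud, small_grid)


def test_quat_to_rot_is_orthonormal(rng):
    q = rng.normal(size=(20, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    R = quat_to_rot(q)
    eye = np.einsum("mij,mkj->mik", R, R)
    assert np.allclose(eye, np.eye(3)[None], atol=1e-12)
    assert np.allclose(np.linalg.det(R), 1.0, atol=1e-12)


# -- initialization ----------------------------------------------------------


def test_init_reference_cloud_default_count_constant():
    from splatmri.gaussians import DEFAULT_REFERENCE_POINTS
    assert DEFAULT_REFERENCE_POINTS == 100_000


def test_init_reference_cloud_zero_volume(small_grid):
    cloud = init_reference_cloud(np.zeros(small_grid.shape, complex),
                                 small_grid, 10, seed=0)
    assert np.all(cloud.densities.data == 0)
    assert cloud.channel_kind == "complex"


def test_init_reference_cloud_correlates_with_target(rng):
    grid = VoxelGrid((32, 32, 8), (4.0, 4.0, 6.0))
    x, y, z = grid.coords()
    blob = np.exp(-((x / 40) ** 2 + (y / 40) ** 2 + (z / 20) ** 2))
    vol = blob * np.exp(1j * 0.3)
    cloud = init_reference_cloud(vol, grid, 600, seed=0)
    recon = voxelize_array(cloud, grid)
    mask = blob > 0.05
    r = np.corrcoef(np.abs(recon[mask]), np.abs(vol[mask]))[0, 1]
    assert r > 0.5


def test_init_reference_cloud_with_replacement_warns(small_grid):
    vol = np.ones(small_grid.shape, complex)
    with pytest.warns(UserWarning):
        init_reference_cloud(vol, small_grid, small_grid.nvoxels + 10, seed=0)


def test_init_mbc_clouds_structure(desk_grid):
    clouds = init_mbc_clouds(desk_grid, (2, 3, 4))
    assert len(clouds) == 9
    sizes = [c.n_kernels for c in clouds]
    assert sizes == [8, 8, 8, 27, 27, 27, 64, 64, 64]
    for c in clouds:
        assert np.all(c.densities.data == 0)
        assert c.channel_kind == "real"


def test_init_mbc_clouds_default_levels():
    from splatmri.gaussians import DEFAULT_MBC_LEVELS
    assert DEFAULT_MBC_LEVELS == (15, 20, 25)


def test_init_mbc_zero_densities_give_zero_fields(desk_grid):
    clouds = init_mbc_clouds(desk_grid, (2, 3, 4))
    for c in clouds[:3]:
        assert np.all(voxelize(c, desk_grid).data == 0)


def test_init_mbc_lattice_covers_grid(desk_grid):
    clouds = init_mbc_clouds(desk_grid, (2, 3, 4))
    fov = np.asarray(desk_grid.fov_mm)
    lo = np.asarray(desk_grid.origin) - 0.5 * np.asarray(desk_grid.spacing)
    for level, cloud in enumerate([clouds[0], clouds[3], clouds[6]]):
        shape = (2, 3, 4)[level]
        pitch = fov / shape
        pos = cloud.positions.data
        assert np.all(pos.min(axis=0) <= lo + pitch)
        assert np.all(pos.max(axis=0) >= lo + fov - pitch)


def test_init_mbc_requires_increasing_levels(desk_grid):
    with pytest.raises(ValueError):
        init_mbc_clouds(desk_grid, (4, 3, 2))


def test_frozen_voxelizer_matches_voxelize(rng, small_grid):
    cloud = random_cloud(rng, m=6, channels=1, grad=False)
    frozen = FrozenVoxelizer(cloud, small_grid, truncation_sigmas=4.0)
    direct = voxelize(cloud, small_grid, truncation_sigmas=4.0).data[0]
    assert np.allclose(frozen(cloud.densities).data, direct, atol=1e-10)


def test_frozen_voxelizer_gradient(rng, small_grid):
    cloud = random_cloud(rng, m=4, channels=1)
    frozen = FrozenVoxelizer(cloud, small_grid)
    w = rng.normal(size=small_grid.shape)

    def loss():
        return (frozen(cloud.densities) * Tensor(w)).sum()

    loss().backward()
    num = numeric_gradient(loss, cloud.densities)
    assert np.allclose(cloud.densities.grad, num, atol=1e-6)
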