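"""Rotation-coordinate construction and evaluation."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import landscape_bridge as lb
from landscape_bridge.rotation import axis_from_dict, axis_to_dict

from conftest import make_endpoint_models, truth_cores


def rotation_angle_deg(mat: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip((np.trace(mat) - 1) / 2, -1, 1))))


def make_p_structure(coords, label="model", chain="M"):
    """One P atom per residue at the given coordinates."""
    n = len(coords)
    return lb.Structure(
        chain_ids=[chain] * n,
        residue_numbers=list(range(1, n + 1)),
        residue_names=["U"] * n,
        atom_names=["P"] * n,
        coords=np.asarray(coords, float),
        label=label,
    )


def pair_search_oracle(coords_a, coords_b):
    """Exhaustive enumeration of P-pair angle changes, independent of the
    implementation's scoring loop."""
    best_ang, best_pair = -1.0, None
    for i, j in combinations(range(len(coords_a)), 2):
        va = coords_a[j] - coords_a[i]
        vb = coords_b[j] - coords_b[i]
        cos = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
        ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        if ang > best_ang:
            best_ang, best_pair = ang, (i, j)
    return best_ang, best_pair


def two_core_models(moving_a, moving_b, seed=0):
    """Fixed core (identical in both models) + a moving core that differs."""
    rng = np.random.default_rng(seed)
    fixed = rng.normal(scale=15, size=(8, 3)) - [40.0, 0.0, 0.0]
    n_f, n_m = len(fixed), len(moving_a)
    def build(moving):
        return lb.Structure(
            chain_ids=["F"] * n_f + ["M"] * n_m,
            residue_numbers=list(range(1, n_f + 1)) + list(range(1, n_m + 1)),
            residue_names=["U"] * (n_f + n_m),
            atom_names=["P"] * (n_f + n_m),
            coords=np.vstack([fixed, moving]),
        )
    fixed_core = lb.CoreSet("fixed", tuple(("F", i + 1) for i in range(n_f)), {}, ())
    moving_core = lb.CoreSet("moving", tuple(("M", i + 1) for i in range(n_m)), {}, ())
    return build(moving_a), build(moving_b), fixed_core, moving_core


class TestIdealize:
    def test_reference_frame_is_fixed_point(self):
        ref = np.random.default_rng(0).normal(scale=10, size=(20, 3))
        out = lb.idealize(ref, ref)
        assert np.allclose(out, ref, atol=1e-10)

    def test_recovers_known_rotation_under_noise(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(scale=12, size=(60, 3))
        rot = Rotation.from_rotvec(np.radians(9) * np.array([0, 0, 1.0])).as_matrix()
        frame = ref @ rot.T + rng.normal(scale=0.3, size=ref.shape)
        ideal = lb.idealize(frame, ref)
        fit = lb.superpose(ref, ideal)
        assert abs(rotation_angle_deg(fit.rotation) - 9.0) < 0.2

    def test_output_exactly_rigid(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(scale=10, size=(15, 3))
        frame = ref + rng.normal(scale=1.0, size=ref.shape)
        ideal = lb.idealize(frame, ref)
        d_ref = np.linalg.norm(ref[:, None] - ref[None], axis=-1)
        d_out = np.linalg.norm(ideal[:, None] - ideal[None], axis=-1)
        assert np.max(np.abs(d_ref - d_out)) < 1e-9


class TestFindMaxRotationPair:
    def test_identical_models_error(self):
        rng = np.random.default_rng(1)
        moving = rng.normal(scale=10, size=(10, 3))
        a, b, fixed_core, moving_core = two_core_models(moving, moving)
        with pytest.raises(ValueError, match="no rotation detected"):
            lb.find_max_rotation_pair(a, b, moving_core, fixed_core)

    def test_toy_twelve_atom_core_matches_oracle(self):
        rng = np.random.default_rng(6)
        moving = rng.normal(scale=8, size=(12, 3))
        moving[3, 2] = moving[9, 2]  # one pair exactly in the rotation plane
        moving[9, :2] = moving[3, :2] + [25.0, 0.0]
        rot = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        a, b, fixed_core, moving_core = two_core_models(moving, moving @ rot.T)
        axis = lb.find_max_rotation_pair(a, b, moving_core, fixed_core)
        oracle_ang, oracle_pair = pair_search_oracle(moving, moving @ rot.T)
        assert abs(axis.pair_angle_change - 10.0) < 1e-6
        assert abs(axis.pair_angle_change - oracle_ang) < 1e-9
        assert tuple(sorted(axis.pair)) == tuple(sorted(oracle_pair))
        # winning pair vector lies in the xy rotation plane
        v = moving[axis.pair[1]] - moving[axis.pair[0]]
        assert abs(v[2]) < 1e-9

    def test_random_axis_forty_atoms_matches_oracle(self):
        rng = np.random.default_rng(11)
        moving = rng.normal(scale=10, size=(40, 3))
        axis_vec = rng.normal(size=3)
        axis_vec /= np.linalg.norm(axis_vec)
        rot = Rotation.from_rotvec(np.radians(7.0) * axis_vec).as_matrix()
        a, b, fixed_core, moving_core = two_core_models(moving, moving @ rot.T)
        axis = lb.find_max_rotation_pair(a, b, moving_core, fixed_core)
        oracle_ang, oracle_pair = pair_search_oracle(moving, moving @ rot.T)
        assert abs(axis.pair_angle_change - oracle_ang) < 1e-9
        assert tuple(sorted(axis.pair)) == tuple(sorted(oracle_pair))
        # no pair can rotate by more than the core rotation itself,
        # and with 780 pairs some pair comes close to perpendicularity
        assert axis.pair_angle_change <= 7.0 + 1e-9
        assert axis.pair_angle_change > 6.9


@pytest.fixture(scope="module")
def axis_setup():
    spec = lb.AssemblySpec(n_fixed_core=30, n_moving_core=30, n_mobile=0,
                           core_jitter_sigma=0.0,
                           rotation_path=(0.0, 10.0), seed=13)
    classical, rotated, truth = make_endpoint_models(spec)
    fixed_core, moving_core = truth_cores(truth)
    axis = lb.find_max_rotation_pair(classical, rotated, moving_core,
                                     fixed_core)
    return classical, axis


class TestComputeAngle:
    def test_reference_model_reads_zero(self, axis_setup):
        classical, axis = axis_setup
        assert abs(lb.compute_angle(classical.coords, classical, axis)) < 1e-9

    def test_synthetic_five_degree_rotation(self, axis_setup):
        classical, axis = axis_setup
        coords = classical.coords.copy()
        moving_idx = classical.atom_indices(
            residues=[k for k, _ in axis.moving_keys])
        rot = Rotation.from_rotvec(
            np.radians(5.0) * axis.plane_normal).as_matrix()
        centroid = coords[moving_idx].mean(axis=0)
        coords[moving_idx] = (coords[moving_idx] - centroid) @ rot.T + centroid
        assert abs(lb.compute_angle(coords, classical, axis) - 5.0) < 0.05

    def test_invariant_under_global_rigid_transform(self, axis_setup):
        classical, axis = axis_setup
        rng = np.random.default_rng(3)
        rot = Rotation.random(random_state=5).as_matrix()
        trans = rng.uniform(-30, 30, 3)
        a0 = lb.compute_angle(classical.coords, classical, axis)
        a1 = lb.compute_angle(classical.coords @ rot.T + trans, classical, axis)
        assert abs(a0 - a1) < 1e-6

    @pytest.mark.parametrize("alpha", [-10.0, -5.0, 0.0, 5.0, 10.0, 20.0])
    def test_round_trip_over_angles(self, axis_setup, alpha):
        classical, axis = axis_setup
        coords = classical.coords.copy()
        moving_idx = classical.atom_indices(
            residues=[k for k, _ in axis.moving_keys])
        rot = Rotation.from_rotvec(
            np.radians(alpha) * axis.plane_normal).as_matrix()
        centroid = coords[moving_idx].mean(axis=0)
        coords[moving_idx] = (coords[moving_idx] - centroid) @ rot.T + centroid
        assert abs(lb.compute_angle(coords, classical, axis) - alpha) < 0.05

    def test_serialization_roundtrip(self, axis_setup):
        classical, axis = axis_setup
        restored = axis_from_dict(axis_to_dict(axis))
        a0 = lb.compute_angle(classical.coords, classical, axis)
        a1 = lb.compute_angle(classical.coords, classical, restored)
        assert a0 == a1


class TestLandmarkDistance:
    def test_centroid_distances(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 5.0, 0], [3.0, 4.0, 0]])
        s = make_p_structure(coords)
        key = lambda i: ((("M", i + 1)), "P")
        # coincident selections
        d0 = lb.landmark_distance(
            coords, s, lb.LandmarkDistance("d", (key(2),), (key(2),)))
        assert d0 == 0.0
        # two single atoms 3-4-5 triangle
        origin_pair = lb.LandmarkDistance("d", (key(0), key(1)), (key(3),))
        assert np.isclose(lb.landmark_distance(coords, s, origin_pair), 5.0)
        # centroid of +-x atoms is the origin, distance to (0,5,0) is 5
        mid = lb.LandmarkDistance("d", (key(0), key(1)), (key(2),))
        assert np.isclose(lb.landmark_distance(coords, s, mid), 5.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            lb.LandmarkDistance("d", (), ((("M", 1), "P"),))

    def test_built_from_text_selections(self):
        from landscape_bridge.rotation import landmark_from_selections

        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 4.0, 0]])
        s = make_p_structure(coords)
        definition = landmark_from_selections(s, "M:1-2", "M:3", label="demo")
        # centroid of residues 1-2 is (1,0,0); residue 3 sits 4 above it
        assert np.isclose(lb.landmark_distance(coords, s, definition), 4.0)


class TestAngleSeries:
    def test_static_trajectory_constant(self, static_assembly):
        _, topo, traj, truth = static_assembly
        classical, rotated, _ = make_endpoint_models(
            lb.AssemblySpec(n_fixed_core=30, n_moving_core=30, n_mobile=0,
                            rotation_path=(0.0, 10.0), seed=7))
        fixed_core, moving_core = truth_cores(truth)
        axis = lb.find_max_rotation_pair(classical, rotated, moving_core,
                                         fixed_core)
        series = lb.angle_series(traj, axis)
        assert np.ptp(series.values) < 1e-9

    def test_stride_subsamples(self, small_assembly):
        _, topo, traj, truth = small_assembly
        spec = lb.AssemblySpec(n_fixed_core=25, n_moving_core=25, n_mobile=10,
                               rotation_path=(0.0, 10.0), seed=42)
        classical, rotated, _ = make_endpoint_models(spec)
        fixed_core, moving_core = truth_cores(truth)
        axis = lb.find_max_rotation_pair(classical, rotated, moving_core,
                                         fixed_core)
        series = lb.angle_series(traj, axis, stride=6)
        assert len(series) == 10

    def test_recovers_prescribed_ramp_noiselessly(self):
        spec = lb.AssemblySpec(n_fixed_core=20, n_moving_core=20, n_mobile=0,
                               core_jitter_sigma=0.0,
                               rotation_path=tuple(np.linspace(0, 10, 101)),
                               seed=1)
        topo, traj, truth = lb.gen_assembly_trajectory(spec)
        classical, rotated, _ = make_endpoint_models(spec)
        fixed_core, moving_core = truth_cores(truth)
        axis = lb.find_max_rotation_pair(classical, rotated, moving_core,
                                         fixed_core)
        series = lb.angle_series(traj, axis)
        assert np.max(np.abs(series.values - truth.rotation_path)) < 0.05
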