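import numpy as np
import pytest
from helpers import linear_triple_trajectory, oracle_angle_deg, oracle_neighbor_counts
from hypothesis import given, settings
from hypothesis import strategies as st

from hbstab.hbonds import HBondID
from hbstab.predictors import (
    MayoParameters,
    average_time_varying,
    compute_environment,
    compute_first_energy,
    compute_geometric,
    compute_static,
    default_registry,
    featurize_trajectory,
    hybridization,
    mayo_energy,
    trailing_mean,
)
from hbstab.synthetic import SyntheticConfig, generate_trajectory
from hbstab.trajectory import Atom, Trajectory

BOND = HBondID(1, 2, 3)


def _triple(d, h, a, aa=None):
    atoms = [
        Atom(1, "N", "N", "ALA", 1, "A"),
        Atom(2, "H", "H", "ALA", 1, "A"),
        Atom(3, "O", "O", "GLY", 2, "A"),
    ]
    pts = [d, h, a]
    if aa is not None:
        atoms.append(Atom(4, "C", "C", "GLY", 2, "A"))
        pts.append(aa)
    coords = np.asarray(pts, dtype=float)[None]
    return Trajectory("p", 1.0, atoms, coords)


def test_collinear_geometry():
    traj = _triple([0, 0, 0], [1, 0, 0], [3, 0, 0])
    geom = compute_geometric(BOND, traj.conformations[0])
    assert geom["Dist_H_A"] == pytest.approx(2.0)
    assert geom["Dist_D_A"] == pytest.approx(3.0)
    assert geom["Dist_H_D"] == pytest.approx(1.0)
    assert geom["Angle_D_H_A"] == pytest.approx(180.0)


def test_right_angle_geometry():
    traj = _triple([0, 0, 0], [1, 0, 0], [1, 1, 0])
    geom = compute_geometric(BOND, traj.conformations[0])
    assert geom["Angle_D_H_A"] == pytest.approx(90.0)


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def test_random_triples_match_vector_math_oracle(rng):
    for _ in range(50):
        d, h, a = rng.normal(scale=2.0, size=(3, 3))
        aa = a + 1.3 * _random_unit(rng)  # keep the antecedent covalent
        if min(np.linalg.norm(d - h), np.linalg.norm(a - h)) < 1e-3:
            continue
        traj = _triple(d, h, a, aa)
        geom = compute_geometric(BOND, traj.conformations[0])
        assert geom["Angle_D_H_A"] == pytest.approx(
            oracle_angle_deg(d, h, a), abs=1e-9)
        if geom["Angle_H_A_AA"] == geom["Angle_H_A_AA"]:
            assert geom["Angle_H_A_AA"] == pytest.approx(
                oracle_angle_deg(h, a, aa), abs=1e-9)
        assert geom["Dist_D_AA"] == pytest.approx(
            np.linalg.norm(np.asarray(aa) - d), abs=1e-9)


def test_missing_antecedent_gives_missing_values():
    traj = _triple([0, 0, 0], [1, 0, 0], [3, 0, 0])  # no AA atom
    geom = compute_geometric(BOND, traj.conformations[0])
    assert np.isnan(geom["Dist_D_AA"])
    assert np.isnan(geom["Angle_H_A_AA"])


def test_geometric_invariant_under_rigid_transform(rng):
    d, h, a = rng.normal(scale=2.0, size=(3, 3))
    aa = a + 1.3 * _random_unit(rng)
    traj = _triple(d, h, a, aa)
    theta = 0.9
    rot = np.array([
        [np.cos(theta), 0, np.sin(theta)],
        [0, 1, 0],
        [-np.sin(theta), 0, np.cos(theta)],
    ])
    moved = Trajectory("p", 1.0, traj.atoms,
                       traj.coords @ rot.T + np.array([1.0, -8.0, 3.0]),
                       topology=traj.topology)
    ref = compute_geometric(BOND, traj.conformations[0])
    got = compute_geometric(BOND, moved.conformations[0])
    for name, value in ref.items():
        assert got[name] == pytest.approx(value, abs=1e-9)


# ---------------------------------------------------------------------------
# Mayo-form energy
# ---------------------------------------------------------------------------

def test_energy_minimum_closed_form():
    e = mayo_energy(2.8, 180.0, 109.5, "sp3", "sp3")
    assert e == pytest.approx(-8.0, abs=1e-9)


def test_energy_vanishes_at_90_degrees():
    assert mayo_energy(2.8, 90.0, 109.5, "sp3", "sp3") == pytest.approx(0.0)
    assert mayo_energy(2.8, 60.0, 109.5, "sp3", "sp3") == 0.0


def test_energy_power_law_decay():
    assert abs(mayo_energy(10.0, 180.0, 109.5, "sp3", "sp3")) < 0.02


def test_energy_never_positive(rng):
    r = rng.uniform(1.5, 6.0, 500)
    theta = rng.uniform(0.0, 180.0, 500)
    phi = rng.uniform(0.0, 180.0, 500)
    for dh in ("sp2", "sp3"):
        for ah in ("sp2", "sp3"):
            e = mayo_energy(r, theta, phi, dh, ah)
            assert (np.asarray(e) <= 0).all()


def test_energy_deepens_toward_linearity():
    thetas = np.linspace(95.0, 180.0, 30)
    e = mayo_energy(np.full_like(thetas, 2.8), thetas, 109.5, "sp3", "sp3")
    assert (np.diff(e) < 0).all()


def test_sp2_sp2_phi_floor():
    params = MayoParameters()
    low = mayo_energy(2.8, 180.0, 100.0, "sp2", "sp2", params)
    floor = mayo_energy(2.8, 180.0, params.phi_lower_deg, "sp2", "sp2", params)
    assert low == pytest.approx(floor)


def test_compute_first_energy_uses_hybridization_table():
    traj = linear_triple_trajectory(dist_ha=1.8, angle_dha_deg=180.0)
    e = compute_first_energy(BOND, traj.conformations[0])
    assert e < 0  # backbone N (sp2) -> carbonyl O (sp2), binding geometry


def test_unknown_hybridization_warns_and_defaults():
    atom = Atom(9, "XX", "N", "UNK", 1, "A")
    with pytest.warns(UserWarning, match="hybridization"):
        assert hybridization(atom) == "sp3"


# ---------------------------------------------------------------------------
# Environment counts
# ---------------------------------------------------------------------------

def test_single_bond_has_no_neighbors():
    traj = linear_triple_trajectory()
    env = compute_environment(BOND, [BOND], traj.conformations[0])
    assert env["Num_hb_spaceNbr"] == 0
    assert env["Num_hb_spaceRgdNbr"] == 0


def test_two_bonds_within_radius_count_each_other():
    cfg = SyntheticConfig(n_bonds=2, n_ticks=1, seed=0, mu=np.array([1.8, 1.8]),
                          s=1e-6, crowded=False, cluster_spacing=3.0)
    res = generate_trajectory(cfg)
    conf = res.trajectory.conformations[0]
    bonds = res.ground_truth.bonds
    for bond in bonds:
        env = compute_environment(bond, bonds, conf, radius=5.0)
        assert env["Num_hb_spaceNbr"] == 1


def test_environment_counts_match_brute_force_oracle():
    cfg = SyntheticConfig(n_bonds=12, n_ticks=3, seed=4,
                          mu=np.full(12, 2.0), s=0.05, crowded=True)
    res = generate_trajectory(cfg)
    traj = res.trajectory
    bonds = res.ground_truth.bonds
    presence = res.ground_truth.presence
    tv, _ = featurize_trajectory(traj, bonds, presence, default_registry(),
                                 env_radius=5.0)
    for t in range(traj.n_ticks):
        mids = np.array([
            0.5 * (traj.conformations[t].coord(b.hydrogen_serial)
                   + traj.conformations[t].coord(b.acceptor_serial))
            for b in bonds
        ])
        # oracle counts all pairs, then restrict to present others
        n = len(bonds)
        expected = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i != j and presence[t, j] and \
                        np.linalg.norm(mids[i] - mids[j]) <= 5.0:
                    expected[i] += 1
        np.testing.assert_array_equal(tv["Num_hb_spaceNbr"][t], expected)


def test_oracle_neighbor_counts_selfcheck(rng):
    pts = rng.normal(scale=3.0, size=(20, 3))
    counts = oracle_neighbor_counts(pts, 4.0)
    assert counts.sum() % 2 == 0  # symmetric relation


# ---------------------------------------------------------------------------
# Static predictors
# ---------------------------------------------------------------------------

def _static_bond(donor_name, donor_res, donor_num, acc_name, acc_res, acc_num,
                 chain_d="A", chain_a="A"):
    atoms = [
        Atom(1, donor_name, "N" if donor_name.startswith("N") else "O",
             donor_res, donor_num, chain_d),
        Atom(2, "H", "H", donor_res, donor_num, chain_d),
        Atom(3, acc_name, "O", acc_res, acc_num, chain_a),
    ]
    coords = np.array([[[0, 0, 0], [1, 0, 0], [2.8, 0, 0]]], dtype=float)
    return Trajectory("p", 1.0, atoms, coords)


def test_backbone_bond_static_values():
    traj = _static_bond("N", "ALA", 10, "O", "GLY", 6)
    static = compute_static(BOND, traj.topology)
    assert static["Ch_type"] == "MM"
    assert static["Range"] == 4
    assert static["Resi_name_H"] == "ALA"
    assert static["Resi_name_A"] == "GLY"


def test_same_residue_range_zero():
    traj = _static_bond("N", "SER", 7, "O", "SER", 7)
    assert compute_static(BOND, traj.topology)["Range"] == 0


def test_sidechain_donor_mainchain_acceptor():
    traj = _static_bond("OG", "SER", 3, "O", "ALA", 9)
    assert compute_static(BOND, traj.topology)["Ch_type"] == "SM"


def test_cross_chain_range_offset():
    traj = _static_bond("N", "ALA", 10, "O", "GLY", 6, chain_d="A", chain_a="B")
    assert compute_static(BOND, traj.topology)["Range"] == 1004


# ---------------------------------------------------------------------------
# Trailing-window averaging
# ---------------------------------------------------------------------------

def test_constant_series_any_window():
    series = {"Dist_H_A": np.full(20, 2.2)}
    out = average_time_varying(series, 7, 5, default_registry())
    assert out["Dist_H_A"] == pytest.approx(2.2)


def test_truncated_window_mean():
    series = {"Dist_H_A": np.array([2.0, 2.2, 2.4])}
    out = average_time_varying(series, 2, 50, default_registry())
    assert out["Dist_H_A"] == pytest.approx(2.2)


def test_window_of_one_is_identity():
    values = np.array([1.0, 5.0, 9.0, 2.0])
    np.testing.assert_array_equal(trailing_mean(values, 1), values)


@given(st.integers(1, 12), st.integers(min_value=2, max_value=60),
       st.integers(0, 2**31 - 1))
@settings(max_examples=60, deadline=None)
def test_trailing_mean_matches_loop_oracle(window, n, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=n)
    values[rng.random(n) < 0.15] = np.nan
    got = trailing_mean(values, window)
    for i in range(n):
        chunk = values[max(0, i - window + 1):i + 1]
        finite = chunk[np.isfinite(chunk)]
        if finite.size == 0:
            assert np.isnan(got[i])
        else:
            assert got[i] == pytest.approx(finite.mean(), abs=1e-12)


def test_white_noise_variance_reduction(rng):
    l_prime = 50
    raw = rng.standard_normal(10_000)
    averaged = trailing_mean(raw, l_prime)[l_prime:]
    ratio = averaged.var() / (raw.var() / l_prime)
    assert 0.7 < ratio < 1.3


def test_degenerate_angle_warns():
    traj = _triple([1, 0, 0], [1, 0, 0], [3, 0, 0])  # D == H
    with pytest.warns(UserWarning):
        geom = compute_geometric(BOND, traj.conformations[0])
    assert np.isnan(geom["Angle_D_H_A"])


def test_featurized_values_match_scalar_path(small_synthetic):
    traj = small_synthetic.trajectory
    truth = small_synthetic.ground_truth
    bonds = truth.bonds
    tv, static = featurize_trajectory(traj, bonds, truth.presence)
    conf = traj.conformations[3]
    for k, bond in enumerate(bonds):
        geom = compute_geometric(bond, conf)
        for name in ("Dist_H_A", "Dist_D_A", "Dist_H_D", "Angle_D_H_A",
                     "Dist_D_AA", "Angle_H_A_AA"):
            assert tv[name][3, k] == pytest.approx(geom[name], abs=1e-9)
        assert tv["FIRST_energy"][3, k] == pytest.approx(
            compute_first_energy(bond, conf), abs=1e-9)


def test_generator_geometry_matches_recomputation(small_synthetic):
    truth = small_synthetic.ground_truth
    tv, _ = featurize_trajectory(small_synthetic.trajectory, truth.bonds,
                                 truth.presence)
    np.testing.assert_allclose(tv["Dist_H_A"], truth.dist_ha, atol=1e-9)
    np.testing.assert_allclose(tv["Angle_D_H_A"], truth.theta_deg, atol=1e-6)
    np.testing.assert_allclose(tv["Angle_H_A_AA"], truth.phi_deg, atol=1e-6)
    np.testing.assert_allclose(tv["Dist_D_A"], truth.dist_da, atol=1e-9)
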