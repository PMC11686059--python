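import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netenergy.core_energy import (
    CANONICAL_NETWORKS,
    CONDITIONS,
    WHOLE_BRAIN,
    ConnectivityMatrix,
    Parcellation,
    brute_force_energy,
    energy_delta,
    energy_table,
    network_energy,
    signed_cbrt,
    subnetwork_energy,
    triangle_census,
)
from netenergy.synthetic_data import make_parcellation

from conftest import complete_matrix, random_matrix


class TestSignedCbrt:
    @pytest.mark.parametrize(
        "x,expected", [(0.125, 0.5), (-1.0, -1.0), (0.0, 0.0), (8.0, 2.0), (-0.027, -0.3)]
    )
    def test_values(self, x, expected):
        assert signed_cbrt(x) == pytest.approx(expected)

    @given(
        st.floats(-2, 2, allow_nan=False),
        st.floats(-2, 2, allow_nan=False),
        st.floats(-2, 2, allow_nan=False),
    )
    def test_multiplicative(self, a, b, c):
        assert signed_cbrt(a * b * c) == pytest.approx(
            signed_cbrt(a) * signed_cbrt(b) * signed_cbrt(c), abs=1e-12
        )

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            signed_cbrt(bad)


class TestConnectivityMatrixValidation:
    def test_too_small(self):
        with pytest.raises(ValueError, match="3 regions"):
            ConnectivityMatrix(weights=np.zeros((2, 2)))

    def test_not_square(self):
        with pytest.raises(ValueError, match="square"):
            ConnectivityMatrix(weights=np.zeros((3, 4)))

    def test_nan_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ConnectivityMatrix(weights=w)

    def test_asymmetry_beyond_tolerance_is_error(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.5
        w[1, 0] = 0.5 + 1e-6
        with pytest.raises(ValueError, match="asymmetry"):
            ConnectivityMatrix(weights=w)

    def test_small_asymmetry_averaged(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.5
        w[1, 0] = 0.5 + 1e-9
        m = ConnectivityMatrix(weights=w)
        assert m.weights[0, 1] == m.weights[1, 0] == pytest.approx(0.5 + 5e-10)

    def test_diagonal_zeroed(self):
        w = np.eye(4)  # correlation matrices arrive with unit diagonal
        m = ConnectivityMatrix(weights=w)
        assert np.all(np.diag(m.weights) == 0)

    def test_out_of_bounds_rejected_and_override(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.5
        with pytest.raises(ValueError, match="exceed"):
            ConnectivityMatrix(weights=w)
        m = ConnectivityMatrix(weights=w, allow_unbounded=True)
        assert m.weights[0, 1] == 1.5


class TestNetworkEnergy:
    def test_all_positive_triangle(self):
        assert network_energy(complete_matrix(3, 1.0)) == pytest.approx(-1.0)

    def test_single_imbalanced_triangle(self):
        w = np.array([[0, 1, 1], [1, 0, -1], [1, -1, 0]], dtype=float)
        assert network_energy(ConnectivityMatrix(weights=w)) == pytest.approx(1.0)

    def test_half_weights(self):
        assert network_energy(complete_matrix(3, 0.5)) == pytest.approx(-0.5)

    def test_four_node_all_positive(self):
        assert network_energy(complete_matrix(4, 1.0)) == pytest.approx(-1.0)

    def test_all_negative_five_nodes(self):
        assert brute_force_energy(complete_matrix(5, -1.0)) == pytest.approx(1.0)

    def test_matches_brute_force_n20(self):
        m = random_matrix(20, seed=7)
        assert network_energy(m) == pytest.approx(brute_force_energy(m), abs=1e-10)

    def test_oracle_equivalence_sweep(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(3, 41))
            m = random_matrix(n, seed=int(rng.integers(0, 2**31)))
            assert network_energy(m) == pytest.approx(
                brute_force_energy(m), abs=1e-10
            )

    def test_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(3, 41))
            u = network_energy(random_matrix(n, seed=int(rng.integers(0, 2**31))))
            assert -1.0 <= u <= 1.0

    def test_scale_covariance(self):
        m = random_matrix(12, seed=3)
        for c in (0.1, 0.5, 0.9):
            scaled = ConnectivityMatrix(weights=c * m.weights)
            assert network_energy(scaled) == pytest.approx(
                c * network_energy(m), abs=1e-12
            )

    def test_sign_flip_negates(self):
        m = random_matrix(15, seed=9)
        flipped = ConnectivityMatrix(weights=-m.weights)
        assert network_energy(flipped) == pytest.approx(-network_energy(m), abs=1e-12)

    def test_permutation_invariance(self):
        m = random_matrix(14, seed=11)
        rng = np.random.default_rng(0)
        perm = rng.permutation(14)
        relabeled = ConnectivityMatrix(weights=m.weights[np.ix_(perm, perm)])
        assert network_energy(relabeled) == pytest.approx(
            network_energy(m), abs=1e-12
        )

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(3, 12))
    def test_bounded_and_oracle_property(self, seed, n):
        m = random_matrix(n, seed=seed)
        u = network_energy(m)
        assert -1.0 <= u <= 1.0
        assert u == pytest.approx(brute_force_energy(m), abs=1e-10)


class TestTriangleCensus:
    def test_all_positive_four_nodes(self):
        c = triangle_census(complete_matrix(4, 1.0))
        assert (c.n_balanced, c.n_imbalanced) == (4, 0)

    def test_single_imbalanced(self):
        w = np.array([[0, 1, 1], [1, 0, -1], [1, -1, 0]], dtype=float)
        c = triangle_census(ConnectivityMatrix(weights=w))
        assert (c.n_balanced, c.n_imbalanced) == (0, 1)

    def test_zero_edge_triangle_counted_as_neither(self):
        w = np.array([[0, 1, 0], [1, 0, -1], [0, -1, 0]], dtype=float)
        c = triangle_census(ConnectivityMatrix(weights=w))
        assert (c.n_balanced, c.n_imbalanced) == (0, 0)

    def test_matches_enumeration_oracle(self):
        m = random_matrix(15, seed=21)
        w = m.weights
        n_bal = n_imb = 0
        for i, j, k in itertools.combinations(range(15), 3):
            p = w[i, j] * w[i, k] * w[j, k]
            if p > 0:
                n_bal += 1
            elif p < 0:
                n_imb += 1
        c = triangle_census(m)
        assert (c.n_balanced, c.n_imbalanced) == (n_bal, n_imb)
        assert c.n_balanced + c.n_imbalanced <= comb(15, 3)

    def test_census_energy_consistency(self):
        for seed in (1, 2, 3):
            m = random_matrix(18, seed=seed)
            assert triangle_census(m).energy() == pytest.approx(
                network_energy(m), abs=1e-10
            )


class TestSubnetworkEnergy:
    def test_whole_scope_is_identity(self):
        m = random_matrix(12, seed=4)
        p = Parcellation(labels={r: "A" for r in m.region_ids})
        assert subnetwork_energy(m, p, WHOLE_BRAIN) == pytest.approx(
            network_energy(m)
        )

    def test_unit_clique_subnetwork(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        np.fill_diagonal(w, 0.0)
        m = ConnectivityMatrix(weights=w)
        labels = {r: ("A" if i < 3 else "B") for i, r in enumerate(m.region_ids)}
        assert subnetwork_energy(m, Parcellation(labels=labels), "A") == pytest.approx(
            -1.0
        )

    def test_matches_manual_slice_oracle(self):
        m = random_matrix(30, seed=17)
        p = make_parcellation(30, 3, seed=0)
        for scope in p.networks:
            members = [r for r in p.members(scope)]
            idx = [m.region_ids.index(r) for r in members]
            sliced = ConnectivityMatrix(weights=m.weights[np.ix_(idx, idx)])
            assert subnetwork_energy(m, p, scope) == pytest.approx(
                brute_force_energy(sliced), abs=1e-10
            )

    def test_small_scope_error_names_scope(self):
        m = random_matrix(6, seed=1)
        labels = {r: ("TINY" if i < 2 else "BIG") for i, r in enumerate(m.region_ids)}
        with pytest.raises(ValueError, match="TINY"):
            subnetwork_energy(m, Parcellation(labels=labels), "TINY")


class TestEnergyDelta:
    def test_basic(self):
        assert energy_delta(-0.2, -0.4) == pytest.approx(0.2)

    def test_identity(self):
        assert energy_delta(-0.3, -0.3) == 0.0

    def test_antisymmetry(self):
        assert energy_delta(0.1, -0.2) == -energy_delta(-0.2, 0.1)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            energy_delta(np.nan, 0.0)


class TestEnergyTable:
    @staticmethod
    def _cohort(n_subjects, n_regions=30, seed=0):
        p = make_parcellation(n_regions, 10, seed=0)
        mats = []
        for s in range(n_subjects):
            for cond in CONDITIONS:
                mats.append(
                    random_matrix(
                        n_regions, seed=seed + 100 * s + CONDITIONS.index(cond),
                        subject_id=f"sub{s}", condition=cond,
                    )
                )
        return mats, p

    def test_record_count(self):
        mats, p = self._cohort(2)
        df = energy_table(mats, p)
        assert len(df) == 2 * 7 * 11  # subjects x conditions x (whole + 10 networks)

    def test_identical_matrices_zero_delta(self):
        p = make_parcellation(30, 10, seed=0)
        base = random_matrix(30, seed=5)
        mats = [
            ConnectivityMatrix(
                weights=base.weights, subject_id="s0", condition=cond
            )
            for cond in CONDITIONS
        ]
        df = energy_table(mats, p)
        deltas = df.loc[df["condition"] != "rest", "dU"]
        assert np.allclose(deltas, 0.0)

    def test_missing_rest_error_lists_subjects(self):
        mats, p = self._cohort(2)
        mats = [m for m in mats if not (m.subject_id == "sub1" and m.condition == "rest")]
        with pytest.raises(ValueError, match="sub1"):
            energy_table(mats, p)
        # without delta it still succeeds
        df = energy_table(mats, p, include_delta=False)
        assert "dU" not in df.columns

    def test_task_conflict_raises_median_delta(self, small_cohort):
        df = energy_table(
            small_cohort.all_matrices(), small_cohort.parcellation,
            scopes=[WHOLE_BRAIN],
        )
        med = df[df["condition"] != "rest"].groupby("condition")["dU"].median()
        assert (med > 0).all()
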