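import math

import numpy as np
import pytest

import hpmatrix as hx
from hpmatrix import core
from conftest import random_state

# golden values computed by direct scalar evaluation of the model formulas
ESCAPE_UNIFORM_STATE = 0.8522781975860239     # n=(10,)*5, p=(0,0,2), defaults
ADULT_SURVIVAL_AT_ZERO = 0.932 / 14.5         # 0.0642758...
RECRUITS_EXAMPLE = 5 * 1.471 * 10 / 15        # 4.90333...


class TestHostMatrix:
    def test_published_entries(self, host_params):
        A = core.build_host_matrix(host_params)
        assert A[1, 0] == 0.484
        assert A[0, 4] == 2.56
        assert A[4, 4] == 0.86
        assert A[2, 0] == 0.016

    def test_first_column_sums_to_one(self, host_params):
        A = core.build_host_matrix(host_params)
        assert A[:, 0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_immortal_static_stages_give_identity(self):
        hp = hx.HostParams(P=(1, 1, 1, 1, 1), G=(0, 0, 0, 0), G_skip13=0.0,
                           F5=0.0)
        assert np.array_equal(core.build_host_matrix(hp), np.eye(5))

    def test_sparsity(self, host_params):
        A = core.build_host_matrix(host_params)
        mask = np.zeros((5, 5), dtype=bool)
        for i, j in core.HOST_SPARSITY:
            mask[i, j] = True
        assert (A[~mask] == 0).all()


class TestEscape:
    def test_no_parasitoids_no_attack(self, para_params):
        state = hx.PopulationState(np.full(5, 7.0), np.zeros(3))
        for mode in ("literal", "scaled_exponent"):
            assert np.array_equal(
                core.escape_probabilities(state, para_params, mode), np.ones(5)
            )

    def test_unattacked_stage_escapes_in_scaled_mode(self, para_params):
        pp = hx.ParasitoidParams(attack_fractions=(0.0, 0.25, 0.25, 0.25, 0.25))
        state = hx.PopulationState(np.full(5, 10.0), np.array([0, 0, 3.0]))
        g = core.escape_probabilities(state, pp, "scaled_exponent")
        assert g[0] == 1.0
        assert (g[1:] < 1.0).all()

    def test_golden_value_uniform_state(self, para_params):
        state = hx.PopulationState(np.full(5, 10.0), np.array([0, 0, 2.0]))
        for mode in ("literal", "scaled_exponent"):  # p1=0 so modes coincide
            g = core.escape_probabilities(state, para_params, mode)
            assert g == pytest.approx(np.full(5, ESCAPE_UNIFORM_STATE), abs=1e-12)

    def test_empty_system_returns_ones(self, para_params):
        state = hx.PopulationState(np.zeros(5), np.zeros(3))
        assert np.array_equal(
            core.escape_probabilities(state, para_params), np.ones(5)
        )

    def test_unknown_mode_rejected(self, para_params):
        state = hx.PopulationState(np.ones(5), np.zeros(3))
        with pytest.raises(ValueError, match="escape mode"):
            core.escape_probabilities(state, para_params, "outside")


class TestEscapeMatrix:
    def test_structure_from_graded_vector(self):
        H = core.build_escape_matrix(np.array([0.9, 0.8, 0.7, 0.6, 0.5]))
        assert H[1, 0] == 0.9
        assert H[4, 3] == 0.6
        assert H[0, 4] == 0.5
        assert H[2, 0] == 0.9  # skip entry carries the origin-stage escape

    def test_all_ones_is_hadamard_neutral(self, host_params):
        A = core.build_host_matrix(host_params)
        H = core.build_escape_matrix(np.ones(5))
        assert np.array_equal(H * A, A)

    def test_zero_vector_gives_zero_matrix(self):
        assert not core.build_escape_matrix(np.zeros(5)).any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="escape"):
            core.build_escape_matrix(np.array([1.1, 0.5, 0.5, 0.5, 0.5]))


class TestAdultSurvival:
    def test_asymptote_is_maximum_daily_survival(self, para_params):
        assert core.adult_parasitoid_survival(1e6, para_params) == pytest.approx(
            0.932, abs=1e-12
        )

    def test_starvation_at_zero_hosts(self, para_params):
        assert core.adult_parasitoid_survival(0.0, para_params) == pytest.approx(
            ADULT_SURVIVAL_AT_ZERO, abs=1e-12
        )

    def test_density_independent_when_theta2_zero(self, para_params):
        import dataclasses
        pp = dataclasses.replace(para_params, theta2=0.0)
        for N in (0.0, 10.0, 1e4):
            assert core.adult_parasitoid_survival(N, pp) == 0.932

    def test_monotone_increasing_in_host_density(self, para_params):
        N = np.linspace(0, 50, 200)
        s = np.array([core.adult_parasitoid_survival(x, para_params) for x in N])
        assert (np.diff(s) >= 0).all()

    def test_inverse_lifespan_mode_bounded(self, para_params):
        for N in (0.0, 5.0, 100.0):
            s = core.adult_parasitoid_survival(N, para_params, "inverse_lifespan")
            assert 0.0 <= s <= 1.0


class TestParasitoidMatrix:
    def test_no_adults_no_fertility(self, para_params):
        state = hx.PopulationState(np.full(5, 10.0), np.array([1.0, 1.0, 0.0]))
        W = core.build_parasitoid_matrix(state, para_params, np.full(5, 0.5))
        assert W[0, 2] == 0.0

    def test_full_escape_no_fertility(self, para_params):
        state = hx.PopulationState(np.full(5, 10.0), np.array([0, 0, 2.0]))
        W = core.build_parasitoid_matrix(state, para_params, np.ones(5))
        assert W[0, 2] == 0.0

    def test_attack_conservation(self, para_params):
        state = hx.PopulationState(np.full(5, 10.0), np.array([0, 0, 2.0]))
        g = core.escape_probabilities(state, para_params)
        W = core.build_parasitoid_matrix(state, para_params, g)
        eggs = W[0, 2] * state.p[2]
        attacked = ((1.0 - g) * state.n).sum()
        assert eggs == pytest.approx(attacked, abs=1e-9)

    def test_survival_override(self, para_params):
        state = hx.PopulationState(np.full(5, 10.0), np.zeros(3))
        W = core.build_parasitoid_matrix(
            state, para_params, np.ones(5), adult_survival_override=0.75
        )
        assert W[2, 2] == 0.75


class TestRecruits:
    def test_no_parasitized_hosts(self, host_params):
        state = hx.PopulationState(np.full(5, 10.0), np.zeros(3))
        assert core.post_parasitism_recruits(state, host_params) == 0.0

    def test_adult_only_example(self, host_params):
        state = hx.PopulationState(
            np.array([0, 0, 0, 0, 10.0]), np.array([5.0, 0, 0])
        )
        assert core.post_parasitism_recruits(state, host_params) == pytest.approx(
            RECRUITS_EXAMPLE, abs=1e-12
        )

    def test_sterile_parasitized_hosts(self):
        hp = hx.HostParams(J=(0.0,) * 5)
        state = hx.PopulationState(np.full(5, 10.0), np.array([5.0, 0, 0]))
        assert core.post_parasitism_recruits(state, hp) == 0.0


def _ones_structural_host():
    C = np.zeros((5, 5))
    for i, j in core.HOST_SPARSITY:
        C[i, j] = 1.0
    return C


def _ones_structural_para():
    C = np.zeros((3, 3))
    for i, j in core.PARASITOID_SPARSITY:
        C[i, j] = 1.0
    return C


class TestHostStep:
    def test_zero_net_growth_at_carrying_capacity(self, host_params):
        n = np.array([0, 0, 0, 0, host_params.K])
        state = hx.PopulationState(n, np.zeros(3))
        A = core.build_host_matrix(host_params)
        out = core.host_step(state, A, core.build_escape_matrix(np.ones(5)),
                             _ones_structural_host(), host_params)
        assert out == pytest.approx(n)

    def test_single_adult_column_projection(self, host_params):
        # 100 adults, no parasitism, no scaling: newborn cohort is
        # phi * F5 * n5 with phi = 5900/6000
        state = hx.PopulationState(np.array([0, 0, 0, 0, 100.0]), np.zeros(3))
        A = core.build_host_matrix(host_params)
        out = core.host_step(state, A, core.build_escape_matrix(np.ones(5)),
                             _ones_structural_host(), host_params)
        assert out[0] == pytest.approx(100 * (5900 / 6000) * 2.56, abs=1e-9)

    def test_recruits_added_to_first_stadium(self, host_params):
        state = hx.PopulationState(np.array([0, 0, 0, 0, 100.0]), np.zeros(3))
        A = core.build_host_matrix(host_params)
        H = core.build_escape_matrix(np.ones(5))
        C = _ones_structural_host()
        base = core.host_step(state, A, H, C, host_params)
        plus = core.host_step(state, A, H, C, host_params, recruits=3.5)
        assert plus[0] - base[0] == pytest.approx(3.5)
        assert np.array_equal(plus[1:], base[1:])

    def test_shape_mismatch_rejected(self, host_params):
        state = hx.PopulationState(np.ones(5), np.zeros(3))
        with pytest.raises(ValueError, match="5x5"):
            core.host_step(state, np.eye(4), np.eye(5), np.eye(5), host_params)


class TestParasitoidStep:
    def test_empty_population_stays_empty(self, host_params, para_params):
        state = hx.PopulationState(np.full(5, 10.0), np.zeros(3))
        W = core.build_parasitoid_matrix(state, para_params, np.ones(5))
        out = core.parasitoid_step(state, W, _ones_structural_para(), host_params)
        assert np.array_equal(out, np.zeros(3))

    def test_collapses_to_full_projection_when_hosts_scarce(
        self, host_params, para_params
    ):
        # N << K so phi ~ 1: the decomposition equals V @ p up to the
        # O(N/K) throttle on the p1 rows
        state = hx.PopulationState(np.zeros(5), np.array([2.0, 3.0, 1.0]))
        g = np.ones(5)
        W = core.build_parasitoid_matrix(state, para_params, g)
        V = W * _ones_structural_para()
        out = core.parasitoid_step(state, W, _ones_structural_para(), host_params)
        assert out == pytest.approx(V @ state.p, rel=1e-2)

    def test_saturation_freezes_host_resident_stage(self, host_params, para_params):
        # N = K exactly: phi = 0, so eggs/larvae neither die nor mature and
        # no eggs enter; mummies and adults evolve freely
        n = np.array([host_params.K - 10.0, 0, 0, 0, 0])
        state = hx.PopulationState(n, np.array([10.0, 4.0, 2.0]))
        assert state.N == host_params.K
        g = core.escape_probabilities(state, para_params)
        W = core.build_parasitoid_matrix(state, para_params, g)
        V = W * _ones_structural_para()
        out = core.parasitoid_step(state, W, _ones_structural_para(), host_params)
        assert out[0] == pytest.approx(10.0)
        assert out[1] == pytest.approx(V[1, 1] * 4.0)
        assert out[2] == pytest.approx(V[2, 1] * 4.0 + V[2, 2] * 2.0)


# ---------------------------------------------------------------------------
# brute-force oracle: an independent scalar re-derivation of the one-day
# update, built entry by entry from the model's defining formulas


def _oracle_step(state, params, mode="literal"):
    hp, pp = params.host, params.parasitoid
    n, (p1, p2, p3) = state.n, state.p
    N = sum(n) + p1
    P, G = hp.P, hp.G
    # escape probabilities
    if N == 0:
        g = [1.0] * 5
    else:
        g = []
        avail = sum(n) / N
        for i in range(5):
            a = pp.attack_fractions[i]
            expo = -a * pp.alpha * p3 * (1 - pp.prop_male) / (
                1 + a * pp.alpha * pp.handling_time * N
            )
            g.append(math.exp(expo) * avail if mode == "literal"
                     else math.exp(expo * avail))
    # dense host matrix M = H o A (no thermal scaling in the oracle)
    M = [[0.0] * 5 for _ in range(5)]
    for i in range(5):
        M[i][i] = P[i] * g[i]
    for i in range(4):
        M[i + 1][i] = G[i] * g[i]
    M[2][0] = hp.G_skip13 * g[0]
    M[0][4] = hp.F5 * g[4]
    phi = (hp.K - N) / hp.K
    d = [sum(M[i][j] * n[j] for j in range(5)) - n[i] for i in range(5)]
    if phi >= 0:
        n_next = [n[i] + phi * d[i] for i in range(5)]
    else:
        n_next = [n[i] + (phi * d[i] if d[i] > 0 else d[i]) for i in range(5)]
    if N > 0 and p1 > 0:
        n_next[0] += sum(p1 * hp.J[i] * n[i] / N for i in range(5))
    n_next = [max(x, 0.0) for x in n_next]
    # parasitoid
    S3 = pp.S_adult_max / (1 + pp.theta2 * math.exp(pp.theta3 * N))
    eggs = sum((1 - g[i]) * n[i] for i in range(5)) if p3 > 0 else 0.0
    phi_pos = max(phi, 0.0)
    dec = phi if phi >= 0 else 1.0
    p_next = [
        max(p1 + dec * (pp.P[0] - 1) * p1 + phi_pos * eggs, 0.0),
        max(phi_pos * pp.G[0] * p1 + pp.P[1] * p2, 0.0),
        max(pp.G[1] * p2 + S3 * p3, 0.0),
    ]
    return np.array(n_next), np.array(p_next)


@pytest.mark.parametrize("mode", ["literal", "scaled_exponent"])
def test_steps_agree_with_scalar_oracle(params, rng, mode):
    """1000 random states: the structured implementation reproduces an
    independently coded dense scalar evaluation of the update to 1e-10."""
    hp, pp = params.host, params.parasitoid
    A = core.build_host_matrix(hp)
    C5, C3 = _ones_structural_host(), _ones_structural_para()
    for k in range(1000):
        scale = 10 ** rng.uniform(-1, 4)  # spans sparse to above-K densities
        state = random_state(rng, scale=scale)
        g = core.escape_probabilities(state, pp, mode)
        H = core.build_escape_matrix(g)
        W = core.build_parasitoid_matrix(state, pp, g)
        rec = core.post_parasitism_recruits(state, hp)
        n_impl = core.host_step(state, A, H, C5, hp, rec)
        p_impl = core.parasitoid_step(state, W, C3, hp)
        n_ref, p_ref = _oracle_step(state, params, mode)
        np.testing.assert_allclose(n_impl, n_ref, rtol=0, atol=1e-10 * max(scale, 1))
        np.testing.assert_allclose(p_impl, p_ref, rtol=0, atol=1e-10 * max(scale, 1))


def test_non_negativity_after_steps(params, rng):
    hp, pp = params.host, params.parasitoid
    A = core.build_host_matrix(hp)
    C5, C3 = _ones_structural_host(), _ones_structural_para()
    for _ in range(200):
        state = random_state(rng, scale=10 ** rng.uniform(0, 4))
        g = core.escape_probabilities(state, pp)
        H = core.build_escape_matrix(g)
        W = core.build_parasitoid_matrix(state, pp, g)
        n2 = core.host_step(state, A, H, C5, hp,
                            core.post_parasitism_recruits(state, hp))
        p2 = core.parasitoid_step(state, W, C3, hp)
        assert (n2 >= 0).all() and (p2 >= 0).all()
        assert np.isfinite(n2).all() and np.isfinite(p2).all()
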