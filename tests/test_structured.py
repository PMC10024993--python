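import numpy as np
import pytest

from invaderkit import fixtures as fx
from invaderkit import structured as st
from invaderkit.games import PayoffMatrix


def island_spec(n, m, delta, y, xhat, W=None):
    if W is None:
        W = PayoffMatrix(w11=2, w10=-1, w01=3, w00=0)  # additive PD
    kernel = st.IslandKernel(n=n, m=m, W=W, delta=delta)
    return st.GroupModelSpec(kernel=kernel, y=[y], xhat=[xhat])


def simulate_island_lineage(spec, generations, n_rep, seed, collect_r=False):
    """Stochastic oracle simulating the island life cycle group by group.

    Each replicate starts from one mutant group in state k=1; every
    generation each mutant group resamples its own state binomially from
    the philopatric mutant share and emigrant mutants found new singleton
    groups (Poisson).  Returns the replicate totals of mutants, and with
    ``collect_r`` the sums needed for the groupmate-relatedness ratio
    estimator.
    """
    rng = np.random.default_rng(seed)
    kernel = spec.kernel
    n = kernel.n
    # precompute per-state philopatric probability and emigrant mean
    phi = np.zeros(n + 1)
    emg = np.zeros(n + 1)
    for k in range(1, n + 1):
        ph, em = kernel.fitness_parts([k], spec.y, spec.xhat)
        phi[k] = k * ph / n
        emg[k] = k * em
    totals = np.zeros(n_rep)
    rx = np.zeros(n_rep)  # sum over mutants of mutant groupmate fraction
    ry = np.zeros(n_rep)  # number of mutants with any groupmates
    for rep in range(n_rep):
        groups = [1]
        for _ in range(generations):
            nxt = []
            for k in groups:
                k2 = rng.binomial(n, phi[k])
                if k2 > 0:
                    nxt.append(k2)
                nxt.extend([1] * rng.poisson(emg[k]))
            groups = nxt
            if not groups:
                break
        totals[rep] = sum(groups)
        if collect_r and groups and n > 1:
            for k in groups:
                rx[rep] += k * (k - 1) / (n - 1)
                ry[rep] += k
    if collect_r:
        return totals, rx, ry
    return totals


class TestEnumerateStates:
    def test_single_class(self):
        assert st.enumerate_group_states([2]) == [(1,), (2,)]
        assert len(st.enumerate_group_states([3])) == 3

    def test_two_classes(self):
        assert st.enumerate_group_states([1, 1]) == [(0, 1), (1, 0), (1, 1)]

    def test_cap(self):
        with pytest.raises(ValueError, match="coarsen"):
            st.enumerate_group_states([200, 200])


class TestProjection:
    def test_neutral_offspring_accounting(self):
        """At neutrality every mutant exactly replaces itself on average:
        the k-weighted column sums of A equal k."""
        spec = island_spec(n=2, m=0.5, delta=0.0, y=1.0, xhat=0.0)
        proj = st.build_projection(spec)
        K = np.array(proj.states, float).ravel()
        for j, k in enumerate(K):
            assert (K * proj.A[:, j]).sum() == pytest.approx(k, abs=1e-12)

    def test_panmictic_single_slot(self):
        """m=1, n=1: the projection collapses to the scalar relative
        fecundity."""
        W = PayoffMatrix(2, -1, 3, 0)
        spec = island_spec(n=1, m=1.0, delta=0.02, y=1.0, xhat=0.0, W=W)
        proj = st.build_projection(spec)
        assert proj.A.shape == (1, 1)
        f_mut = 1 + 0.02 * (-1)  # w(y=1 against resident xhat=0) = w10
        f_res = 1 + 0.02 * 0  # w00
        assert proj.A[0, 0] == pytest.approx(f_mut / f_res)
        lam, _ = st.leading_eigenpair(proj.A)
        assert lam == pytest.approx(f_mut / f_res)

    @pytest.mark.parametrize("seed", range(20))
    def test_offspring_accounting_random_linear_kernels(self, seed):
        """Total class-s' offspring of the mutants in a group equal the
        k'-weighted column sums of the projection matrix (exact, both for
        one and two classes)."""
        rng = np.random.default_rng(seed)
        n_s = [2] if seed % 2 else [2, 1]
        kernel = fx.random_group_kernel(n_s, rng)
        spec = st.GroupModelSpec(kernel=kernel, y=kernel.y, xhat=kernel.xhat)
        proj = st.build_projection(spec)
        K = np.array(proj.states, float)
        for j, k in enumerate(proj.states):
            lhs = K.T @ proj.A[:, j]  # per class s'
            omega = st._omega_matrix(spec, k)
            rhs = omega @ np.asarray(k, float)
            assert np.allclose(lhs, rhs, atol=1e-10), (k, lhs, rhs)


class TestEigenAndLineage:
    def test_leading_eigenpair_simple(self):
        lam, u = st.leading_eigenpair(np.array([[2.0, 0.0], [0.0, 1.0]]))
        assert lam == pytest.approx(2.0)
        assert np.allclose(u, [1.0, 0.0])

    def test_leading_eigenpair_matches_power_iteration(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0, 1, size=(10, 10))
        lam, u = st.leading_eigenpair(A)
        v = np.full(10, 0.1)
        for _ in range(10_000):
            w = A @ v
            v = w / w.sum()
        assert lam == pytest.approx((A @ v).sum(), abs=1e-10)
        assert np.allclose(u, v, atol=1e-8)

    def test_neutral_lambda_one(self):
        for n, m in [(1, 1.0), (2, 0.5), (3, 0.2)]:
            spec = island_spec(n=n, m=m, delta=0.0, y=0.8, xhat=0.1)
            lam, _ = st.leading_eigenpair(st.build_projection(spec).A)
            assert lam == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_lineage_fitness_equals_eigenvalue(self, seed):
        """The stationary-context average of individual fitness reproduces
        the Perron eigenvalue, for island and random linear kernels."""
        rng = np.random.default_rng(100 + seed)
        if seed % 2:
            kernel = fx.random_group_kernel([2] if seed % 4 == 1 else [2, 1], rng)
            spec = st.GroupModelSpec(kernel=kernel, y=kernel.y, xhat=kernel.xhat)
        else:
            spec = island_spec(
                n=int(rng.integers(2, 4)), m=float(rng.uniform(0.2, 1.0)),
                delta=0.01, y=1.0, xhat=0.0,
            )
        proj = st.build_projection(spec)
        lam, u = st.leading_eigenpair(proj.A)
        assert st.lineage_fitness(spec, u, proj.states) == pytest.approx(lam, abs=1e-9)

    def test_growth_matches_stochastic_branching(self):
        """Deterministic lambda agrees with mean lineage growth in a
        stochastic simulation of the same life cycle (3 SE)."""
        for i, (n, m, delta) in enumerate([(2, 0.5, 0.05), (3, 0.3, 0.03), (2, 1.0, 0.04)]):
            spec = island_spec(n=n, m=m, delta=delta, y=1.0, xhat=0.0)
            lam, _ = st.leading_eigenpair(st.build_projection(spec).A)
            G = 12
            totals = simulate_island_lineage(spec, G, 40_000, seed=300 + i)
            # E[N_G] = sum_k' K A^G e_start exactly; compare to simulation
            proj = st.build_projection(spec)
            K = np.array(proj.states, float).ravel()
            e0 = np.zeros(len(K))
            e0[proj.states.index((1,))] = 1.0
            expected = float(K @ np.linalg.matrix_power(proj.A, G) @ e0)
            se = totals.std(ddof=1) / np.sqrt(len(totals))
            assert abs(totals.mean() - expected) < 3 * se, (expected, totals.mean(), se)


class TestSummaries:
    def test_single_slot_relatedness_undefined(self):
        spec = island_spec(n=1, m=1.0, delta=0.0, y=0.5, xhat=0.5)
        res = st.invasion_analysis(spec)
        assert np.isnan(res.r_sigma_s[0, 0])

    def test_relatedness_approaches_one_without_migration(self):
        prev = 0.0
        for m in [0.5, 0.2, 0.05, 0.01, 0.002]:
            spec = island_spec(n=2, m=m, delta=0.0, y=0.5, xhat=0.5)
            r = st.invasion_analysis(spec).r_sigma_s[0, 0]
            assert r > prev
            prev = r
        assert prev > 0.95

    def test_relatedness_matches_identity_by_descent_simulation(self):
        """Neutral lineage relatedness equals the mutant-groupmate fraction
        in a stochastic simulation of the same life cycle (3 SE)."""
        spec = island_spec(n=2, m=0.5, delta=0.0, y=0.5, xhat=0.5)
        r_det = st.invasion_analysis(spec).r_sigma_s[0, 0]
        totals, rx, ry = simulate_island_lineage(
            spec, generations=30, n_rep=100_000, seed=42, collect_r=True
        )
        mask = ry > 0
        r_hat = rx[mask].sum() / ry[mask].sum()
        # delta-method standard error of the ratio estimator
        n_surv = int(mask.sum())
        resid = rx[mask] - r_hat * ry[mask]
        se = np.sqrt((resid**2).sum()) / ry[mask].sum()
        assert abs(r_hat - r_det) < 3 * se, (r_det, r_hat, se)

    def test_reproductive_values_normalised(self):
        rng = np.random.default_rng(5)
        kernel = fx.random_group_kernel([2, 1], rng)
        spec = st.GroupModelSpec(kernel=kernel, y=kernel.y, xhat=kernel.xhat)
        res = st.invasion_analysis(spec)
        shares = np.array([2, 1]) / 3.0
        assert res.v_s @ shares == pytest.approx(1.0)
        assert res.q_ks.sum() == pytest.approx(1.0)
        assert res.q_s.sum() == pytest.approx(1.0)


class TestPartitions:
    def test_zero_deviation_zero_coefficients(self):
        spec = island_spec(n=3, m=0.5, delta=0.05, y=0.4, xhat=0.4)
        part = st.decompose_costs_benefits(spec)
        assert np.allclose(part.cost, 0.0)
        assert np.allclose(part.benefit_total, 0.0)

    def test_pd_signs(self):
        spec = island_spec(n=3, m=0.5, delta=0.02, y=1.0, xhat=0.0)
        part = st.decompose_costs_benefits(spec)
        assert part.cost[0, 0] > 0  # cooperating is individually costly
        assert part.benefit_total[0, 0, 0] > 0  # and helps groupmates

    def test_asocial_kernel_no_benefits(self):
        W = PayoffMatrix(1, 1, 2, 2)  # pay-off independent of partner
        spec = island_spec(n=3, m=1.0, delta=0.02, y=1.0, xhat=0.0, W=W)
        part = st.decompose_costs_benefits(spec)
        assert np.allclose(part.benefit_total, 0.0, atol=1e-9)

    @pytest.mark.parametrize("n,m", [(2, 0.2), (2, 0.5), (2, 1.0), (3, 0.2), (3, 0.5), (3, 1.0)])
    def test_partitions_agree_and_converge_quadratically(self, n, m):
        """Inclusive-fitness and group-selection partitions coincide exactly
        and approach the eigenvalue at rate O(delta^2) for an additive
        game."""
        gaps = []
        for delta in [0.02, 0.01, 0.005]:
            spec = island_spec(n=n, m=m, delta=delta, y=1.0, xhat=0.0)
            res = st.invasion_analysis(spec)
            part = st.decompose_costs_benefits(spec)
            summ = (res.q_ks, res.q_s, res.v_s, res.r_sigma_s)
            lam_if = st.inclusive_fitness(spec, summ, part)
            _, _, lam_gs = st.group_partition(spec, summ, part)
            assert lam_if == pytest.approx(lam_gs, abs=1e-12)
            gaps.append(abs(lam_if - res.lam))
        if gaps[0] > 1e-9:  # panmictic cases are exact; ratios are noise
            assert gaps[0] / gaps[1] > 3.0
            assert gaps[1] / gaps[2] > 3.0

    def test_altruism_sign_structure(self):
        """A costly helping trait is favoured between groups and disfavoured
        within them."""
        spec = island_spec(n=3, m=0.2, delta=0.01, y=1.0, xhat=0.0)
        res = st.invasion_analysis(spec)
        part = st.decompose_costs_benefits(spec)
        omega_G, omega_dG, _ = st.group_partition(
            spec, (res.q_ks, res.q_s, res.v_s, res.r_sigma_s), part
        )
        assert omega_G[0, 0] > 0
        assert omega_dG[0, 0] < 0

    def test_clonal_group_limit_no_within_selection(self):
        """With relatedness pinned at 1 the within-group term vanishes."""
        spec = island_spec(n=3, m=0.2, delta=0.01, y=1.0, xhat=0.0)
        part = st.decompose_costs_benefits(spec)
        q_ks = np.array([[0.0], [0.0], [1.0]])
        summ = (q_ks, np.array([1.0]), np.array([1.0]), np.array([[1.0]]))
        _, omega_dG, _ = st.group_partition(spec, summ, part)
        assert np.allclose(omega_dG, 0.0, atol=1e-14)

    def test_cost_only_kernel_decreasing(self):
        W = PayoffMatrix(0, 0, 1, 1)  # own cooperation only hurts
        spec = island_spec(n=2, m=1.0, delta=0.02, y=1.0, xhat=0.0, W=W)
        res = st.invasion_analysis(spec)
        part = st.decompose_costs_benefits(spec)
        summ = (res.q_ks, res.q_s, res.v_s, res.r_sigma_s)
        lam_if = st.inclusive_fitness(spec, summ, part)
        assert np.allclose(part.benefit_total, 0.0, atol=1e-9)
        assert lam_if == pytest.approx(1.0 - float(part.cost[0, 0]))
        assert lam_if < 1.0


class TestSexRatio:
    def test_neutral_self(self):
        for x in [0.2, 0.5, 0.8]:
            assert st.sex_ratio_invasion(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_fisherian_ratio_flat(self):
        for y in np.linspace(0.05, 0.95, 19):
            assert st.sex_ratio_invasion(y, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_mutant_toward_half_invades(self):
        assert st.sex_ratio_invasion(0.5, 0.3) > 1.0
        assert st.sex_ratio_invasion(0.5, 0.7) > 1.0
        assert st.sex_ratio_invasion(0.4, 0.3) > 1.0

    def test_half_is_unique_uninvadable(self):
        residents = np.round(np.arange(0.05, 0.951, 0.05), 10)
        mutants = residents
        uninvadable = [
            x
            for x in residents
            if all(st.sex_ratio_invasion(y, x) <= 1.0 + 1e-12 for y in mutants)
        ]
        assert uninvadable == [0.5]

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            st.sex_ratio_invasion(0.5, 0.0)
        with pytest.raises(ValueError):
            st.sex_ratio_invasion(1.0, 0.5)
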