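import numpy as np
import pytest

from matphase.completion import (
    CompletionError,
    NuclearNormCompleter,
    OptSpaceCompleter,
    SVTCompleter,
    SVTParams,
    FactorTriple,
    complete_optspace,
    optspace_clean,
    project_rank_r,
    shrink_singular_values,
    trim,
    as_read_matrix,
)
from matphase.io import Fragment, build_read_matrix


def _rank2_sign_matrix(rng, n=12, l=8):
    hp = rng.choice([-1.0, 1.0], size=l)
    hm = np.where(rng.random(l) < 0.5, -hp, hp)
    return np.array([hp if rng.random() < 0.5 else hm for _ in range(n)])


class TestShrinkage:
    def test_scalar_shrinkage_on_diagonal(self):
        out = shrink_singular_values(np.diag([3.0, 1.0]), 2.0)
        assert np.allclose(out, np.diag([1.0, 0.0]))

    def test_zero_threshold_is_identity(self, rng):
        M = rng.normal(size=(5, 7))
        assert np.allclose(shrink_singular_values(M, 0.0), M, atol=1e-10)

    def test_rank_one_matrix_annihilated_at_its_scale(self, rng):
        u = rng.normal(size=4)
        v = rng.normal(size=6)
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        M = 5.0 * np.outer(u, v)
        assert np.allclose(shrink_singular_values(M, 5.0), 0.0, atol=1e-10)

    def test_singular_values_are_soft_thresholded(self, rng):
        M = rng.normal(size=(6, 9))
        tau = 1.3
        s_in = np.linalg.svd(M, compute_uv=False)
        s_out = np.linalg.svd(shrink_singular_values(M, tau), compute_uv=False)
        expect = np.maximum(s_in - tau, 0.0)
        assert np.allclose(np.sort(s_out)[::-1], expect, atol=1e-10)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            shrink_singular_values(np.eye(2), -1.0)

    def test_minimizes_frobenius_plus_nuclear_objective(self, rng):
        """Oracle: the shrinkage output beats random perturbations on the
        proximal objective 0.5*||M-Z||_F^2 + tau*||Z||_*."""

        def objective(M, Z, tau):
            return 0.5 * np.sum((M - Z) ** 2) + tau * np.linalg.svd(Z, compute_uv=False).sum()

        for _ in range(5):
            M = rng.normal(size=(3, 3)) * 2.0
            tau = float(rng.uniform(0.2, 2.0))
            Z = shrink_singular_values(M, tau)
            base = objective(M, Z, tau)
            for _ in range(60):
                step = rng.choice([1e-3, 1e-2, 1e-1])
                assert base <= objective(M, Z + step * rng.normal(size=(3, 3)), tau) + 1e-12


class TestSVT:
    def test_fully_observed_rank2_meets_residual_rule(self, rng):
        M = _rank2_sign_matrix(rng)
        c = SVTCompleter().fit(M)
        assert c.converged_
        assert c.residuals_[-1] <= c.eps * np.linalg.norm(M)

    def test_residual_trace_recorded_and_consistent(self, b2ar_read_matrix):
        c = SVTCompleter(max_iter=50).fit(b2ar_read_matrix)
        assert len(c.residuals_) == c.n_iter_
        assert c.converged_ or c.n_iter_ == 50

    def test_empty_omega_rejected(self):
        with pytest.raises(CompletionError):
            SVTCompleter().fit(np.zeros((3, 3)))

    @pytest.mark.parametrize("bad", [dict(tau=-1), dict(delta=0), dict(eps=2), dict(max_iter=0)])
    def test_params_validated(self, bad):
        with pytest.raises(ValueError):
            SVTParams(**bad)


class TestNuclearNorm:
    def test_constraint_satisfied_at_solution(self, b2ar_read_matrix):
        c = NuclearNormCompleter(eps=1e-3).fit(b2ar_read_matrix)
        assert c.feasibility_ <= c.eps + c.feas_tol

    def test_fully_observed_objective_bounded_by_input(self, rng):
        M = _rank2_sign_matrix(rng)
        H = NuclearNormCompleter(eps=1e-3).fit_transform(M)
        assert (
            np.linalg.svd(H, compute_uv=False).sum()
            <= np.linalg.svd(M, compute_uv=False).sum() + 1e-6
        )

    def test_loose_constraint_gives_zero_matrix(self, b2ar_read_matrix):
        eps = float(np.linalg.norm(b2ar_read_matrix.densify())) + 1.0
        H = NuclearNormCompleter(eps=eps).fit_transform(b2ar_read_matrix)
        assert np.allclose(H, 0.0, atol=1e-6)

    def test_size_cap_advises_per_block_use(self):
        with pytest.raises(CompletionError, match="block"):
            NuclearNormCompleter(size_cap=4).fit(np.eye(3))


class TestTrim:
    def test_worked_example_unchanged(self, b2ar_read_matrix):
        out = trim(b2ar_read_matrix)
        assert (out.matrix != b2ar_read_matrix.matrix).nnz == 0

    def test_overobserved_column_zeroed(self):
        # column 0 observed by every read; the other columns are sparse
        frags = [
            Fragment(f"r{i}", ((0, 1), (1 + i % 4, -1))) for i in range(10)
        ]
        rm = build_read_matrix(frags, 5)  # col 0 degree 10 > 2*20/5 = 8
        col_deg = np.diff(rm.matrix.tocsc().indptr)
        thresh = 2 * rm.n_observed / rm.n_sites
        assert col_deg[0] > thresh  # scenario premise
        out = trim(rm)
        assert np.diff(out.matrix.tocsc().indptr)[0] == 0

    def test_uniform_degree_always_unchanged(self, rng):
        M = rng.choice([-1.0, 1.0], size=(6, 6))
        rm = as_read_matrix(M)
        assert (trim(rm).matrix != rm.matrix).nnz == 0


class TestProjection:
    def test_fully_observed_rank1_exact(self, rng):
        u = rng.choice([-1.0, 1.0], size=5)
        M = np.outer(np.ones(4), u)
        f = project_rank_r(as_read_matrix(M), 1)
        assert np.allclose(f.full(), M, atol=1e-10)
        assert not f.rank_deficient

    def test_worked_example_matches_svd_oracle(self, b2ar_read_matrix):
        f = project_rank_r(b2ar_read_matrix, 2)
        R = b2ar_read_matrix.densify()
        U, s, Vt = np.linalg.svd(R)
        scale = 100 / b2ar_read_matrix.n_observed
        oracle = scale * (U[:, :2] * s[:2]) @ Vt[:2]
        assert np.allclose(f.full(), oracle, atol=1e-8)

    def test_rank_beyond_matrix_rank_flagged(self):
        M = np.outer([1.0, 1.0, 1.0], [1.0, -1.0])
        f = project_rank_r(as_read_matrix(M), 2)
        assert f.rank_deficient
        assert np.allclose(np.diag(f.S)[1:], 0.0)


class TestCleaning:
    def test_objective_trace_non_increasing(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            M = _rank2_sign_matrix(r, 14, 9)
            mask = r.random(M.shape) < 0.6
            rm = as_read_matrix(M * mask)
            init = project_rank_r(trim(rm), 2)
            _, diag = optspace_clean(rm, init)
            trace = np.array(diag["objective_trace"])
            assert np.all(np.diff(trace) <= 0)

    def test_noiseless_fully_observed_reaches_zero(self, rng):
        M = _rank2_sign_matrix(rng)
        rm = as_read_matrix(M)
        factors, diag = optspace_clean(rm, project_rank_r(rm, 2), tol=1e-12)
        assert diag["final_objective"] < 1e-8

    def test_optimal_init_terminates_immediately(self, rng):
        M = _rank2_sign_matrix(rng)
        rm = as_read_matrix(M)
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        init = FactorTriple(U[:, :2], np.diag(s[:2]), Vt[:2].T)
        _, diag = optspace_clean(rm, init)
        assert diag["n_iter"] <= 1
        assert diag["objective_trace"][-1] <= diag["objective_trace"][0] + 1e-12


class TestOptSpace:
    def test_rank_validated(self, b2ar_read_matrix):
        with pytest.raises(ValueError):
            OptSpaceCompleter(rank=3).fit(b2ar_read_matrix)

    def test_all_het_noiseless_rank1_exact(self, rng):
        hp = rng.choice([-1.0, 1.0], size=8)
        M = np.array([hp * (1 if rng.random() < 0.5 else -1) for _ in range(10)])
        mask = rng.random(M.shape) < 0.7
        mask[:, mask.sum(0) == 0] = True
        H = complete_optspace(M * mask, rank=1)
        assert np.array_equal(np.sign(H[0]) * np.sign(H[0, 0]), hp * hp[0])

    def test_sklearn_param_interface(self):
        c = OptSpaceCompleter(rank=1, max_iter=7)
        assert c.get_params()["max_iter"] == 7
        c.set_params(max_iter=9)
        assert c.max_iter == 9
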