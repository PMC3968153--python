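"""Likelihood-ratio and restricted-likelihood-ratio tests of a single
variance component on the boundary, with exact simulated finite-sample nulls.

Model.  y = beta0 + X beta + G gamma + eps with gamma_j ~ N(0, tau w_j^2)
and eps ~ N(0, sigma^2 I); equivalently (kernel formulation) a random effect
h ~ N(0, tau K) with K = G W G'.  Writing lambda = tau / sigma^2, the
marginal covariance is sigma^2 (I + lambda C) with C = G W G' or K, and the
set-association null hypothesis is H0: lambda = 0 — a boundary hypothesis,
so the usual chi-square asymptotics do not apply.

Observed statistics.  The profile (restricted) log-likelihood in lambda is
maximised over [0, inf) on a log-spaced grid with golden-section refinement;
LRT_n = max(0, 2[sup_l l(lambda) - l(0)]), and similarly for the REML
objective.  lambda-hat at the maximiser doubles as an effect measure through
the set heritability lambda / (1 + lambda).

Null distribution.  Both statistics admit a spectral representation driven
only by the eigenvalues xi_j of W^1/2 G'G W^1/2 (resp. of K) and mu_j of
W^1/2 G'P0 G W^1/2 (resp. K^1/2 P0 K^1/2), where P0 projects off the fixed
effects.  With u_j iid standard normal,

    N(l)  = sum_j [l mu_j / (1 + l mu_j)] u_j^2
    D(l)  = sum_j u_j^2 / (1 + l mu_j)  +  sum_{j > K} u_j^2        (n - p terms)
    LRT   =d sup_l { n log(1 + N/D) - sum_j log(1 + l xi_j) }
    ReLRT =d sup_l { (n - p) log(1 + N/D) - sum_j log(1 + l mu_j) }

Simulating this maximum over the SAME lambda grid used for the observed
statistic yields the exact finite-sample null, including its point mass at
zero, and p-values follow by direct comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import GenotypeMatrix
from .weights_kernels import KernelMatrix, NullProjection, WeightVector, null_projection

logger = logging.getLogger(__name__)

EIG_TRUNC_REL = 1e-10    # drop eigenvalues below this times the largest
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# lambda grid
# ---------------------------------------------------------------------------

@dataclass
class LambdaGrid:
    """Maximisation grid over the variance ratio lambda; always contains 0."""

    values: np.ndarray
    refine_tol: float = 1e-4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values[0] != 0.0:
            raise ValueError("grid must start at lambda = 0")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def positive(self) -> np.ndarray:
        return self.values[1:]


def default_lambda_grid() -> LambdaGrid:
    """{0} plus 81 log-spaced points on [1e-4, 1e4]."""
    return LambdaGrid(values=np.concatenate([[0.0], np.logspace(-4, 4, 81)]))


# ---------------------------------------------------------------------------
# spectral bases
# ---------------------------------------------------------------------------

@dataclass
class SpectralBasis:
    """Eigenvalue pairs driving the observed statistic's null distribution.

    ``xi``: spectrum of the unprojected covariance factor; ``mu``: spectrum
    of the P0-projected factor; both sorted descending, truncated at the
    common active count ``K_active`` set by the xi spectrum.
    """

    xi: np.ndarray
    mu: np.ndarray
    n: int
    p_rank: int
    K_active: int = field(init=False)

    def __post_init__(self) -> None:
        self.xi = np.sort(np.clip(np.asarray(self.xi, dtype=float), 0.0, None))[::-1].copy()
        self.mu = np.sort(np.clip(np.asarray(self.mu, dtype=float), 0.0, None))[::-1].copy()
        if len(self.mu) < len(self.xi):
            self.mu = np.concatenate([self.mu, np.zeros(len(self.xi) - len(self.mu))])
        self.mu = self.mu[: len(self.xi)]
        # projection shrinks the ordered spectrum (Poincare separation)
        self.mu = np.minimum(self.mu, self.xi)
        self.K_active = len(self.xi)

    @property
    def degenerate(self) -> bool:
        return self.K_active == 0 or self.xi.size == 0 or self.xi[0] <= 0


def _truncate(evals: np.ndarray) -> np.ndarray:
    evals = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    if evals.size == 0 or evals.max() <= 0:
        return np.empty(0)
    return evals[evals > EIG_TRUNC_REL * evals.max()]


def spectral_basis_mixed(g: GenotypeMatrix, w: WeightVector,
                         proj: NullProjection) -> SpectralBasis:
    """Eigenvalues of W^1/2 G'G W^1/2 (xi) and W^1/2 G'P0 G W^1/2 (mu),
    computed in the m x m space."""
    n = g.n_samples
    if n - proj.rank <= 1:
        raise ValueError("too few residual degrees of freedom (n - p - 1 <= 1)")
    A = g.counts * w.scaled                        # n x m = G W^1/2
    xi_all = np.linalg.eigvalsh(A.T @ A)
    PA = proj.apply(A)
    mu_all = np.linalg.eigvalsh(A.T @ PA)
    xi = _truncate(xi_all)
    K = len(xi)
    mu = np.sort(np.clip(mu_all, 0.0, None))[::-1][:K]
    return SpectralBasis(xi=xi, mu=mu, n=n, p_rank=proj.rank)


def spectral_basis_kernel(k: KernelMatrix, proj: NullProjection) -> SpectralBasis:
    """Eigenvalues of K (xi) and of K^1/2 P0 K^1/2 (mu).

    The mu spectrum is obtained from P0 K P0, which shares the nonzero
    eigenvalues of K^1/2 P0 K^1/2 (both are Gram matrices of P0 K^1/2) but
    avoids forming the matrix square root.
    """
    n = k.n
    if n - proj.rank <= 1:
        raise ValueError("too few residual degrees of freedom (n - p - 1 <= 1)")
    xi_all = np.linalg.eigvalsh(k.values)
    PKP = proj.apply(proj.apply(k.values).T)
    mu_all = np.linalg.eigvalsh(0.5 * (PKP + PKP.T))
    xi = _truncate(xi_all)
    K = len(xi)
    mu = np.sort(np.clip(mu_all, 0.0, None))[::-1][:K]
    return SpectralBasis(xi=xi, mu=mu, n=n, p_rank=proj.rank)


# ---------------------------------------------------------------------------
# profile likelihoods
# ---------------------------------------------------------------------------

class ProfiledLikelihood:
    """Profile ML and REML log-likelihoods in lambda (up to lambda-free
    constants) for V_lambda = I + lambda C, with C = G W G' or K.

    Uses the eigendecomposition C = U1 diag(s) U1' (nonzero part only), so a
    single O(n m) precomputation makes each likelihood evaluation O(K p).
    """

    def __init__(self, y: np.ndarray, proj: NullProjection,
                 s: np.ndarray, U1: np.ndarray):
        y = np.asarray(y, dtype=float)
        Xd = proj.X_design
        self.n = len(y)
        self.p1 = proj.rank
        self.s = np.asarray(s, dtype=float)
        self.XtX = Xd.T @ Xd
        self.Xty = Xd.T @ y
        self.yty = float(y @ y)
        self.TX = U1.T @ Xd        # K x (p+1)
        self.ty = U1.T @ y         # K

    @classmethod
    def from_genotypes(cls, y: np.ndarray, proj: NullProjection,
                       g: GenotypeMatrix, w: WeightVector) -> "ProfiledLikelihood":
        A = g.counts * w.scaled
        s_all, V = np.linalg.eigh(A.T @ A)
        keep = s_all > EIG_TRUNC_REL * max(s_all[-1], 0.0) if s_all[-1] > 0 else np.zeros_like(s_all, bool)
        s = s_all[keep]
        U1 = (A @ V[:, keep]) / np.sqrt(s)
        return cls(y, proj, s, U1)

    @classmethod
    def from_kernel(cls, y: np.ndarray, proj: NullProjection,
                    k: KernelMatrix) -> "ProfiledLikelihood":
        s_all, U = np.linalg.eigh(k.values)
        keep = s_all > EIG_TRUNC_REL * max(s_all[-1], 0.0) if s_all[-1] > 0 else np.zeros_like(s_all, bool)
        return cls(y, proj, s_all[keep], U[:, keep])

    def _gls_pieces(self, lam: float) -> tuple[float, float, np.ndarray]:
        """(rss, logdetV, M_X) at the GLS fit for V = I + lam C."""
        d = lam * self.s / (1.0 + lam * self.s)        # shrinkage factors
        MX = self.XtX - self.TX.T @ (d[:, None] * self.TX)
        v = self.Xty - self.TX.T @ (d * self.ty)
        qyy = self.yty - float(d @ self.ty**2)
        b = np.linalg.solve(MX, v)
        rss = max(qyy - float(v @ b), np.finfo(float).tiny)
        logdetV = float(np.sum(np.log1p(lam * self.s)))
        return rss, logdetV, MX

    def ml(self, lam: float) -> float:
        """Profile ML log-likelihood at lambda, up to a lambda-free constant."""
        rss, logdetV, _ = self._gls_pieces(lam)
        return -0.5 * self.n * np.log(rss) - 0.5 * logdetV

    def reml(self, lam: float) -> float:
        """Profile REML log-likelihood at lambda, up to a lambda-free constant."""
        rss, logdetV, MX = self._gls_pieces(lam)
        sign, logdetM = np.linalg.slogdet(MX)
        if sign <= 0:
            raise FloatingPointError("X'V^-1 X not positive definite")
        return (-0.5 * (self.n - self.p1) * np.log(rss)
                - 0.5 * logdetV - 0.5 * logdetM)


def profile_ml_loglik(lam: float, y: np.ndarray, proj: NullProjection, *,
                      genotypes: GenotypeMatrix | None = None,
                      weights: WeightVector | None = None,
                      kernel: KernelMatrix | None = None) -> float:
    """Convenience wrapper building the profiled objective for one lambda."""
    return _make_lik(y, proj, genotypes, weights, kernel).ml(lam)


def profile_reml_loglik(lam: float, y: np.ndarray, proj: NullProjection, *,
                        genotypes: GenotypeMatrix | None = None,
                        weights: WeightVector | None = None,
                        kernel: KernelMatrix | None = None) -> float:
    if proj.n - proj.rank == 1:
        logger.warning("only one residual degree of freedom; REML is fragile here")
    return _make_lik(y, proj, genotypes, weights, kernel).reml(lam)


def _make_lik(y, proj, genotypes, weights, kernel) -> ProfiledLikelihood:
    if kernel is not None:
        return ProfiledLikelihood.from_kernel(y, proj, kernel)
    if genotypes is None or weights is None:
        raise ValueError("supply either kernel= or genotypes= and weights=")
    return ProfiledLikelihood.from_genotypes(y, proj, genotypes, weights)


# ---------------------------------------------------------------------------
# maximisation
# ---------------------------------------------------------------------------

def maximize_over_lambda(objective, grid: LambdaGrid) -> tuple[float, float]:
    """Maximise a profile objective over the grid, golden-section refine,
    and return (lambda_hat, statistic = max(0, 2 [sup - value at 0]))."""
    f0 = objective(0.0)
    pos = grid.positive
    fpos = np.array([objective(l) for l in pos])
    if fpos.max() <= f0:
        return 0.0, 0.0
    i = int(np.argmax(fpos))
    logp = np.log(pos)
    step = logp[1] - logp[0] if len(pos) > 1 else 1.0
    lo = logp[i - 1] if i > 0 else logp[0] - step
    if i == len(pos) - 1:
        logger.warning("lambda-hat at the upper grid boundary (%.3g)", pos[i])
        hi = logp[i]
    else:
        hi = logp[i + 1]
    # golden-section on log-lambda
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = objective(np.exp(c)), objective(np.exp(d))
    while (b - a) > grid.refine_tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = objective(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = objective(np.exp(d))
    lam_best = float(np.exp(0.5 * (a + b)))
    f_best = max(objective(lam_best), fpos[i])
    if f_best == fpos[i]:
        lam_best = float(pos[i])
    stat = max(0.0, 2.0 * (f_best - f0))
    if stat == 0.0:
        lam_best = 0.0
    return lam_best, stat


# ---------------------------------------------------------------------------
# exact simulated null
# ---------------------------------------------------------------------------

def _null_objective_grid(basis: SpectralBasis, kind: str, u2: np.ndarray,
                         tail: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Spectral-form statistic values, shape (n_sims, len(lams))."""
    mu = basis.mu
    xi = basis.xi
    lmu = lams[:, None] * mu[None, :]                # L x K
    ratio = lmu / (1.0 + lmu)
    N = u2 @ ratio.T                                 # S x L
    D = u2 @ (1.0 / (1.0 + lmu)).T + tail[:, None]
    core = np.log1p(N / D)
    if kind == "LRT":
        pen = np.log1p(lams[:, None] * xi[None, :]).sum(axis=1)
        return basis.n * core - pen[None, :]
    pen = np.log1p(lmu).sum(axis=1)
    return (basis.n - basis.p_rank) * core - pen[None, :]


def _null_objective_at(basis: SpectralBasis, kind: str, u2: np.ndarray,
                       tail: np.ndarray, lam_vec: np.ndarray) -> np.ndarray:
    """Per-replicate statistic at per-replicate lambda values (vectorised)."""
    mu = basis.mu
    xi = basis.xi
    lmu = lam_vec[:, None] * mu[None, :]             # S x K
    N = (u2 * lmu / (1.0 + lmu)).sum(axis=1)
    D = (u2 / (1.0 + lmu)).sum(axis=1) + tail
    core = np.log1p(N / D)
    if kind == "LRT":
        pen = np.log1p(lam_vec[:, None] * xi[None, :]).sum(axis=1)
        return basis.n * core - pen
    pen = np.log1p(lmu).sum(axis=1)
    return (basis.n - basis.p_rank) * core - pen


def simulate_null(basis: SpectralBasis, kind: str, n_sims: int,
                  grid: LambdaGrid | None = None,
                  seed: int | np.random.SeedSequence | None = 0) -> np.ndarray:
    """Draw ``n_sims`` values from the exact finite-sample null of the LRT
    or ReLRT statistic via its spectral representation.

    Each replicate draws n - p independent standard-normal coordinates (the
    trailing n - p - K of which enter only through their chi-square sum,
    drawn directly), evaluates the spectral objective over the same lambda
    grid used for observed statistics, refines the per-replicate maximiser
    by vectorised golden-section, and clips at zero.  Returns the sorted
    sample.
    """
    if kind not in ("LRT", "ReLRT"):
        raise ValueError("kind must be 'LRT' or 'ReLRT'")
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    if basis.xi.size == 0:
        raise ValueError("empty active spectrum")
    if basis.xi[0] <= 0:
        # all-zero spectrum: the statistic is identically zero
        return np.zeros(n_sims)
    grid = grid or default_lambda_grid()
    rng = np.random.default_rng(seed)
    K = basis.K_active
    df_tail = basis.n - basis.p_rank - K
    if df_tail < 0:
        raise ValueError("active spectrum larger than residual dimension")
    u2 = rng.standard_normal((n_sims, K)) ** 2
    tail = rng.chisquare(df_tail, n_sims) if df_tail > 0 else np.zeros(n_sims)

    lams = grid.positive
    F = _null_objective_grid(basis, kind, u2, tail, lams)
    best = F.max(axis=1)
    arg = F.argmax(axis=1)

    # vectorised golden-section refinement around each replicate's grid peak
    logp = np.log(lams)
    step = logp[1] - logp[0] if len(lams) > 1 else 1.0
    lo = np.where(arg > 0, logp[np.maximum(arg - 1, 0)], logp[0] - step)
    hi = np.where(arg < len(lams) - 1, logp[np.minimum(arg + 1, len(lams) - 1)], logp[-1])
    a, b = lo.copy(), hi.copy()
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = _null_objective_at(basis, kind, u2, tail, np.exp(c))
    fd = _null_objective_at(basis, kind, u2, tail, np.exp(d))
    n_iter = max(1, int(np.ceil(np.log(grid.refine_tol / (2 * step)) / np.log(_GOLDEN))))
    for _ in range(n_iter):
        left = fc >= fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c_new = b - _GOLDEN * (b - a)
        d_new = a + _GOLDEN * (b - a)
        fc_new = np.where(left, np.nan, fd)
        fd_new = np.where(left, fc, np.nan)
        eval_c = left
        lam_eval = np.where(eval_c, c_new, d_new)
        f_eval = _null_objective_at(basis, kind, u2, tail, np.exp(lam_eval))
        fc = np.where(eval_c, f_eval, fc_new)
        fd = np.where(eval_c, fd_new, f_eval)
        c, d = c_new, d_new
    refined = _null_objective_at(basis, kind, u2, tail,
                                 np.exp(0.5 * (a + b)))
    values = np.maximum(0.0, np.maximum(best, refined))
    return np.sort(values)


def pvalue_from_null(statistic: float, null_sample: np.ndarray) -> float:
    """p = (#{null >= statistic} + 1) / (n_sims + 1)."""
    null_sample = np.asarray(null_sample)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    n_ge = null_sample.size - np.searchsorted(np.sort(null_sample), statistic, side="left")
    return (n_ge + 1) / (null_sample.size + 1)


def chibar_pvalue(statistic: float) -> float:
    """Conservative 50:50 chi2_0 : chi2_1 mixture p-value (cross-check only;
    the simulated finite-sample null is the default)."""
    if statistic <= 0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(statistic, 1))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

VC_METHODS = ("LRT.M", "ReLRT.M", "LRT.K", "ReLRT.K")


@dataclass
class VcTestResult:
    """Per-set variance-component test output."""

    method: str
    statistic: float
    lambda_hat: float
    heritability: float
    p_value: float
    n_null_sims: int
    null_zero_mass: float
    seed: int | None = None
    testable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.statistic < 0 or self.lambda_hat < 0:
            raise ValueError("statistic and lambda-hat must be >= 0")
        if not (0 <= self.heritability < 1):
            raise ValueError("heritability must lie in [0, 1)")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def test_set(y: np.ndarray, X: np.ndarray | None, *,
             genotypes: GenotypeMatrix | None = None,
             weights: WeightVector | None = None,
             kernel: KernelMatrix | None = None,
             method: str = "ReLRT.M",
             n_null_sims: int = 10_000,
             grid: LambdaGrid | None = None,
             seed: int = 0) -> VcTestResult:
    """Run one variance-component test on an aligned (y, X, set) triple.

    ``.M`` methods use the weighted genotype matrix directly; ``.K`` methods
    use a kernel (built as the weighted linear kernel when only genotypes
    are supplied).  The observed statistic comes from the data-dependent
    profile likelihood; its p-value from the spectral-representation null
    simulated with the same lambda grid.
    """
    if method not in VC_METHODS:
        raise ValueError(f"method must be one of {VC_METHODS}")
    y = np.asarray(y, dtype=float)
    grid = grid or default_lambda_grid()
    proj = null_projection(X, n=len(y))
    kind = "LRT" if method.startswith("LRT") else "ReLRT"

    if method.endswith(".M"):
        if genotypes is None or weights is None:
            raise ValueError("mixed-model methods need genotypes and weights")
        basis = spectral_basis_mixed(genotypes, weights, proj)
        lik = ProfiledLikelihood.from_genotypes(y, proj, genotypes, weights)
    else:
        if kernel is None:
            from .weights_kernels import weighted_linear_kernel
            if genotypes is None or weights is None:
                raise ValueError("kernel methods need a kernel or genotypes+weights")
            kernel = weighted_linear_kernel(genotypes, weights)
        basis = spectral_basis_kernel(kernel, proj)
        lik = ProfiledLikelihood.from_kernel(y, proj, kernel)

    if basis.degenerate:
        return VcTestResult(method=method, statistic=0.0, lambda_hat=0.0,
                            heritability=0.0, p_value=1.0, n_null_sims=0,
                            null_zero_mass=1.0, seed=seed, testable=False,
                            note="degenerate spectrum (no genetic variation)")

    objective = lik.ml if kind == "LRT" else lik.reml
    lam_hat, statistic = maximize_over_lambda(objective, grid)
    null = simulate_null(basis, kind, n_null_sims, grid, seed)
    p = pvalue_from_null(statistic, null)
    return VcTestResult(
        method=method,
        statistic=statistic,
        lambda_hat=lam_hat,
        heritability=lam_hat / (1.0 + lam_hat),
        p_value=p,
        n_null_sims=n_null_sims,
        null_zero_mass=float(np.mean(null == 0.0)),
        seed=seed,
    )
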