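"""Self-contained rare-variant simulation for the type-I-error and power
studies.

Two genotype backends are provided.

``genealogical`` (default)
    A neutral coalescent simulation (via msprime): a 100 kb region for n
    diploid individuals with canonical human-scale parameters (effective
    population size 1e4, mutation and recombination rates 1.5e-8 and 1e-8
    per bp per generation), from which a random contiguous 30% subregion is
    taken and a contiguous run of ``m_target`` polymorphic rare variants
    (realised MAF below the configured ceiling) is extracted.  Under these
    parameters the expected segregating-site counts are theta * H_{2n-1}
    with theta = 4 Ne mu L = 60, i.e. about 418/435/449 sites at n =
    300/400/500, about 30% of which fall in the subregion and about a third
    of those are rare — around 41/47/51 usable rare variants.  Because the
    variants share a genealogy they carry realistic linkage disequilibrium,
    which is what makes sign-mixed causal effects partially cancel in the
    power study.

``pool``
    An LD-free surrogate: site frequencies drawn from a truncated power-law
    spectrum (density proportional to maf^-alpha; alpha = 1 is the neutral
    1/x shape), sites placed independently on a haplotype pool, individuals
    formed as random haplotype pairs.  Useful for spectrum-level checks and
    for isolating LD effects, but unable to produce cross-variant effect
    cancellation.

Phenotypes follow the standard two-covariate design: x1 ~ N(0, 1),
x2 ~ Bernoulli(0.5), y = b1 x1 + b2 x2 [+ sum_c gamma_c g_c] + eps with
unit-variance Gaussian noise by default.  Causal variants are a fixed
fraction (default 30%) of the rare variants, with effect magnitude
|gamma| = 0.3 |log10 MAF| (so 1.2 at MAF 1e-4, 0.6 at MAF 0.01) and a
configurable fraction of negated signs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeMatrix

BACKENDS = ("genealogical", "pool")


@dataclass
class GenotypeSimConfig:
    n: int = 300
    m_target: int = 41
    maf_range: tuple[float, float] = (5e-4, 0.01)
    backend: str = "genealogical"
    # pool backend
    sfs_alpha: float = 1.0
    haplotype_pool_size: int = 1000   # individuals' worth; pool = 2x haplotypes
    # genealogical backend
    region_length: float = 1e5
    subregion_fraction: float = 0.30
    effective_population_size: float = 1e4
    mutation_rate: float = 1.5e-8
    recombination_rate: float = 1e-8
    seed: int | np.random.SeedSequence | None = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < floor < ceiling <= 0.5")
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")
        if hi * 2 * self.haplotype_pool_size < 1:
            raise ValueError("infeasible config: ceiling * pool haplotypes < 1")
        if self.n < 2 or self.m_target < 1:
            raise ValueError("need n >= 2 and m_target >= 1")


@dataclass
class PhenotypeSimConfig:
    causal_fraction: float = 0.30
    effect_scale: float = 0.3        # c in |gamma| = c |log10 MAF|
    negative_fraction: float = 0.0
    covariate_betas: tuple[float, float] = (0.5, 0.5)
    noise_sd: float = 1.0
    seed: int | np.random.SeedSequence | None = 0

    def __post_init__(self) -> None:
        for f in (self.causal_fraction, self.negative_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def truncated_powerlaw_mean(lo: float, hi: float, alpha: float) -> float:
    """Analytic mean of the density proportional to x^-alpha on (lo, hi)."""
    if alpha == 1.0:
        return (hi - lo) / np.log(hi / lo)
    if alpha == 2.0:
        return np.log(hi / lo) / (1 / lo - 1 / hi)
    a1, a2 = 1.0 - alpha, 2.0 - alpha
    return (a1 / a2) * (hi ** a2 - lo ** a2) / (hi ** a1 - lo ** a1)


def draw_site_frequencies(rng: np.random.Generator, m: int,
                          lo: float, hi: float, alpha: float) -> np.ndarray:
    """Inverse-CDF draws from the truncated power-law frequency spectrum."""
    u = rng.uniform(size=m)
    if alpha == 1.0:
        return lo * (hi / lo) ** u
    a1 = 1.0 - alpha
    return (lo ** a1 + u * (hi ** a1 - lo ** a1)) ** (1.0 / a1)


def _simulate_pool(cfg: GenotypeSimConfig, rng: np.random.Generator) -> GenotypeMatrix:
    lo, hi = cfg.maf_range
    n_hap = 2 * cfg.haplotype_pool_size
    pair_idx = rng.integers(0, n_hap, size=(cfg.n, 2))

    cols = np.empty((cfg.n, cfg.m_target))
    mafs = np.empty(cfg.m_target)
    for j in range(cfg.m_target):
        for _attempt in range(1000):
            f = draw_site_frequencies(rng, 1, lo, hi, cfg.sfs_alpha)[0]
            hap = rng.random(n_hap) < f
            if not hap.any():
                continue
            col = hap[pair_idx[:, 0]].astype(float) + hap[pair_idx[:, 1]]
            realized = col.mean() / 2.0
            if 0.0 < realized < hi:
                cols[:, j] = col
                mafs[j] = realized
                break
        else:
            raise RuntimeError("could not realise a polymorphic rare site")
    ids = [f"rv{j+1}" for j in range(cfg.m_target)]
    return GenotypeMatrix(samples=[f"s{i+1}" for i in range(cfg.n)],
                          variant_ids=ids, counts=cols, maf=mafs)


def _simulate_genealogical(cfg: GenotypeSimConfig,
                           rng: np.random.Generator) -> GenotypeMatrix:
    import msprime

    hi = cfg.maf_range[1]
    L = cfg.region_length
    win = cfg.subregion_fraction * L
    for _attempt in range(60):
        ts = msprime.sim_ancestry(
            samples=cfg.n, population_size=cfg.effective_population_size,
            sequence_length=L, recombination_rate=cfg.recombination_rate,
            random_seed=int(rng.integers(1, 2**31 - 1)))
        mts = msprime.sim_mutations(
            ts, rate=cfg.mutation_rate,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel())
        H = mts.genotype_matrix()                 # sites x 2n haplotypes
        if H.shape[0] == 0:
            continue
        dos = (H[:, 0::2] + H[:, 1::2]).T.astype(float)   # n x sites
        freq = dos.mean(axis=0) / 2.0
        flip = freq > 0.5
        dos[:, flip] = 2.0 - dos[:, flip]
        maf = np.where(flip, 1.0 - freq, freq)
        pos = mts.tables.sites.position
        # a few random subregion placements per tree sequence
        for _w in range(8):
            start = rng.uniform(0, L - win)
            rare = np.where((pos >= start) & (pos < start + win)
                            & (maf > 0) & (maf < hi))[0]
            if len(rare) < cfg.m_target:
                continue
            s = rng.integers(0, len(rare) - cfg.m_target + 1)
            take = rare[s:s + cfg.m_target]
            ids = [f"pos{int(round(pos[j]))}_{k}" for k, j in enumerate(take)]
            return GenotypeMatrix(
                samples=[f"s{i+1}" for i in range(cfg.n)],
                variant_ids=ids, counts=dos[:, take], maf=maf[take],
                pos=pos[take])
    raise RuntimeError("could not realise enough rare variants; lower m_target "
                       "or enlarge the region")


def simulate_genotypes(cfg: GenotypeSimConfig) -> GenotypeMatrix:
    """Draw an n x m_target rare-variant dosage matrix (see module doc)."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.backend == "pool":
        return _simulate_pool(cfg, rng)
    return _simulate_genealogical(cfg, rng)


# ---------------------------------------------------------------------------
# covariates, effects, phenotypes
# ---------------------------------------------------------------------------

def simulate_covariates(n: int, seed: int | np.random.SeedSequence | None = 0) -> np.ndarray:
    """Two independent columns: x1 ~ N(0, 1) and x2 ~ Bernoulli(0.5)."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.integers(0, 2, size=n).astype(float)
    return np.column_stack([x1, x2])


def effect_size(maf: float | np.ndarray, scale: float = 0.3) -> float | np.ndarray:
    """|gamma| = scale * |log10 MAF| — the MAF-dependent effect rule."""
    return scale * np.abs(np.log10(maf))


def assign_effects(g: GenotypeMatrix, cfg: PhenotypeSimConfig,
                   rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pick the causal set and its signed effect sizes.

    Returns (causal indices, gamma vector over the causal indices).  The
    causal count is round(causal_fraction * m); round(negative_fraction * q)
    of the causal effects are negated, both chosen uniformly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    m = g.n_variants
    q = int(round(cfg.causal_fraction * m))
    if q < 1 and cfg.causal_fraction > 0:
        q = 1
    causal = np.sort(rng.choice(m, size=q, replace=False))
    gamma = np.asarray(effect_size(g.maf[causal], cfg.effect_scale), dtype=float)
    n_neg = int(round(cfg.negative_fraction * q))
    if n_neg:
        neg = rng.choice(q, size=n_neg, replace=False)
        gamma[neg] *= -1.0
    return causal, gamma


def simulate_phenotype(X: np.ndarray, g: GenotypeMatrix,
                       effects: tuple[np.ndarray, np.ndarray] | None,
                       cfg: PhenotypeSimConfig, null: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """y = b1 x1 + b2 x2 (+ genetic sum unless null) + Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if g.n_samples != n:
        raise ValueError("covariate/genotype sample mismatch")
    b1, b2 = cfg.covariate_betas
    y = b1 * X[:, 0] + b2 * X[:, 1] + cfg.noise_sd * rng.standard_normal(n)
    if not null:
        if effects is None:
            raise ValueError("need effects for non-null phenotypes")
        causal, gamma = effects
        y = y + g.counts[:, causal] @ gamma
    return y
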