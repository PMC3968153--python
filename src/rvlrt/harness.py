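"""Simulation-study harness (type-I error and power) and per-set analysis.

A study cell is a (sample size, scenario) pair; every replicate inside a
cell simulates fresh genotypes (by default), covariates and a phenotype,
runs the requested tests on the *same* data, and records their p-values.
Common random numbers across methods make power differences far less noisy
than the per-method powers themselves.

Seeding: each replicate derives an independent stream from the root seed
through ``numpy.random.SeedSequence(root, spawn_key=(study, n, scenario,
replicate))``, so results are byte-identical across reruns and independent
of worker scheduling.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data_io import (AssociationRecord, EmptyVariantSetError, GenotypeMatrix,
                      PhenotypeTable, VariantSet, align, rare_filter)
from .score_tests import burden_test, skat_o, skat_test
from .synth_data import (GenotypeSimConfig, PhenotypeSimConfig, assign_effects,
                         simulate_covariates, simulate_genotypes,
                         simulate_phenotype)
from .vc_lrt import LambdaGrid, default_lambda_grid, test_set
from .weights_kernels import beta_maf_weights, null_projection

logger = logging.getLogger(__name__)

ALL_METHODS = ("burden", "skat", "skato", "lrt.k", "relrt.k", "lrt.m", "relrt.m")
_VC_NAME = {"lrt.m": "LRT.M", "relrt.m": "ReLRT.M",
            "lrt.k": "LRT.K", "relrt.k": "ReLRT.K"}

# default mapping of sample size to emitted rare-variant count, mirroring a
# coalescent panel in which larger samples expose more segregating rare sites
DEFAULT_VARIANTS_PER_N = {300: 41, 400: 47, 500: 51}


@dataclass
class SimStudyConfig:
    sample_sizes: tuple[int, ...] = (300, 400, 500)
    alphas: tuple[float, ...] = (0.01, 0.05)
    n_reps_null: int = 2000
    n_reps_power: int = 1000
    negative_fractions: tuple[float, ...] = (0.0, 0.3, 0.5)
    methods: tuple[str, ...] = ALL_METHODS
    n_null_sims: int = 2000
    skato_n_mc: int = 1000
    seed: int = 0
    n_jobs: int = 1
    variants_per_n: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_VARIANTS_PER_N))
    causal_fraction: float = 0.30
    effect_scale: float = 0.3
    covariate_betas: tuple[float, float] = (0.5, 0.5)
    noise_sd: float = 1.0
    maf_range: tuple[float, float] = (5e-4, 0.01)
    genotype_backend: str = "genealogical"
    sfs_alpha: float = 1.0
    haplotype_pool_size: int = 1000
    fresh_genotypes: bool = True

    def __post_init__(self) -> None:
        if self.n_reps_null < 100 or self.n_reps_power < 100:
            raise ValueError("any reported cell needs at least 100 replicates")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def m_for(self, n: int) -> int:
        if n in self.variants_per_n:
            return self.variants_per_n[n]
        # interpolate on the configured anchors
        ks = sorted(self.variants_per_n)
        return int(round(np.interp(n, ks, [self.variants_per_n[k] for k in ks])))


@dataclass
class StudyReport:
    type1: pd.DataFrame | None = None
    power: pd.DataFrame | None = None
    loss: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)

    def to_tsv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("type1", "power", "loss"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {"config": self.config}
        for name in ("type1", "power", "loss"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = df.to_dict(orient="records")
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _replicate_pvalues(root_seed: int, study: int, n: int, scen: int, rep: int,
                       m: int, negative_fraction: float | None,
                       cfg_dict: dict) -> dict[str, float]:
    """One replicate: simulate data, run every requested method, return p's.

    ``negative_fraction`` None means a null (no-association) phenotype.
    """
    ss = np.random.SeedSequence(root_seed, spawn_key=(study, n, scen, rep))
    s_geno, s_cov, s_eff, s_phen, s_skato, s_vc = ss.spawn(6)
    geno = simulate_genotypes(GenotypeSimConfig(
        n=n, m_target=m, maf_range=tuple(cfg_dict["maf_range"]),
        backend=cfg_dict["genotype_backend"], sfs_alpha=cfg_dict["sfs_alpha"],
        haplotype_pool_size=cfg_dict["haplotype_pool_size"], seed=s_geno))
    X = simulate_covariates(n, s_cov)
    pcfg = PhenotypeSimConfig(
        causal_fraction=cfg_dict["causal_fraction"],
        effect_scale=cfg_dict["effect_scale"],
        negative_fraction=negative_fraction or 0.0,
        covariate_betas=tuple(cfg_dict["covariate_betas"]),
        noise_sd=cfg_dict["noise_sd"])
    is_null = negative_fraction is None
    effects = None if is_null else assign_effects(geno, pcfg, np.random.default_rng(s_eff))
    y = simulate_phenotype(X, geno, effects, pcfg, null=is_null,
                           rng=np.random.default_rng(s_phen))

    w = beta_maf_weights(geno.maf)
    methods = cfg_dict["methods"]
    out: dict[str, float] = {}
    if {"burden", "skat", "skato"} & set(methods):
        proj = null_projection(X)
        if "burden" in methods:
            out["burden"] = burden_test(y, proj, geno, w).p_value
        if "skat" in methods:
            out["skat"] = skat_test(y, proj, geno, w).p_value
        if "skato" in methods:
            out["skato"] = skat_o(y, proj, geno, w,
                                  n_mc=cfg_dict["skato_n_mc"], seed=s_skato).p_value
    vc_seeds = s_vc.spawn(4)
    grid = default_lambda_grid()
    for i, key in enumerate(("lrt.m", "relrt.m", "lrt.k", "relrt.k")):
        if key in methods:
            res = test_set(y, X, genotypes=geno, weights=w,
                           method=_VC_NAME[key],
                           n_null_sims=cfg_dict["n_null_sims"],
                           grid=grid, seed=vc_seeds[i])
            out[key] = res.p_value
    return out


def _run_cell(cfg: SimStudyConfig, study: int, n: int, scen: int,
              negative_fraction: float | None, reps: int) -> pd.DataFrame:
    m = cfg.m_for(n)
    cfg_dict = asdict(cfg)
    rows = Parallel(n_jobs=cfg.n_jobs)(
        delayed(_replicate_pvalues)(cfg.seed, study, n, scen, rep, m,
                                    negative_fraction, cfg_dict)
        for rep in range(reps))
    return pd.DataFrame(rows)


def run_type1_study(cfg: SimStudyConfig) -> StudyReport:
    """Empirical type-I error per (n, method, alpha) with binomial CIs."""
    records = []
    for n in cfg.sample_sizes:
        pvals = _run_cell(cfg, study=0, n=n, scen=0,
                          negative_fraction=None, reps=cfg.n_reps_null)
        for method in pvals.columns:
            for alpha in cfg.alphas:
                rate = float((pvals[method] <= alpha).mean())
                se = float(np.sqrt(alpha * (1 - alpha) / cfg.n_reps_null))
                records.append(dict(n=n, method=method, alpha=alpha, rate=rate,
                                    se=se, ci_lo=max(rate - 1.96 * se, 0.0),
                                    ci_hi=min(rate + 1.96 * se, 1.0),
                                    reps=cfg.n_reps_null))
        logger.info("type-I cell n=%d done", n)
    return StudyReport(type1=pd.DataFrame(records), config=asdict(cfg))


def run_power_study(cfg: SimStudyConfig) -> StudyReport:
    """Power per (n, method, alpha, negative fraction) plus the loss table
    (power at 0%% negative minus power at each other fraction, with a
    cross-sample-size average row)."""
    fracs = tuple(cfg.negative_fractions)
    if 0.0 not in fracs:
        fracs = (0.0,) + fracs
    records = []
    for n in cfg.sample_sizes:
        for si, frac in enumerate(fracs):
            pvals = _run_cell(cfg, study=1, n=n, scen=si,
                              negative_fraction=frac, reps=cfg.n_reps_power)
            for method in pvals.columns:
                for alpha in cfg.alphas:
                    records.append(dict(n=n, method=method, alpha=alpha,
                                        negative_fraction=frac,
                                        power=float((pvals[method] <= alpha).mean()),
                                        reps=cfg.n_reps_power))
            logger.info("power cell n=%d frac=%.2f done", n, frac)
    power = pd.DataFrame(records)

    loss_rows = []
    base = power[power.negative_fraction == 0.0].set_index(["n", "method", "alpha"]).power
    for frac in [f for f in fracs if f > 0]:
        sub = power[power.negative_fraction == frac]
        for _, row in sub.iterrows():
            loss_rows.append(dict(n=row.n, method=row.method, alpha=row.alpha,
                                  negative_fraction=frac,
                                  loss=float(base.loc[(row.n, row.method, row.alpha)]
                                             - row.power)))
    loss = pd.DataFrame(loss_rows)
    if not loss.empty:
        avg = (loss.groupby(["method", "alpha", "negative_fraction"], as_index=False)
               .loss.mean())
        avg.insert(0, "n", "average")
        loss = pd.concat([loss, avg], ignore_index=True)
    return StudyReport(power=power, loss=loss, config=asdict(cfg))


# ---------------------------------------------------------------------------
# per-set analysis (the CLI's engine)
# ---------------------------------------------------------------------------

def analyze_sets(geno: GenotypeMatrix, pheno: PhenotypeTable,
                 sets: list[VariantSet], methods: tuple[str, ...],
                 formulation: str = "mixed", kernel_kind: str = "linear.weighted",
                 maf_max: float = 0.01, n_null_sims: int = 10_000,
                 skato_n_mc: int = 1000, seed: int = 0,
                 grid: LambdaGrid | None = None) -> list[AssociationRecord]:
    """Run the requested tests on each variant set and collect result rows."""
    from .weights_kernels import make_kernel

    if formulation not in ("mixed", "kernel"):
        raise ValueError("formulation must be 'mixed' or 'kernel'")
    grid = grid or default_lambda_grid()
    records = []
    for k, vset in enumerate(sets):
        child = np.random.SeedSequence(seed, spawn_key=(k,))
        s_skato, s_lrt, s_relrt = child.spawn(3)
        try:
            g_set, ph = align(geno, pheno, vset)
            m_total = g_set.n_variants
            g_rare = rare_filter(g_set, maf_max)
        except EmptyVariantSetError as exc:
            records.append(AssociationRecord(
                set_name=vset.name, m_total=len(vset.variant_ids), m_rare=0,
                testable=False, note=f"not_testable: {exc}"))
            continue
        w = beta_maf_weights(g_rare.maf)
        y, X = ph.y, ph.X
        rec = AssociationRecord(set_name=vset.name, m_total=m_total,
                                m_rare=g_rare.n_variants)
        if {"burden", "skat", "skato"} & set(methods):
            proj = null_projection(X, n=len(y))
            if "burden" in methods:
                r = burden_test(y, proj, g_rare, w)
                rec.p_values["burden"], rec.statistics["burden"] = r.p_value, r.Q
            if "skat" in methods:
                r = skat_test(y, proj, g_rare, w)
                rec.p_values["skat"], rec.statistics["skat"] = r.p_value, r.Q
            if "skato" in methods:
                r = skat_o(y, proj, g_rare, w, n_mc=skato_n_mc, seed=s_skato)
                rec.p_values["skato"], rec.statistics["skato"] = r.p_value, r.Q
        kern = None
        if formulation == "kernel" and {"lrt", "relrt"} & set(methods):
            kern = make_kernel(g_rare, w, kernel_kind)
        suffix = ".M" if formulation == "mixed" else ".K"
        if "lrt" in methods:
            r = test_set(y, X, genotypes=g_rare, weights=w, kernel=kern,
                         method="LRT" + suffix, n_null_sims=n_null_sims,
                         grid=grid, seed=s_lrt)
            rec.p_values["lrt"], rec.statistics["lrt"] = r.p_value, r.statistic
            rec.lambda_lrt, rec.heritability_lrt = r.lambda_hat, r.heritability
            logger.info("set %s: m_rare=%d lambda_lrt=%.4g zero_mass=%.3f",
                        vset.name, g_rare.n_variants, r.lambda_hat, r.null_zero_mass)
        if "relrt" in methods:
            r = test_set(y, X, genotypes=g_rare, weights=w, kernel=kern,
                         method="ReLRT" + suffix, n_null_sims=n_null_sims,
                         grid=grid, seed=s_relrt)
            rec.p_values["relrt"], rec.statistics["relrt"] = r.p_value, r.statistic
            rec.lambda_relrt, rec.heritability_relrt = r.lambda_hat, r.heritability
        records.append(rec)
    return records
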