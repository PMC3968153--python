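"""Readers, writers and in-memory containers for genotype/phenotype/set data.

Genotypes are held as minor-allele dosages (additive coding): 0, 1 or 2
copies of the *minor* allele per individual and variant.  Variants whose
alternate-allele frequency exceeds 0.5 in the file are recoded so that the
counted allele is always the minor one; this recoding is done per dataset,
before any set restriction, so that MAF-based weights are stable across
tested sets.

Missing genotypes are resolved at load time according to a policy:

``mean``
    replace a missing entry by twice the variant's MAF computed from the
    observed entries (the common convention in kernel-association software);
``drop_variant``
    remove any variant with at least one missing call;
``fail``
    raise on the first missing call.

Mean imputation leaves the per-variant MAF computed over the full column
identical to the MAF computed over observed calls, which the containers
assert as an invariant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("mean", "drop_variant", "fail")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class EmptyVariantSetError(DataError):
    """No variant survives filtering; the set is not testable."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """n x m minor-allele dosage matrix with per-variant MAF.

    ``counts[i, j]`` is the dosage of the minor allele of variant ``j`` in
    sample ``i``.  Observed calls are integers in {0, 1, 2}; mean-imputed
    entries may be fractional but stay within [0, 2].  ``maf`` is the
    frequency of the coded (minor) allele, in (0, 0.5] for polymorphic sites
    and 0 for monomorphic ones.
    """

    samples: list[str]
    variant_ids: list[str]
    counts: np.ndarray
    maf: np.ndarray
    chrom: list[str] | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def recomputed_maf(self) -> np.ndarray:
        return self.counts.mean(axis=0) / 2.0

    def validate(self) -> None:
        n, m = self.counts.shape
        if n < 2:
            raise DataError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise DataError("need at least one variant")
        if len(self.samples) != n or len(self.variant_ids) != m:
            raise DataError("label/matrix dimension mismatch")
        if len(set(self.variant_ids)) != m:
            raise DataError("duplicate variant identifiers")
        if np.any(~np.isfinite(self.counts)):
            raise DataError("non-finite genotype entries (unresolved missing data?)")
        if self.counts.min() < 0 or self.counts.max() > 2:
            raise DataError("genotype dosages must lie in [0, 2]")
        if np.any(self.maf < 0) or np.any(self.maf > 0.5 + 1e-12):
            raise DataError("MAF must lie in [0, 0.5]")
        if not np.allclose(self.recomputed_maf(), self.maf, rtol=0, atol=1e-12):
            raise DataError("stored MAF inconsistent with counts")

    def subset_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variant_ids=[self.variant_ids[i] for i in idx],
            counts=self.counts[:, idx],
            maf=self.maf[idx],
            chrom=[self.chrom[i] for i in idx] if self.chrom is not None else None,
            pos=self.pos[idx] if self.pos is not None else None,
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        counts = self.counts[idx, :]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variant_ids=list(self.variant_ids),
            counts=counts,
            maf=counts.mean(axis=0) / 2.0,
            chrom=self.chrom,
            pos=self.pos,
        )


@dataclass
class PhenotypeTable:
    """Continuous phenotype plus optional covariates, sample-aligned."""

    samples: list[str]
    y: np.ndarray
    X: np.ndarray  # n x p, p >= 0
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(len(self.y), -1)
        if self.X.size == 0:
            self.X = np.empty((len(self.y), 0))
        n = len(self.samples)
        if self.y.shape != (n,) or self.X.shape[0] != n:
            raise DataError("phenotype/covariate dimension mismatch")
        if np.any(~np.isfinite(self.y)):
            raise DataError("missing phenotype values")
        if self.X.shape[1]:
            design = np.column_stack([np.ones(n), self.X])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                raise DataError("covariate columns collinear with the intercept")

    def subset(self, index: Sequence[int]) -> "PhenotypeTable":
        idx = np.asarray(index, dtype=int)
        return PhenotypeTable(
            samples=[self.samples[i] for i in idx],
            y=self.y[idx],
            X=self.X[idx, :],
            covariate_names=list(self.covariate_names),
        )


@dataclass
class VariantSet:
    """A named a-priori region: gene/pathway mapped to variant IDs."""

    name: str
    variant_ids: list[str]

    def __post_init__(self) -> None:
        if not self.variant_ids:
            raise DataError(f"variant set {self.name!r} is empty")
        seen: dict[str, None] = {}
        dups = 0
        for v in self.variant_ids:
            if v in seen:
                dups += 1
            seen[v] = None
        if dups:
            logger.warning("set %s: %d duplicate variant ids de-duplicated", self.name, dups)
            self.variant_ids = list(seen)


@dataclass
class AssociationRecord:
    """Per-set association output row (one line of the results table)."""

    set_name: str
    m_total: int
    m_rare: int
    p_values: dict[str, float] = field(default_factory=dict)
    statistics: dict[str, float] = field(default_factory=dict)
    lambda_lrt: float | None = None
    lambda_relrt: float | None = None
    heritability_lrt: float | None = None
    heritability_relrt: float | None = None
    testable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        for method, p in self.p_values.items():
            if not (0 < p <= 1):
                raise DataError(f"p-value for {method} outside (0, 1]: {p}")
        for lam in (self.lambda_lrt, self.lambda_relrt):
            if lam is not None and lam < 0:
                raise DataError("lambda-hat must be >= 0")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _resolve_missing(raw: np.ndarray, variant_ids: list[str],
                     chrom: list[str] | None, pos: np.ndarray | None,
                     policy: str) -> tuple[np.ndarray, list[str], list[str] | None, np.ndarray | None]:
    """Minor-allele recoding + missing-data resolution on a raw dosage
    matrix (NaN = missing, entries counted toward the file's ALT/coded
    allele)."""
    if policy not in MISSING_POLICIES:
        raise DataError(f"unknown missing policy {policy!r}")
    n, m = raw.shape
    obs = ~np.isnan(raw)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        bad = [variant_ids[j] for j in np.where(n_obs == 0)[0]]
        raise DataError(f"all-missing variants: {bad[:5]}")

    # per-dataset minor-allele recode
    freq = np.nansum(raw, axis=0) / (2.0 * n_obs)
    flip = freq > 0.5
    if np.any(flip):
        raw = raw.copy()
        raw[:, flip] = 2.0 - raw[:, flip]
        logger.info("recoded %d variants toward the minor allele", int(flip.sum()))

    missing_any = (~obs).any(axis=0)
    if policy == "fail" and np.any(missing_any):
        bad = [variant_ids[j] for j in np.where(missing_any)[0]]
        raise DataError(f"missing genotypes under policy=fail: {bad[:5]}")
    if policy == "drop_variant":
        keep = np.where(~missing_any)[0]
        if keep.size == 0:
            raise DataError("all variants dropped by missing policy")
        raw = raw[:, keep]
        variant_ids = [variant_ids[j] for j in keep]
        chrom = [chrom[j] for j in keep] if chrom is not None else None
        pos = pos[keep] if pos is not None else None
    elif policy == "mean":
        maf_obs = np.nansum(raw, axis=0) / (2.0 * obs.sum(axis=0))
        fill = np.broadcast_to(2.0 * maf_obs, raw.shape)
        raw = np.where(np.isnan(raw), fill, raw)
    return raw, variant_ids, chrom, pos


def read_genotypes(path: str | Path, format: str = "matrix",
                   missing_policy: str = "mean") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a dosage-matrix TSV.

    The TSV layout is one row per variant: first column the variant ID, the
    remaining columns one per sample, entries 0/1/2 or ``.`` for missing.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format == "vcf":
        return _read_vcf(path, missing_policy)
    if format == "matrix":
        return _read_matrix(path, missing_policy)
    raise DataError(f"unknown genotype format {format!r}")


def _read_matrix(path: Path, policy: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] < 1 or df.shape[1] < 2:
        raise DataError(f"{path}: need >=1 variant row and >=2 sample columns")
    vals = df.to_numpy(dtype=object)
    missing = vals == "."
    raw = np.empty(vals.shape, dtype=float)
    raw[missing] = np.nan
    try:
        raw[~missing] = vals[~missing].astype(float)
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric genotype entry ({exc})")
    raw = raw.T  # -> samples x variants
    if np.any((raw[~np.isnan(raw)] % 1 != 0) | (raw[~np.isnan(raw)] < 0) | (raw[~np.isnan(raw)] > 2)):
        raise DataError(f"{path}: entries must be 0/1/2/.")
    ids = [str(v) for v in df.index]
    if len(set(ids)) != len(ids):
        raise DataError(f"{path}: duplicate variant IDs")
    counts, ids, _, _ = _resolve_missing(raw, ids, None, None, policy)
    return GenotypeMatrix(
        samples=[str(s) for s in df.columns],
        variant_ids=ids,
        counts=counts,
        maf=counts.mean(axis=0) / 2.0,
    )


def _read_vcf(path: Path, policy: str) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise DataError(f"{path}: fewer than 2 samples")
    ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(
                f"{path}: multi-allelic site at {var.CHROM}:{var.POS}; split upstream"
            )
        dose = np.asarray(var.gt_types, dtype=float)  # 0/1/2 alt copies, 3 missing
        dose[dose == 3] = np.nan
        rows.append(dose)
        ids.append(f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}")
        chroms.append(str(var.CHROM))
        poss.append(var.POS)
    if not rows:
        raise DataError(f"{path}: no variant records")
    raw = np.vstack(rows).T  # samples x variants
    counts, ids, chroms, poss = _resolve_missing(raw, ids, chroms, np.asarray(poss), policy)
    return GenotypeMatrix(
        samples=samples,
        variant_ids=ids,
        counts=counts,
        maf=counts.mean(axis=0) / 2.0,
        chrom=chroms,
        pos=poss,
    )


def write_genotype_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage-matrix TSV (rows = variants) that ``read_genotypes``
    accepts; integer entries are rendered without a decimal point so that a
    write/read round trip is exact."""
    mat = g.counts.T
    with open(path, "w") as fh:
        fh.write("variant_id\t" + "\t".join(g.samples) + "\n")
        for j, vid in enumerate(g.variant_ids):
            row = ["%d" % v if float(v).is_integer() else repr(float(v)) for v in mat[j]]
            fh.write(vid + "\t" + "\t".join(row) + "\n")


def read_phenotypes(path: str | Path, pheno_col: str,
                    covar_cols: Sequence[str] = ()) -> PhenotypeTable:
    """Read a phenotype TSV (first column = sample ID, named columns)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in [pheno_col, *covar_cols]:
        if col not in df.columns:
            raise DataError(f"{path}: no column named {col!r}")
    df = df.dropna(subset=[pheno_col, *covar_cols])
    X = df[list(covar_cols)].to_numpy(dtype=float) if covar_cols else np.empty((len(df), 0))
    return PhenotypeTable(
        samples=[str(s) for s in df.index],
        y=df[pheno_col].to_numpy(dtype=float),
        X=X,
        covariate_names=list(covar_cols),
    )


def write_phenotypes(ph: PhenotypeTable, path: str | Path, pheno_col: str = "y") -> None:
    df = pd.DataFrame({pheno_col: ph.y}, index=pd.Index(ph.samples, name="sample"))
    for j, name in enumerate(ph.covariate_names or [f"x{j+1}" for j in range(ph.X.shape[1])]):
        df[name] = ph.X[:, j]
    df.to_csv(path, sep="\t")


def read_variant_sets(path: str | Path) -> list[VariantSet]:
    """Read a two-column (set name, variant ID) file, the usual SetID layout;
    no header line is expected."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two whitespace-delimited columns")
    sets = []
    for name, sub in df.groupby(0, sort=False):
        sets.append(VariantSet(name=str(name), variant_ids=[str(v) for v in sub[1]]))
    return sets


# ---------------------------------------------------------------------------
# filtering / alignment
# ---------------------------------------------------------------------------

def rare_filter(g: GenotypeMatrix, maf_threshold: float = 0.01) -> GenotypeMatrix:
    """Keep variants with 0 < MAF < ``maf_threshold``.

    Monomorphic variants are dropped with a warning; raises
    :class:`EmptyVariantSetError` when nothing survives, which callers report
    as a "not testable" set.
    """
    if not (0 < maf_threshold <= 0.5):
        raise DataError("maf_threshold must lie in (0, 0.5]")
    mono = g.maf <= 0
    if np.any(mono):
        logger.warning("dropping %d monomorphic variants", int(mono.sum()))
    keep = np.where((g.maf > 0) & (g.maf < maf_threshold))[0]
    if keep.size == 0:
        raise EmptyVariantSetError(
            f"no polymorphic variant with MAF < {maf_threshold}: set not testable"
        )
    return g.subset_variants(keep)


def align(g: GenotypeMatrix, ph: PhenotypeTable,
          vset: VariantSet | None = None) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Intersect samples (ordered as in the genotype data) and optionally
    restrict the genotype columns to a variant set."""
    ph_index = {s: i for i, s in enumerate(ph.samples)}
    shared = [i for i, s in enumerate(g.samples) if s in ph_index]
    if len(shared) < 2:
        raise DataError("fewer than 2 samples shared between genotypes and phenotypes")
    if len(shared) < g.n_samples or len(shared) < len(ph.samples):
        logger.info("aligning on %d shared samples", len(shared))
    g2 = g.subset_samples(shared) if len(shared) < g.n_samples else g
    ph2 = ph.subset([ph_index[g2.samples[i]] for i in range(len(shared))])

    if vset is not None:
        gidx = {v: j for j, v in enumerate(g2.variant_ids)}
        present = [gidx[v] for v in vset.variant_ids if v in gidx]
        absent = len(vset.variant_ids) - len(present)
        if absent:
            logger.warning("set %s: %d listed variants absent from the data",
                           vset.name, absent)
        if not present:
            raise EmptyVariantSetError(f"set {vset.name}: no listed variant present")
        g2 = g2.subset_variants(present)
    return g2, ph2


# ---------------------------------------------------------------------------
# results output
# ---------------------------------------------------------------------------

_METHOD_ORDER = ("burden", "skat", "skato", "lrt", "relrt")


def format_p(p: float | None) -> str:
    if p is None or not np.isfinite(p):
        return "NA"
    return f"{p:.2e}" if p < 1e-3 else f"{p:.4f}"


def format_lambda(lam: float | None) -> str:
    if lam is None or not np.isfinite(lam):
        return "NA"
    return "<0.001" if lam < 1e-3 else f"{lam:.3f}"


def write_results(records: Sequence[AssociationRecord], path: str | Path) -> None:
    """Write the per-set association table (TSV, fixed column order).

    P-values below 1e-3 are rendered in scientific notation; the machine
    columns ``lambda_lrt``/``lambda_relrt`` carry full precision while the
    ``*_display`` twins use the human-readable "<0.001" convention.
    """
    methods = [m for m in _METHOD_ORDER
               if any(m in r.p_values for r in records)] or list(_METHOD_ORDER)
    cols = (["set", "m_total", "m_rare"]
            + [f"p_{m}" for m in methods]
            + ["lambda_lrt", "lambda_relrt",
               "lambda_lrt_display", "lambda_relrt_display",
               "heritability_lrt", "heritability_relrt", "note"])
    lines = ["\t".join(cols)]
    for r in records:
        row = [r.set_name, str(r.m_total), str(r.m_rare)]
        row += [format_p(r.p_values.get(m)) for m in methods]
        row += [repr(float(r.lambda_lrt)) if r.lambda_lrt is not None else "NA",
                repr(float(r.lambda_relrt)) if r.lambda_relrt is not None else "NA",
                format_lambda(r.lambda_lrt), format_lambda(r.lambda_relrt),
                format_p(r.heritability_lrt) if r.heritability_lrt is not None else "NA",
                format_p(r.heritability_relrt) if r.heritability_relrt is not None else "NA",
                r.note or ("ok" if r.testable else "not_testable")]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
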