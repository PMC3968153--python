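"""MAF-based variant weights, kernel construction and the null projector.

The recommended per-variant weight is the Beta(1, 25) density evaluated at
the variant's MAF, w_j = 25 (1 - MAF_j)^24, which up-weights rarer variants.
Weights are rescaled by their maximum (per tested set, after the rare-variant
filter) so that max_j w_j = 1; this keeps the variance-ratio parameter of the
mixed model on a numerically benign scale.  The squared scaled weights form
the diagonal W of the random-effect covariance tau * W, and the weighted
linear kernel K = G W G' is the sample-by-sample covariance the kernel
formulation shares with the mixed-model one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import GenotypeMatrix

PSD_CLAMP_REL = 1e-10  # eigenvalues below this times the largest are zeroed


@dataclass
class WeightVector:
    """Beta(MAF; 1, 25) weights and their max-scaled version."""

    raw: np.ndarray
    scaled: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.scaled = np.asarray(self.scaled, dtype=float)
        if self.raw.shape != self.scaled.shape:
            raise ValueError("raw/scaled length mismatch")
        if np.any(self.scaled <= 0) or np.any(self.scaled > 1 + 1e-12):
            raise ValueError("scaled weights must lie in (0, 1]")
        if abs(self.scaled.max() - 1.0) > 1e-12:
            raise ValueError("max scaled weight must equal 1")

    def __len__(self) -> int:
        return len(self.raw)


@dataclass
class KernelMatrix:
    """Symmetric PSD n x n genomic-similarity matrix."""

    values: np.ndarray
    kind: str = "linear.weighted"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel must be symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NullProjection:
    """Residual projector off the column space of [1, X]."""

    X_design: np.ndarray   # n x (p+1), first column all ones
    P0: np.ndarray         # n x n symmetric idempotent
    rank: int              # p + 1
    Q: np.ndarray          # n x (p+1) orthonormal basis of the design space

    @property
    def n(self) -> int:
        return self.X_design.shape[0]

    def apply(self, v: np.ndarray) -> np.ndarray:
        """P0 @ v without forming the n x n product (v may be a matrix)."""
        return v - self.Q @ (self.Q.T @ v)


def beta_maf_weights(maf: np.ndarray) -> WeightVector:
    """Beta(1, 25) density weights, max-scaled.

    raw_j = 25 (1 - maf_j)^24; scaled_j = raw_j / max(raw).  Requires
    0 < maf < 1 (the density is zero or undefined otherwise).
    """
    maf = np.asarray(maf, dtype=float)
    if maf.size == 0:
        raise ValueError("empty MAF vector")
    if np.any(maf <= 0) or np.any(maf >= 1):
        raise ValueError("MAF must lie strictly in (0, 1) for Beta weights")
    raw = stats.beta.pdf(maf, 1, 25)
    return WeightVector(raw=raw, scaled=raw / raw.max())


def clamp_psd(values: np.ndarray, rel_tol: float = PSD_CLAMP_REL) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by zeroing eigenvalues
    below ``rel_tol`` times the largest; errors if any eigenvalue is more
    negative than float noise allows."""
    values = 0.5 * (values + values.T)
    evals, evecs = np.linalg.eigh(values)
    top = max(evals[-1], 0.0)
    if evals[0] < -1e-8 * max(top, 1.0):
        raise ValueError("matrix is not positive semi-definite")
    evals = np.where(evals < rel_tol * max(top, 1.0), 0.0, evals)
    return (evecs * evals) @ evecs.T


def weighted_linear_kernel(g: GenotypeMatrix, w: WeightVector) -> KernelMatrix:
    """K = G W G' with W = diag(scaled_j^2); PSD by construction."""
    if len(w) != g.n_variants:
        raise ValueError("weight/variant dimension mismatch")
    A = g.counts * w.scaled  # n x m, columns scaled by w_j
    K = A @ A.T
    return KernelMatrix(values=0.5 * (K + K.T), kind="linear.weighted")


def make_kernel(g: GenotypeMatrix, w: WeightVector, kind: str = "linear.weighted",
                **params) -> KernelMatrix:
    """Kernel factory.  Only ``linear.weighted`` participates in the
    validated mixed-model/kernel equivalences; the remaining kinds are
    experimental conveniences behind the same interface."""
    if kind == "linear.weighted":
        return weighted_linear_kernel(g, w)
    if kind == "linear":
        K = g.counts @ g.counts.T
        return KernelMatrix(values=0.5 * (K + K.T), kind=kind)
    if kind == "IBS.weighted":
        W = w.scaled ** 2
        n = g.n_samples
        K = np.empty((n, n))
        for i in range(n):
            diff = np.abs(g.counts[i] - g.counts)  # n x m
            K[i] = ((2.0 - diff) * W).sum(axis=1) / (2.0 * W.sum())
        return KernelMatrix(values=clamp_psd(K), kind=kind)
    if kind == "gaussian":
        bw = params.get("bandwidth", float(g.n_variants))
        A = g.counts * w.scaled
        sq = (A ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2 * A @ A.T
        return KernelMatrix(values=clamp_psd(np.exp(-np.maximum(d2, 0) / bw)), kind=kind)
    if kind == "polynomial":
        degree = params.get("degree", 2)
        A = g.counts * w.scaled
        return KernelMatrix(values=clamp_psd((1.0 + A @ A.T) ** degree), kind=kind)
    raise ValueError(f"unknown kernel kind {kind!r}")


def kernel_sqrt(k: KernelMatrix) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition (negative noise
    eigenvalues clamped to zero)."""
    evals, evecs = np.linalg.eigh(k.values)
    top = max(evals[-1], 0.0)
    if evals[0] < -1e-8 * max(top, 1.0):
        raise ValueError("kernel is not PSD")
    evals = np.clip(evals, 0.0, None)
    return (evecs * np.sqrt(evals)) @ evecs.T


def null_projection(X: np.ndarray | None, n: int | None = None) -> NullProjection:
    """Build P0 = I - Xd (Xd'Xd)^-1 Xd' for the design Xd = [1, X].

    Raises on rank deficiency, naming the offending design columns.
    """
    if X is None or (hasattr(X, "size") and X.size == 0):
        if n is None:
            raise ValueError("need n when X is empty")
        Xd = np.ones((n, 1))
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        n = X.shape[0]
        Xd = np.column_stack([np.ones(n), X])
    from scipy.linalg import qr

    Qfull, R, piv = qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xd.shape) * np.finfo(float).eps
    bad = [int(piv[i]) for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        names = ["intercept" if j == 0 else f"covariate {j}" for j in sorted(bad)]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {names}")
    Q = Qfull
    P0 = np.eye(n) - Q @ Q.T
    return NullProjection(X_design=Xd, P0=0.5 * (P0 + P0.T), rank=Xd.shape[1], Q=Q)
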