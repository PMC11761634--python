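"""Fréchet Protein Distance (FPD) on structure embeddings.

Two embedding clouds are each summarized by their first two moments
(μ, Σ) and compared with the Fréchet (2-Wasserstein²) distance between the
corresponding Gaussians:

    FPD = ||μ_data − μ_sample||² + Tr(Σ_data + Σ_sample − 2 (Σ_data Σ_sample)^{1/2})

Lower is a better distributional match. Stratifying the sample cloud by
designability yields FPD-D (designable rows only) and FPD-ND (undesignable
rows), whose difference — the FPD gap — separates genuine coverage of the
reference distribution from excursions into non-natural structure space.
A subsample-convergence diagnostic quantifies how many samples suffice to
estimate the full-set FPD.

The matrix square root is evaluated on the symmetrized product
Σa^{1/2} Σb Σa^{1/2} (same trace as (Σa Σb)^{1/2}, numerically stable) via
eigendecomposition, with tiny negative eigenvalues clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .embed import EmbeddingMatrix

#: eigenvalues more negative than -EIG_TOL * λmax abort with a numerical
#: error; anything between that and zero is clamped
EIG_TOL = 1e-8


@dataclass
class GaussianSummary:
    """First two moments of an embedding cloud."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.n < 2:
            raise ValueError("a summary needs n >= 2 rows")
        scale = max(np.abs(self.covariance).max(), 1e-300)
        if np.abs(self.covariance - self.covariance.T).max() > 1e-9 * scale:
            raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class FpdReport:
    """FPD over all samples plus the designability-stratified variants.
    ``fpd_d`` / ``fpd_nd`` are None when the stratum is too small; the gap
    is fpd_d − fpd_nd when both exist."""

    fpd: float
    fpd_d: float | None = None
    fpd_nd: float | None = None
    gap: float | None = None
    n_designable: int = 0
    n_undesignable: int = 0


def summarize(e: EmbeddingMatrix | np.ndarray) -> GaussianSummary:
    """Column mean and unbiased (n−1) covariance of an embedding matrix,
    symmetrized."""
    values = e.values if isinstance(e, EmbeddingMatrix) else np.asarray(e, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    mean = values.mean(axis=0)
    cov = np.cov(values, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    cov = 0.5 * (cov + cov.T)
    return GaussianSummary(mean=mean, covariance=cov, n=values.shape[0])


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    lam_max = max(w.max(), 0.0)
    if w.min() < -EIG_TOL * max(lam_max, 1e-300):
        raise FloatingPointError(
            f"matrix not PSD within tolerance: min eigenvalue {w.min():.3e}, "
            f"max {lam_max:.3e}"
        )
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def fpd(a: GaussianSummary, b: GaussianSummary) -> float:
    """Fréchet distance between two Gaussian summaries (see module docs).

    Symmetric in its arguments within 1e-8; results within numerical noise
    below zero are clamped to 0.
    """
    if a.dim != b.dim:
        raise ValueError("dimension mismatch")
    dmu = a.mean - b.mean
    sa_half = _psd_sqrt(a.covariance)
    inner = sa_half @ b.covariance @ sa_half
    inner = 0.5 * (inner + inner.T)
    w = np.linalg.eigh(inner)[0]
    lam_max = max(w.max(), 0.0)
    if w.min() < -EIG_TOL * max(lam_max, 1e-300):
        raise FloatingPointError(
            f"cross term not PSD within tolerance: min eigenvalue {w.min():.3e}"
        )
    trace_cross = np.sqrt(np.clip(w, 0.0, None)).sum()
    val = float(
        dmu @ dmu + np.trace(a.covariance) + np.trace(b.covariance) - 2.0 * trace_cross
    )
    return max(val, 0.0)


def ridge_regularize(s: GaussianSummary, epsilon_scale: float = 1e-6) -> GaussianSummary:
    """Optional ridge for n close to d: add ε·I with ε = scale·trace/d."""
    d = s.dim
    eps = epsilon_scale * np.trace(s.covariance) / d
    return GaussianSummary(mean=s.mean, covariance=s.covariance + eps * np.eye(d), n=s.n)


def fpd_stratified(reference: EmbeddingMatrix, sample: EmbeddingMatrix) -> FpdReport:
    """FPD of the full sample set plus FPD-D / FPD-ND over the designable /
    undesignable strata, all against the same reference summary.

    A stratum with fewer than d+1 rows yields no value for its field (with
    a warning); the gap requires both strata.
    """
    ref_sum = summarize(reference)
    total = fpd(ref_sum, summarize(sample))
    report = FpdReport(fpd=total)
    if sample.designable is None:
        return report
    d = sample.dim
    flags = sample.designable
    report.n_designable = int(flags.sum())
    report.n_undesignable = int((~flags).sum())
    strata = {}
    for name, mask, count in (
        ("fpd_d", flags, report.n_designable),
        ("fpd_nd", ~flags, report.n_undesignable),
    ):
        if count >= d + 1:
            strata[name] = fpd(ref_sum, summarize(sample.subset(mask)))
        elif count > 0:
            warnings.warn(
                f"stratum for {name} has only {count} rows (< d+1 = {d + 1}); omitted",
                stacklevel=2,
            )
    report.fpd_d = strata.get("fpd_d")
    report.fpd_nd = strata.get("fpd_nd")
    if report.fpd_d is not None and report.fpd_nd is not None:
        report.gap = report.fpd_d - report.fpd_nd
    return report


def subsample_convergence(
    reference: EmbeddingMatrix,
    sample: EmbeddingMatrix,
    sizes: list[int],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """FPD of seeded without-replacement subsamples of the sample cloud
    against the full reference, per subsample size.

    Returns a table (size, mean_fpd, std_fpd, reps); the estimator's
    stability over sizes shows how few samples suffice to approximate the
    full-set distance.
    """
    if reps < 2:
        raise ValueError("need reps >= 2")
    for size in sizes:
        if size > sample.n:
            raise ValueError(f"subsample size {size} exceeds {sample.n} rows")
    ref_sum = summarize(reference)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        vals = []
        for _ in range(reps):
            idx = rng.choice(sample.n, size=size, replace=False)
            vals.append(fpd(ref_sum, summarize(sample.values[idx])))
        vals = np.array(vals)
        rows.append(
            {
                "size": size,
                "mean_fpd": vals.mean(),
                "std_fpd": vals.std(ddof=1),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
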