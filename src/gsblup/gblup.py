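"""GBLUP / RR-BLUP engine.

The model is y = mu + g + e with g ~ N(0, K sigma_g^2) and
e ~ N(0, I sigma_e^2), where K is the realized additive relationship
matrix computed from centered marker dosages (VanRaden centering:
W = M - 2p, c = 2 sum_j p_j (1 - p_j), K = W W' / c).  Variance
components are estimated by REML, parameterized by the ratio
lambda = sigma_e^2 / sigma_g^2 and profiled through one spectral
decomposition of K restricted to the orthogonal complement of the
intercept, so each likelihood evaluation is O(n).  GEBVs are
g_hat = K (K + lambda I)^-1 (y - mu 1); marker effects are recovered by
the ridge back-solve u_hat = W' alpha / c with alpha the BLUP dual
coefficients, which reproduces W u_hat = g_hat exactly.

Narrow-sense heritability is h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2);
with adjusted genotype means as y it is on the entry-mean scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh, qr

from ._errors import AlignmentError, ConvergenceError, DegenerateGenotypesError
from .io_formats import GenotypeMatrix, dosage_0_2
from .pheno_prep import AdjustedPhenotypes

LOG_LAMBDA_BOUNDS = (-20.0, 20.0)
_EIG_CLIP = 1e-10


@dataclass
class KinshipMatrix:
    """Realized additive relationship matrix with its centering metadata.

    ``centering_frequencies`` (marker -> p on the [0, 2] scale) and the
    scale constant c pin the coordinate system marker effects and
    candidate predictions live in; monomorphic markers are excluded.
    """

    individual_ids: list[str]
    K: np.ndarray
    centering_frequencies: dict[str, float]
    scale_constant: float

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.individual_ids)
        if self.K.shape != (n, n):
            raise ValueError("kinship matrix shape does not match individual ids")
        if not np.isfinite(self.K).all():
            raise ValueError("kinship matrix has non-finite entries")
        asym = np.abs(self.K - self.K.T).max()
        if asym > 1e-10:
            raise ValueError(f"kinship matrix asymmetric (max |K-K'| = {asym:g})")
        if self.scale_constant <= 0:
            raise ValueError("kinship scale constant must be positive")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.centering_frequencies)

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        index = {name: i for i, name in enumerate(self.individual_ids)}
        rows = [index[i] for i in ids]
        return KinshipMatrix(
            list(ids), self.K[np.ix_(rows, rows)].copy(),
            dict(self.centering_frequencies), self.scale_constant,
        )


@dataclass
class ModelFit:
    """Fitted GBLUP model: variance components, GEBVs and diagnostics.

    ``residuals`` satisfy y = mu + gebv + residual per individual, and
    h2 = sigma_g2 / (sigma_g2 + sigma_e2) by construction.  ``boundary``
    flags an optimum at the edge of the lambda search interval.
    """

    mu: float
    sigma_g2: float
    sigma_e2: float
    lam: float
    gebvs: dict[str, float]
    residuals: dict[str, float]
    h2: float
    reml_loglik: float
    boundary: bool = False
    # BLUP dual coefficients alpha = (K + lam I)^-1 (y - mu 1), aligned with
    # individual_ids; needed for the marker-effect back-solve.
    individual_ids: list[str] = field(default_factory=list)
    alpha: np.ndarray | None = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma_g2": self.sigma_g2,
            "sigma_e2": self.sigma_e2,
            "lambda": self.lam if math.isfinite(self.lam) else "inf",
            "h2": self.h2,
            "reml_loglik": self.reml_loglik,
            "boundary": self.boundary,
            "n_individuals": len(self.gebvs),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class MarkerEffects:
    """Additive effect per (polymorphic, model) marker plus the training
    centering frequencies needed to score new individuals."""

    effects: dict[str, float]
    centering_frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.effects) != set(self.centering_frequencies):
            raise ValueError("effects and centering frequencies name different markers")
        if not all(math.isfinite(v) for v in self.effects.values()):
            raise ValueError("non-finite marker effect")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": list(self.effects), "effect": list(self.effects.values())}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def kinship_matrix(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden realized relationship matrix K = W W' / c.

    Dosages are taken on the [0, 2] scale; each polymorphic marker is
    centered by twice its sample frequency and the cross-product is scaled
    by c = 2 sum p(1-p).  Requires a complete (imputed) matrix.
    """
    if g.has_missing():
        raise ValueError("kinship requires a complete matrix; impute first")
    if g.n_individuals < 2:
        raise ValueError("kinship requires at least 2 individuals")
    M = dosage_0_2(g)
    poly = np.ptp(M, axis=0) > 1e-12
    if not poly.any():
        raise DegenerateGenotypesError("all markers are monomorphic")
    p = M[:, poly].mean(axis=0) / 2.0
    W = M[:, poly] - 2.0 * p
    c = float(2.0 * np.sum(p * (1.0 - p)))
    K = (W @ W.T) / c
    K = (K + K.T) / 2.0  # symmetrize away rounding noise
    freqs = {
        m: float(pj) for m, pj in zip(np.asarray(g.marker_ids)[poly], p)
    }
    return KinshipMatrix(list(g.individual_ids), K, freqs, c)


def centered_dosages(
    g: GenotypeMatrix, centering_frequencies: dict[str, float]
) -> np.ndarray:
    """Dosages centered by 2p for the given (training) frequencies, columns
    in the order of ``centering_frequencies``; markers absent from g error."""
    sub = g.subset_markers(list(centering_frequencies))
    M = dosage_0_2(sub)
    p = np.array([centering_frequencies[m] for m in sub.marker_ids])
    return M - 2.0 * p


# ---------------------------------------------------------------------------
# spectral REML
# ---------------------------------------------------------------------------

def _intercept_complement(n: int) -> np.ndarray:
    """Orthonormal basis (n x n-1) of the complement of the 1 vector."""
    A = np.hstack([np.full((n, 1), 1.0 / math.sqrt(n)), np.eye(n)[:, : n - 1]])
    Q, _ = qr(A, mode="economic")
    # first column of Q spans 1; the rest span its complement
    return Q[:, 1:]


def project_spectrum(K: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues xi of K restricted to the intercept's orthogonal
    complement, and the rotated data eta = U' y (both length n-1).

    Small negative eigenvalues (numerical PSD noise, > -1e-10 relative)
    are clipped to zero.
    """
    n = K.shape[0]
    U0 = _intercept_complement(n)
    A = U0.T @ K @ U0
    xi, V = eigh((A + A.T) / 2.0)
    scale = max(xi.max(), 1.0)
    xi = np.where(xi > -_EIG_CLIP * scale, np.maximum(xi, 0.0), xi)
    if xi.min() < 0:
        raise ValueError(f"kinship not PSD (eigenvalue {xi.min():g})")
    eta = V.T @ (U0.T @ y)
    return xi, eta


def restricted_log_likelihood(
    lam: float, eigenvalues: np.ndarray, rotated_y: np.ndarray
) -> float:
    """Profiled restricted log-likelihood of the variance ratio lambda.

    l_R(lambda) = -1/2 [ (n-1) ln(2 pi sigma_g^2) + sum_i ln(xi_i + lambda)
    + (n-1) ] with sigma_g^2 = mean_i eta_i^2 / (xi_i + lambda) profiled
    out; eigenvalues/rotated_y come from :func:`project_spectrum`.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    xi = np.asarray(eigenvalues, dtype=float)
    eta = np.asarray(rotated_y, dtype=float)
    nm1 = xi.size
    denom = xi + lam
    sigma_g2 = float(np.sum(eta ** 2 / denom) / nm1)
    sigma_g2 = max(sigma_g2, 1e-300)
    return -0.5 * (
        nm1 * math.log(2.0 * math.pi * sigma_g2)
        + float(np.log(denom).sum())
        + nm1
    )


def _align(y: AdjustedPhenotypes, K: KinshipMatrix) -> tuple[list[str], np.ndarray, KinshipMatrix]:
    kin_ids = set(K.individual_ids)
    missing = [g for g in y.values if g not in kin_ids]
    if missing:
        raise AlignmentError(
            f"{len(missing)} phenotyped individuals absent from kinship "
            f"(e.g. {missing[:3]})"
        )
    ids = [i for i in K.individual_ids if i in y.values]
    return ids, np.array([y.values[i] for i in ids]), K.subset(ids)


def fit_gblup(y: AdjustedPhenotypes, K: KinshipMatrix) -> ModelFit:
    """Fit the GBLUP model by spectral REML.

    The restricted likelihood is maximized over ln lambda in [-20, 20] by
    bounded 1-D optimization (tolerance 1e-8); a boundary optimum is
    flagged with a warning rather than an error.  Returns variance
    components, the GLS mean, GEBVs, residuals and h^2.
    """
    ids, yv, Ksub = _align(y, K)
    n = len(ids)
    if n < 3:
        raise AlignmentError("GBLUP needs at least 3 phenotyped individuals in K")
    xi, eta = project_spectrum(Ksub.K, yv)

    neg = lambda t: -restricted_log_likelihood(math.exp(t), xi, eta)
    res = optimize.minimize_scalar(
        neg, bounds=LOG_LAMBDA_BOUNDS, method="bounded", options={"xatol": 1e-8}
    )
    if not res.success or not math.isfinite(res.fun):
        raise ConvergenceError("REML optimization of lambda failed")
    # the bounded optimizer never evaluates the endpoints themselves; when
    # the profile is monotone the true optimum sits exactly on a bound
    log_lam = float(res.x)
    for bound in LOG_LAMBDA_BOUNDS:
        if neg(bound) < neg(log_lam):
            log_lam = bound
    lam = math.exp(log_lam)
    boundary = (
        log_lam <= LOG_LAMBDA_BOUNDS[0] + 1e-4
        or log_lam >= LOG_LAMBDA_BOUNDS[1] - 1e-4
    )
    if boundary:
        warnings.warn(
            f"REML optimum at the boundary (ln lambda = {log_lam:.2f}); "
            "variance components are at the edge of the search interval",
            stacklevel=2,
        )
    loglik = -neg(log_lam)
    nm1 = n - 1
    sigma_g2 = float(np.sum(eta ** 2 / (xi + lam)) / nm1)
    sigma_e2 = lam * sigma_g2
    h2 = sigma_g2 / (sigma_g2 + sigma_e2)

    c, low = cho_factor(Ksub.K + lam * np.eye(n), lower=True)
    Vi1 = cho_solve((c, low), np.ones(n))
    mu = float(Vi1 @ yv) / float(Vi1.sum())
    alpha = cho_solve((c, low), yv - mu)
    gebv = Ksub.K @ alpha
    resid = yv - mu - gebv

    return ModelFit(
        mu=mu,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        lam=lam,
        gebvs={i: float(v) for i, v in zip(ids, gebv)},
        residuals={i: float(v) for i, v in zip(ids, resid)},
        h2=h2,
        reml_loglik=loglik,
        boundary=boundary,
        individual_ids=ids,
        alpha=alpha,
    )


def marker_effects(
    fit: ModelFit, g: GenotypeMatrix, K: KinshipMatrix
) -> MarkerEffects:
    """Ridge back-solve of per-marker additive effects.

    u_hat = W' (K + lambda I)^-1 (y - mu 1) / c with W, c and centering
    frequencies exactly as in the kinship construction, so that
    W u_hat = g_hat.  Monomorphic (excluded) markers get no effect.
    """
    if not K.centering_frequencies:
        raise ValueError("kinship carries no centering frequencies")
    if fit.alpha is None:
        raise ValueError("model fit carries no dual coefficients")
    sub = g.subset_individuals(fit.individual_ids)
    W = centered_dosages(sub, K.centering_frequencies)
    u = (W.T @ fit.alpha) / K.scale_constant
    effects = {m: float(e) for m, e in zip(K.marker_ids, u)}
    return MarkerEffects(effects, dict(K.centering_frequencies))
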