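"""Phenotype preprocessing: from plot-level observations to one value per
genotype per trait.

For replicated field designs (RCBD, alpha lattice, augmented) a linear
mixed model is fitted by REML with genotype as a fixed effect and
replications and/or incomplete blocks as random intercepts; the adjusted
value is the estimated genotype mean on the phenotype scale.  When no
design information is available, the arithmetic mean of the non-missing
observations is used.  Values from multiple trials are averaged,
unweighted, over the trials in which each genotype appears.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from ._errors import ConvergenceError, FormatError, InsufficientDataError
from .io_formats import Design, PhenotypeTable

_MISSING_LEVEL = "__missing__"


class AdjustMethod(enum.Enum):
    REML_FIXED_EFFECT = "REML_FIXED_EFFECT"
    ARITHMETIC_MEAN = "ARITHMETIC_MEAN"
    CROSS_TRIAL_AVERAGE = "CROSS_TRIAL_AVERAGE"


@dataclass
class AdjustedPhenotypes:
    """One finite phenotype value per genotype for a single trait (the
    mixed model's y); genotypes with no usable observation are absent."""

    trait: str
    values: dict[str, float]
    method: AdjustMethod
    source_trials: list[str]

    def __post_init__(self) -> None:
        if not self.values:
            raise InsufficientDataError(
                f"no adjusted values for trait {self.trait!r}"
            )
        for g, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite adjusted value for genotype {g!r}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.trait, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genotype": g, "value": v, "method": self.method.value,
             "trials": ";".join(self.source_trials)}
            for g, v in self.values.items()
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# restricted likelihood for the adjustment model
# ---------------------------------------------------------------------------

def _restricted_loglik_and_means(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    log_thetas: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Profiled restricted log-likelihood of y = X b + sum_k Z_k u_k + e.

    theta_k = sigma_k^2 / sigma_e^2 are the variance ratios; the error
    variance is profiled out.  Returns (l_R, GLS genotype means).
    """
    n, p = X.shape
    V = np.eye(n)
    for Z, lt in zip(Z_list, log_thetas):
        V += math.exp(lt) * (Z @ Z.T)
    c, low = cho_factor(V, lower=True)
    ViX = cho_solve((c, low), X)
    Viy = cho_solve((c, low), y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    resid = y - X @ beta
    quad = float(resid @ cho_solve((c, low), resid))
    sigma_e2 = max(quad / (n - p), 1e-30)
    logdet_V = 2.0 * float(np.log(np.diag(c)).sum())
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise ConvergenceError("singular fixed-effect information matrix")
    ll = -0.5 * ((n - p) * math.log(sigma_e2) + logdet_V + logdet_XtViX)
    return ll, beta


def _fit_adjustment_model(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    label: str,
) -> np.ndarray:
    """Maximize the restricted likelihood over log variance ratios in
    [-12, 12] per component and return the GLS genotype means."""
    k = len(Z_list)

    def neg(lts: np.ndarray) -> float:
        ll, _ = _restricted_loglik_and_means(y, X, Z_list, np.atleast_1d(lts))
        return -ll

    if k == 1:
        res = optimize.minimize_scalar(
            lambda t: neg(np.array([t])), bounds=(-12.0, 12.0),
            method="bounded", options={"xatol": 1e-8},
        )
        opt = np.array([res.x])
        ok = res.success
    else:
        res = optimize.minimize(
            neg, x0=np.zeros(k), method="Powell",
            bounds=[(-12.0, 12.0)] * k, options={"xtol": 1e-8, "ftol": 1e-10},
        )
        opt = np.atleast_1d(res.x)
        ok = res.success
    ll, beta = _restricted_loglik_and_means(y, X, Z_list, opt)
    if not ok or not math.isfinite(ll) or not np.isfinite(beta).all():
        raise ConvergenceError(f"REML adjustment did not converge for {label}")
    return beta


def _indicator(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str), dtype=float).to_numpy()


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def adjust_single_trial(
    p: PhenotypeTable, trait: str, trial: str
) -> AdjustedPhenotypes:
    """Reduce one trial's plot observations of one trait to per-genotype
    adjusted values.

    Designed trials are fitted by REML (genotype fixed; replication and/or
    block — block nested in replication when both are recorded — as random
    intercepts) and the estimated genotype means are returned.  Trials with
    design UNKNOWN or no replication/block information fall back to the
    arithmetic mean.  Rows with a missing trait value are dropped first;
    genotypes left without observations are omitted.
    """
    if trait not in p.trait_names:
        raise FormatError(
            f"trait {trait!r} not in phenotype table; available: {p.trait_names}"
        )
    df = p.data[p.data["trial"].astype(str) == str(trial)]
    if df.empty:
        raise FormatError(
            f"trial {trial!r} not in phenotype table; available: {p.trial_ids}"
        )
    design: Design = df["design"].iloc[0]
    df = df[df[trait].notna()].copy()
    genotypes = df["genotype"].astype(str)
    if genotypes.nunique() < 2:
        raise InsufficientDataError(
            f"trial {trial!r}, trait {trait!r}: fewer than 2 genotypes with data"
        )

    rep_avail = df["replication"].notna().any()
    block_avail = df["block"].notna().any()
    use_mixed = design is not Design.UNKNOWN and (rep_avail or block_avail)

    if use_mixed:
        y = df[trait].to_numpy(dtype=float)
        geno_levels = pd.unique(genotypes)
        X = pd.get_dummies(
            pd.Categorical(genotypes, categories=geno_levels), dtype=float
        ).to_numpy()
        if len(y) - len(geno_levels) < 1:
            warnings.warn(
                f"trial {trial!r}, trait {trait!r}: no residual degrees of "
                "freedom for a mixed model; using arithmetic means",
                stacklevel=2,
            )
            use_mixed = False
        else:
            Z_list: list[np.ndarray] = []
            if rep_avail:
                Z_list.append(_indicator(df["replication"].fillna(_MISSING_LEVEL)))
            if block_avail:
                blk = df["block"].fillna(_MISSING_LEVEL).astype(str)
                if rep_avail:  # blocks nested within replications
                    blk = df["replication"].fillna(_MISSING_LEVEL).astype(str) + ":" + blk
                Z_list.append(_indicator(blk))
            beta = _fit_adjustment_model(
                y, X, Z_list, f"trial {trial!r} / trait {trait!r}"
            )
            values = {str(g): float(b) for g, b in zip(geno_levels, beta)}
            return AdjustedPhenotypes(
                trait, values, AdjustMethod.REML_FIXED_EFFECT, [str(trial)]
            )

    means = df.groupby(genotypes)[trait].mean()
    values = {str(g): float(v) for g, v in means.items()}
    return AdjustedPhenotypes(
        trait, values, AdjustMethod.ARITHMETIC_MEAN, [str(trial)]
    )


def combine_trials(parts: list[AdjustedPhenotypes]) -> AdjustedPhenotypes:
    """Average per-genotype adjusted values across trials (unweighted, over
    the trials where each genotype has a value)."""
    if not parts:
        raise InsufficientDataError("combine_trials: empty input")
    trait = parts[0].trait
    for part in parts[1:]:
        if part.trait != trait:
            raise FormatError(
                f"combine_trials: mixed traits {trait!r} and {part.trait!r}"
            )
    acc: dict[str, list[float]] = {}
    trials: list[str] = []
    for part in parts:
        for t in part.source_trials:
            if t not in trials:
                trials.append(t)
        for g, v in part.values.items():
            acc.setdefault(g, []).append(v)
    values = {g: float(np.mean(vs)) for g, vs in acc.items()}
    return AdjustedPhenotypes(trait, values, AdjustMethod.CROSS_TRIAL_AVERAGE, trials)


def common_traits(tables: list[PhenotypeTable]) -> list[str]:
    """Traits with at least one non-missing value in every table, sorted."""
    if not tables:
        raise FormatError("common_traits: empty input")
    common: set[str] | None = None
    for table in tables:
        present = {
            t for t in table.trait_names if table.data[t].notna().any()
        }
        common = present if common is None else common & present
    return sorted(common or set())
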