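"""Model evaluation: k-fold cross-validation of prediction accuracy,
phenotypic trait correlations and descriptive statistics.

Accuracy is the mean Pearson correlation, over folds, between predicted
GEBVs and the observed (adjusted) phenotypes of held-out individuals.
Each fold refits the whole pipeline on the training folds only —
including the kinship centering frequencies and scale constant — so no
information leaks from the validation set into the model.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import AlignmentError, FoldSizeError
from .gblup import centered_dosages, fit_gblup, kinship_matrix, marker_effects
from .io_formats import GenotypeMatrix
from .pheno_prep import AdjustedPhenotypes


@dataclass
class CVResult:
    """Outcome of one seeded k-fold cross-validation run.

    ``fold_correlations`` holds one Pearson r per fold (NaN where a fold's
    correlation was undefined); ``accuracy`` is the mean over the defined
    folds.
    """

    k: int
    seed: int
    fold_assignment: dict[str, int]
    fold_correlations: list[float]
    accuracy: float

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "fold_assignment": self.fold_assignment,
            "fold_correlations": [
                None if math.isnan(r) else r for r in self.fold_correlations
            ],
            "accuracy": self.accuracy,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations between traits."""

    trait_names: list[str]
    r: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.trait_names, columns=self.trait_names)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "trait"
        df.to_csv(path, sep="\t", na_rep="NA")


def _partition(ids: list[str], k: int, seed: int) -> dict[str, int]:
    """Seeded near-equal partition: fold sizes differ by at most 1, the
    n mod k larger folds determined by the shuffle."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment: dict[str, int] = {}
    base, extra = divmod(len(ids), k)
    start = 0
    for f in range(1, k + 1):
        size = base + (1 if f <= extra else 0)
        for idx in order[start : start + size]:
            assignment[ids[idx]] = f
        start += size
    return assignment


def k_fold_cross_validate(
    y: AdjustedPhenotypes,
    g: GenotypeMatrix,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Estimate prediction accuracy by seeded k-fold cross-validation.

    Individuals are randomly split into k near-equal folds.  For each
    fold, kinship, REML variance components and marker effects are fit on
    the other folds only; held-out GEBVs are predicted via the marker
    effects (with training-derived centering frequencies) and correlated
    with the held-out adjusted phenotypes.  Folds with zero variance on
    either side are recorded as NaN and excluded from the mean, with a
    warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if g.has_missing():
        raise ValueError("cross-validation requires a complete (imputed) matrix")
    geno_ids = set(g.individual_ids)
    missing = [i for i in y.values if i not in geno_ids]
    if missing:
        raise AlignmentError(
            f"{len(missing)} phenotyped individuals have no genotypes "
            f"(e.g. {missing[:3]})"
        )
    ids = [i for i in g.individual_ids if i in y.values]
    n = len(ids)
    if n < 2 * k:
        raise FoldSizeError(f"n = {n} too small for k = {k} folds")
    if n // k < 3:
        raise FoldSizeError(
            f"folds of ~{n // k} individuals are too small (need >= 3); "
            "use a smaller k"
        )

    assignment = _partition(ids, k, seed)
    correlations: list[float] = []
    for fold in range(1, k + 1):
        test_ids = [i for i in ids if assignment[i] == fold]
        train_ids = [i for i in ids if assignment[i] != fold]
        g_train = g.subset_individuals(train_ids)
        y_train = AdjustedPhenotypes(
            y.trait, {i: y.values[i] for i in train_ids}, y.method, y.source_trials
        )
        K_train = kinship_matrix(g_train)
        fit = fit_gblup(y_train, K_train)
        eff = marker_effects(fit, g_train, K_train)
        W_test = centered_dosages(
            g.subset_individuals(test_ids), eff.centering_frequencies
        )
        pred = W_test @ np.array(list(eff.effects.values()))
        observed = np.array([y.values[i] for i in test_ids])
        if np.ptp(observed) < 1e-14 or np.ptp(pred) < 1e-14:
            warnings.warn(
                f"fold {fold}: zero variance in predictions or observations; "
                "correlation undefined and excluded from the accuracy",
                stacklevel=2,
            )
            correlations.append(float("nan"))
            continue
        r = float(stats.pearsonr(pred, observed).statistic)
        correlations.append(r)

    defined = [r for r in correlations if not math.isnan(r)]
    accuracy = float(np.mean(defined)) if defined else float("nan")
    return CVResult(k, seed, assignment, correlations, accuracy)


def trait_correlations(parts: list[AdjustedPhenotypes]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between per-trait adjusted
    phenotypes; pairs with fewer than 3 complete genotypes are NaN."""
    if len(parts) < 2:
        raise ValueError("need at least 2 traits for a correlation matrix")
    df = pd.DataFrame({p.trait: p.to_series() for p in parts})
    r = df.corr(method="pearson", min_periods=3)
    present = df.notna()
    n_pairs = (present.T.astype(int) @ present.astype(int)).to_numpy()
    rmat = r.to_numpy()
    np.fill_diagonal(rmat, 1.0)
    return CorrelationMatrix(list(df.columns), rmat, n_pairs)


def descriptive_stats(y: AdjustedPhenotypes) -> dict[str, float]:
    """count / mean / sd (n-1) / min / median / max of the adjusted values;
    sd is NaN for a single observation."""
    v = np.array(list(y.values.values()), dtype=float)
    return {
        "count": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        "min": float(v.min()),
        "median": float(np.median(v)),
        "max": float(v.max()),
    }
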