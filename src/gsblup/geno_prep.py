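"""Marker-data preparation: KNN imputation of missing dosages and
per-marker summary statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ImputationError, InsufficientDataError
from .io_formats import Encoding, GenotypeMatrix, dosage_0_2


@dataclass
class MarkerSummary:
    """Summary of one marker on the [0, 2] dosage scale.

    ``allele_frequency`` is the frequency of the counted allele (mean
    dosage / 2 over non-missing entries).
    """

    marker_id: str
    allele_frequency: float
    missing_rate: float
    monomorphic: bool


def _pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Overlap-corrected Euclidean distances between individuals.

    For a pair sharing s of the m markers the distance is the Euclidean
    distance over the shared markers scaled by sqrt(m / s), so sparse
    overlaps are not spuriously close; pairs sharing no marker get +inf.
    """
    n, m = X.shape
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)
    sq = X0 ** 2
    shared = obs.astype(float) @ obs.T  # pairwise overlap counts
    cross = sq @ obs.T
    d2 = cross + cross.T - 2.0 * (X0 @ X0.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(np.maximum(d2, 0.0) * m / shared)
    d[shared == 0] = np.inf
    np.fill_diagonal(d, np.inf)  # an individual is not its own neighbor
    return d


def knn_impute(g: GenotypeMatrix, k: int = 5) -> GenotypeMatrix:
    """Fill missing dosages from the k nearest individuals.

    Each missing cell (i, j) becomes the mean dosage at marker j among the
    k nearest neighbors of i that have data at j (neighbors missing at j
    are skipped in favor of the next nearest; ties broken by ascending row
    index).  If no reachable neighbor has data at j, the column mean is
    used.  Output is on the canonical [0, 2] scale with encoding
    CONTINUOUS; a matrix with no missing values is returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not g.has_missing():
        return g
    if g.n_individuals < 2:
        raise InsufficientDataError("KNN imputation needs at least 2 individuals")

    X = dosage_0_2(g)
    obs = ~np.isnan(X)
    all_missing = np.where(~obs.any(axis=0))[0]
    if all_missing.size:
        raise ImputationError(
            f"marker {g.marker_ids[all_missing[0]]!r} is missing in all individuals"
        )
    D = _pairwise_distances(X)
    isolated = np.where(np.isinf(D).all(axis=1))[0]
    if isolated.size:
        raise ImputationError(
            f"individual {g.individual_ids[isolated[0]]!r} shares no observed "
            "marker with any other individual"
        )

    col_means = np.nanmean(X, axis=0)
    out = X.copy()
    # stable argsort: equal distances resolve by ascending row index
    order = np.argsort(D, axis=1, kind="stable")
    for i in range(X.shape[0]):
        missing_js = np.where(~obs[i])[0]
        if missing_js.size == 0:
            continue
        reachable = order[i][np.isfinite(D[i, order[i]])]
        for j in missing_js:
            donors = reachable[obs[reachable, j]][:k]
            if donors.size:
                out[i, j] = X[donors, j].mean()
            else:
                out[i, j] = col_means[j]
    return GenotypeMatrix(
        list(g.individual_ids), list(g.marker_ids), out, Encoding.CONTINUOUS
    )


def marker_summaries(g: GenotypeMatrix) -> list[MarkerSummary]:
    """Allele frequency, missing rate and monomorphism flag per marker,
    computed on the [0, 2] scale."""
    X = dosage_0_2(g)
    n = X.shape[0]
    summaries = []
    for j, marker in enumerate(g.marker_ids):
        col = X[:, j]
        seen = col[~np.isnan(col)]
        missing_rate = 1.0 - seen.size / n
        if seen.size == 0:
            summaries.append(MarkerSummary(marker, float("nan"), 1.0, True))
            continue
        p = float(seen.mean() / 2.0)
        mono = bool(np.ptp(seen) < 1e-12)
        summaries.append(MarkerSummary(marker, p, missing_rate, mono))
    return summaries
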