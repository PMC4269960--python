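"""Scoring selection candidates and ranking by a multi-trait selection
index."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._errors import AlignmentError, IncompatiblePopulationsError
from .gblup import MarkerEffects, ModelFit
from .io_formats import GenotypeMatrix, dosage_0_2


@dataclass
class SelectionIndexResult:
    """Weighted sum of per-trait GEBVs per genotype, ranked descending."""

    weights: dict[str, float]
    index: dict[str, float]  # insertion order = descending index, ties by name
    traits_used: list[str]


def predict_candidates(
    fit: ModelFit,
    eff: MarkerEffects,
    cand: GenotypeMatrix,
) -> dict[str, float]:
    """GEBVs of genotyped-only selection candidates.

    Candidate dosages are centered with the *training* centering
    frequencies (the model's coordinate system) over the markers shared
    with the training set; GEBV = w . u_hat.  Effects of training markers
    the candidates lack are dropped, with a warning reporting the overlap;
    candidates never enter the training fit.  The candidate matrix must be
    complete (imputed).
    """
    if cand.has_missing():
        raise ValueError("candidate matrix has missing dosages; impute first")
    model_markers = list(eff.centering_frequencies)
    cand_set = set(cand.marker_ids)
    shared = [m for m in model_markers if m in cand_set]
    if not shared:
        raise IncompatiblePopulationsError(
            "candidates share no markers with the fitted model"
        )
    if len(shared) < len(model_markers):
        warnings.warn(
            f"candidates cover {len(shared)}/{len(model_markers)} model markers "
            f"(overlap {len(shared) / len(model_markers):.3f}); effects of the "
            "absent markers are dropped",
            stacklevel=2,
        )
    sub = cand.subset_markers(shared)
    M = dosage_0_2(sub)
    p = np.array([eff.centering_frequencies[m] for m in shared])
    u = np.array([eff.effects[m] for m in shared])
    gebv = (M - 2.0 * p) @ u
    return {i: float(v) for i, v in zip(cand.individual_ids, gebv)}


def selection_index(
    gebv_tables: dict[str, dict[str, float]],
    weights: dict[str, float],
    standardize: bool = False,
) -> SelectionIndexResult:
    """Rank genotypes by the weighted sum of their per-trait GEBVs.

    The index runs over the genotypes having a GEBV for every weighted
    trait.  ``standardize`` z-scores each trait's GEBVs (over that
    intersection) before weighting, for traits on incommensurable scales;
    the default is the raw weighted sum.
    """
    if not weights:
        raise ValueError("selection index needs at least one trait weight")
    missing = [t for t in weights if t not in gebv_tables]
    if missing:
        raise AlignmentError(f"no GEBV table for weighted trait(s) {missing}")
    traits = list(weights)
    genotypes: set[str] | None = None
    for t in traits:
        s = set(gebv_tables[t])
        genotypes = s if genotypes is None else genotypes & s
    if not genotypes:
        raise AlignmentError(
            "no genotype has GEBVs for every weighted trait"
        )
    members = sorted(genotypes)
    columns = {}
    for t in traits:
        col = np.array([gebv_tables[t][g] for g in members], dtype=float)
        if standardize:
            sd = col.std(ddof=1)
            col = (col - col.mean()) / sd if sd > 0 else col - col.mean()
        columns[t] = col
    total = np.zeros(len(members))
    for t in traits:
        total += weights[t] * columns[t]
    ranked = sorted(zip(members, total), key=lambda kv: (-kv[1], kv[0]))
    return SelectionIndexResult(
        weights=dict(weights),
        index={g: float(v) for g, v in ranked},
        traits_used=traits,
    )
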