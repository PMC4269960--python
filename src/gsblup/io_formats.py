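"""File formats and core containers for genomic-selection data.

Genotypes are biallelic marker dosages, individuals x markers, read from
TSV with the missing token ``NA``.  Two integer encodings are accepted,
``[-1, 0, 1]`` and ``[0, 1, 2]``; continuous dosages (always on the
``[0, 2]`` scale) arise only from imputation.  Phenotypes are plot-level
CSV tables carrying field-trial design metadata (trial, genotype,
replication, block, design label) plus one column per trait.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import EncodingError, FormatError, IncompatiblePopulationsError

MISSING_TOKEN = "NA"


class Encoding(enum.Enum):
    MINUS1_0_1 = "MINUS1_0_1"
    ZERO_1_2 = "ZERO_1_2"
    CONTINUOUS = "CONTINUOUS"


class Design(enum.Enum):
    RCBD = "RCBD"
    ALPHA_LATTICE = "ALPHA_LATTICE"
    AUGMENTED = "AUGMENTED"
    UNKNOWN = "UNKNOWN"


_ALLOWED = {
    Encoding.MINUS1_0_1: (-1.0, 0.0, 1.0),
    Encoding.ZERO_1_2: (0.0, 1.0, 2.0),
}


def _check_unique(names: list[str], what: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise FormatError(f"duplicate {what} id: {n!r}")
        seen.add(n)


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with declared encoding.

    ``dosage`` is a float array; missing entries are NaN.  For the integer
    encodings every non-missing entry must be one of the allowed codes;
    CONTINUOUS entries (post-imputation) must lie within [0, 2].
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    encoding: Encoding

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = len(self.individual_ids), len(self.marker_ids)
        if n < 1 or m < 1:
            raise FormatError("genotype matrix needs at least 1 individual and 1 marker")
        if self.dosage.shape != (n, m):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match ids ({n}, {m})"
            )
        _check_unique(self.individual_ids, "individual")
        _check_unique(self.marker_ids, "marker")
        obs = self.dosage[~np.isnan(self.dosage)]
        if self.encoding is Encoding.CONTINUOUS:
            if obs.size and (obs.min() < -1e-9 or obs.max() > 2 + 1e-9):
                raise EncodingError("continuous dosages must lie within [0, 2]")
        else:
            allowed = _ALLOWED[self.encoding]
            if obs.size and not np.isin(obs, allowed).all():
                bad = obs[~np.isin(obs, allowed)][0]
                raise EncodingError(
                    f"dosage {bad} invalid for encoding {self.encoding.value}"
                )

    # -- convenience -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosage).any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.individual_ids, columns=self.marker_ids
        )

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        index = {name: i for i, name in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise FormatError(f"individuals not in genotype matrix: {missing[:5]}")
        rows = [index[i] for i in ids]
        return GenotypeMatrix(list(ids), list(self.marker_ids),
                              self.dosage[rows, :].copy(), self.encoding)

    def subset_markers(self, markers: list[str]) -> "GenotypeMatrix":
        index = {name: j for j, name in enumerate(self.marker_ids)}
        missing = [m for m in markers if m not in index]
        if missing:
            raise FormatError(f"markers not in genotype matrix: {missing[:5]}")
        cols = [index[m] for m in markers]
        return GenotypeMatrix(list(self.individual_ids), list(markers),
                              self.dosage[:, cols].copy(), self.encoding)


@dataclass
class PhenotypeTable:
    """Plot-level trait observations with trial-design metadata.

    ``data`` columns: trial, genotype, design (required), replication and
    block (optional, may be missing), plus one numeric column per trait.
    A (trial, genotype) pair may span multiple rows (replicated plots).
    """

    data: pd.DataFrame

    _META = ("trial", "genotype", "design", "replication", "block")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("trial", "genotype", "design"):
            if col not in df.columns:
                raise FormatError(f"phenotype table missing required column {col!r}")
        for col in ("replication", "block"):
            if col not in df.columns:
                df[col] = pd.NA
        df["design"] = df["design"].map(
            lambda d: d if isinstance(d, Design) else Design(str(d))
        )
        if not self.trait_names_of(df):
            raise FormatError("phenotype table has no trait columns")
        for t in self.trait_names_of(df):
            df[t] = pd.to_numeric(df[t], errors="raise")
        self.data = df

    @classmethod
    def trait_names_of(cls, df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c not in cls._META]

    @property
    def trait_names(self) -> list[str]:
        return self.trait_names_of(self.data)

    @property
    def trial_ids(self) -> list[str]:
        return list(pd.unique(self.data["trial"].astype(str)))


@dataclass
class IndividualList:
    """Named, ordered set of individual names (a custom list)."""

    name: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"individual list {self.name!r} is empty")
        _check_unique(self.members, "list member")


@dataclass
class MarkerMatchReport:
    n_train_markers: int
    n_candidate_markers: int
    n_shared: int
    overlap_fraction: float  # relative to the training marker set
    shared_markers: list[str] = field(repr=False, default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotype_matrix(path) -> GenotypeMatrix:
    """Read a genotype dosage TSV and auto-detect its encoding.

    The file has a header row ``id<TAB>marker1<TAB>...`` and one row per
    individual; cells are dosages or ``NA``.  Encoding is MINUS1_0_1 if
    any entry is -1, else ZERO_1_2; a file containing both -1 and 2 is
    rejected as inconsistent.  A {0,1}-only file is ambiguous and defaults
    to ZERO_1_2 with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING_TOKEN],
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected id column plus at least one marker")
    individual_ids = df.iloc[:, 0].astype(str).tolist()
    marker_ids = [str(c) for c in df.columns[1:]]
    _check_unique(individual_ids, "individual")
    _check_unique(marker_ids, "marker")

    cells = df.iloc[:, 1:].to_numpy(dtype=object)
    dosage = np.full(cells.shape, np.nan)
    valid = {"-1": -1.0, "0": 0.0, "1": 1.0, "2": 2.0,
             "−1": -1.0}  # tolerate the unicode minus
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            cell = cells[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            token = str(cell).strip()
            if token not in valid:
                raise FormatError(
                    f"{path}: invalid dosage {token!r} at row {individual_ids[i]!r}, "
                    f"column {marker_ids[j]!r} (allowed: -1, 0, 1, 2, NA)"
                )
            dosage[i, j] = valid[token]

    obs = dosage[~np.isnan(dosage)]
    has_minus1 = bool((obs == -1).any())
    has_two = bool((obs == 2).any())
    if has_minus1 and has_two:
        raise FormatError(
            f"{path}: inconsistent encoding — file contains both -1 and 2"
        )
    if has_minus1:
        encoding = Encoding.MINUS1_0_1
    else:
        if not has_two and obs.size:
            warnings.warn(
                f"{path}: dosages are all in {{0,1}}; encoding is ambiguous, "
                "assuming ZERO_1_2",
                stacklevel=2,
            )
        encoding = Encoding.ZERO_1_2
    return GenotypeMatrix(individual_ids, marker_ids, dosage, encoding)


def write_genotype_matrix(g: GenotypeMatrix, path) -> None:
    df = g.to_dataframe()
    df.index.name = "id"
    # %.17g keeps continuous dosages bit-exact and prints integer codes
    # without a trailing ".0"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.17g")


def read_phenotype_table(path) -> PhenotypeTable:
    """Read a plot-level phenotype CSV (columns: trial, genotype, design,
    optional replication/block, remaining columns are traits)."""
    df = pd.read_csv(path, dtype=str, na_values=[MISSING_TOKEN, ""],
                     keep_default_na=False)
    table = PhenotypeTable(df)
    return table


def write_phenotype_table(p: PhenotypeTable, path) -> None:
    df = p.data.copy()
    df["design"] = df["design"].map(lambda d: d.value)
    df.to_csv(path, index=False, na_rep=MISSING_TOKEN)


def read_individual_list(path, name: str | None = None) -> IndividualList:
    """Read a list file: one individual name per line, ``#`` comments ignored."""
    members: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if not entry:
                continue
            if entry in seen:
                warnings.warn(f"{path}: duplicate list entry {entry!r} ignored",
                              stacklevel=2)
                continue
            seen.add(entry)
            members.append(entry)
    return IndividualList(name or str(path), members)


# ---------------------------------------------------------------------------
# encoding conversion and marker matching
# ---------------------------------------------------------------------------

def convert_encoding(g: GenotypeMatrix, target: Encoding) -> GenotypeMatrix:
    """Affine map between the two integer dosage codes (0,1,2 <-> -1,0,1).

    Missing entries are preserved; converting to CONTINUOUS is invalid, as
    is converting from it (continuous dosages arise only from imputation).
    """
    if target is Encoding.CONTINUOUS:
        raise EncodingError("cannot convert to CONTINUOUS: not an integer code")
    if g.encoding is Encoding.CONTINUOUS:
        raise EncodingError("cannot convert a CONTINUOUS matrix between integer codes")
    if target is g.encoding:
        return GenotypeMatrix(list(g.individual_ids), list(g.marker_ids),
                              g.dosage.copy(), g.encoding)
    shift = -1.0 if target is Encoding.MINUS1_0_1 else 1.0
    return GenotypeMatrix(list(g.individual_ids), list(g.marker_ids),
                          g.dosage + shift, target)


def dosage_0_2(g: GenotypeMatrix) -> np.ndarray:
    """Dosages on the canonical [0, 2] scale (copy)."""
    if g.encoding is Encoding.MINUS1_0_1:
        return g.dosage + 1.0
    return g.dosage.copy()


def match_markers(
    train: GenotypeMatrix,
    cand: GenotypeMatrix,
    min_overlap: float = 0.5,
) -> tuple[GenotypeMatrix, GenotypeMatrix, MarkerMatchReport]:
    """Restrict both matrices to their shared markers, in training order.

    Candidate populations can only be scored on markers the training
    population was genotyped with; the report carries the overlap fraction
    relative to the training marker set, and overlaps below ``min_overlap``
    are rejected.
    """
    cand_set = set(cand.marker_ids)
    shared = [m for m in train.marker_ids if m in cand_set]
    if not shared:
        raise IncompatiblePopulationsError(
            "training and candidate populations share no markers"
        )
    overlap = len(shared) / train.n_markers
    if overlap < min_overlap:
        raise IncompatiblePopulationsError(
            f"marker overlap {overlap:.3f} below the minimum {min_overlap:.3f} "
            f"({len(shared)}/{train.n_markers} training markers shared)"
        )
    report = MarkerMatchReport(
        n_train_markers=train.n_markers,
        n_candidate_markers=cand.n_markers,
        n_shared=len(shared),
        overlap_fraction=overlap,
        shared_markers=shared,
    )
    return train.subset_markers(shared), cand.subset_markers(shared), report


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def sorted_value_table(values: dict[str, float], value_col: str) -> pd.DataFrame:
    """Deterministic ranking table: descending value, ties by name."""
    rows = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["genotype", value_col])


def write_value_table(values: dict[str, float], path, value_col: str = "value") -> None:
    sorted_value_table(values, value_col).to_csv(path, sep="\t", index=False)
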