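import warnings

import numpy as np
import pandas as pd
import pytest

from gsblup import (
    AdjustMethod,
    Design,
    FormatError,
    InsufficientDataError,
    PhenotypeTable,
    adjust_single_trial,
    combine_trials,
    common_traits,
    simulate_trial,
)
from gsblup.pheno_prep import AdjustedPhenotypes


def _table(rows):
    return PhenotypeTable(pd.DataFrame(rows))


def _unknown_row(genotype, value, trial="t1"):
    return {"trial": trial, "genotype": genotype, "design": "UNKNOWN",
            "trait1": value}


class TestAdjustSingleTrial:
    def test_balanced_rcbd_equals_raw_means(self):
        """With balanced data the REML genotype means coincide with the
        per-genotype arithmetic means, whatever the replication variance."""
        vals = {"gA": 10.0, "gB": 12.0, "gC": 9.0}
        tbl = simulate_trial(vals, Design.RCBD, n_reps=2, block_sd=1.0,
                             plot_sd=0.3, seed=5)
        adj = adjust_single_trial(tbl, "trait1", "trial1")
        assert adj.method is AdjustMethod.REML_FIXED_EFFECT
        raw = tbl.data.groupby("genotype")["trait1"].mean()
        for g in vals:
            assert adj.values[g] == pytest.approx(raw[g], abs=1e-6)

    def test_unknown_design_takes_arithmetic_mean(self):
        tbl = _table([
            _unknown_row("A", 4.0), _unknown_row("A", 6.0),
            _unknown_row("B", None), _unknown_row("B", 3.0),
        ])
        adj = adjust_single_trial(tbl, "trait1", "t1")
        assert adj.method is AdjustMethod.ARITHMETIC_MEAN
        assert adj.values == {"A": 5.0, "B": 3.0}

    def test_all_missing_genotype_omitted(self):
        tbl = _table([
            _unknown_row("A", 1.0), _unknown_row("B", 2.0),
            _unknown_row("C", None),
        ])
        adj = adjust_single_trial(tbl, "trait1", "t1")
        assert "C" not in adj.values

    def test_translation_equivariance(self):
        vals = {f"g{i}": float(i) for i in range(8)}
        tbl = simulate_trial(vals, Design.ALPHA_LATTICE, n_reps=3,
                             block_sd=1.0, plot_sd=0.5, seed=3, block_size=4)
        adj = adjust_single_trial(tbl, "trait1", "trial1")
        shifted = PhenotypeTable(tbl.data.assign(trait1=tbl.data["trait1"] + 7.5))
        adj2 = adjust_single_trial(shifted, "trait1", "trial1")
        for g in adj.values:
            assert adj2.values[g] == pytest.approx(adj.values[g] + 7.5, abs=1e-6)

    def test_matches_independent_mixed_model_fit(self):
        """Unbalanced RCBD: genotype means agree with statsmodels MixedLM
        (random replication intercept, REML)."""
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(42)
        vals = {f"g{i:02d}": float(v) for i, v in enumerate(rng.normal(50, 5, 15))}
        tbl = simulate_trial(vals, Design.RCBD, n_reps=3, block_sd=2.0,
                             plot_sd=1.0, seed=9)
        df = tbl.data.sample(frac=1.0, random_state=1).iloc[6:].reset_index(drop=True)
        tbl2 = PhenotypeTable(df)
        adj = adjust_single_trial(tbl2, "trait1", "trial1")
        d = tbl2.data.assign(y=tbl2.data["trait1"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "y ~ 0 + C(genotype)", d, groups=np.ones(len(d)),
                vc_formula={"rep": "0 + C(replication)"},
            ).fit(reml=True, method="lbfgs")
        oracle = {k.split("[")[1].rstrip("]"): v for k, v in fit.fe_params.items()}
        for g, v in adj.values.items():
            assert v == pytest.approx(oracle[g], abs=1e-4)

    def test_fewer_than_two_genotypes_rejected(self):
        tbl = _table([_unknown_row("A", 1.0), _unknown_row("A", 2.0)])
        with pytest.raises(InsufficientDataError):
            adjust_single_trial(tbl, "trait1", "t1")

    def test_unknown_trait_and_trial_errors(self):
        tbl = _table([_unknown_row("A", 1.0), _unknown_row("B", 2.0)])
        with pytest.raises(FormatError, match="trait"):
            adjust_single_trial(tbl, "nope", "t1")
        with pytest.raises(FormatError, match="trial"):
            adjust_single_trial(tbl, "trait1", "t9")


class TestCombineTrials:
    def _adj(self, values, trial):
        return AdjustedPhenotypes("trait1", values,
                                  AdjustMethod.ARITHMETIC_MEAN, [trial])

    def test_mean_across_trials(self):
        combined = combine_trials([
            self._adj({"A": 10.0, "B": 1.0}, "t1"),
            self._adj({"A": 20.0}, "t2"),
            self._adj({"C": 7.0}, "t3"),
        ])
        assert combined.method is AdjustMethod.CROSS_TRIAL_AVERAGE
        assert combined.values["A"] == 15.0
        assert combined.values["B"] == 1.0  # averaged over trials where present
        assert combined.values["C"] == 7.0
        assert combined.source_trials == ["t1", "t2", "t3"]

    def test_single_trial_is_identity(self):
        part = self._adj({"A": 3.0, "B": 4.0}, "t1")
        assert combine_trials([part]).values == part.values

    def test_permutation_invariant(self):
        parts = [self._adj({"A": 1.0}, "t1"), self._adj({"A": 5.0}, "t2"),
                 self._adj({"A": 9.0}, "t3")]
        assert (combine_trials(parts).values
                == combine_trials(parts[::-1]).values)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            combine_trials([])


class TestCommonTraits:
    def _tbl(self, traits, trial="t1"):
        rows = []
        for g in ("A", "B"):
            row = {"trial": trial, "genotype": g, "design": "UNKNOWN"}
            row.update({t: 1.0 for t in traits})
            rows.append(row)
        return _table(rows)

    def test_intersection_sorted(self):
        assert common_traits([self._tbl(["b", "a"]), self._tbl(["b", "c"])]) == ["b"]
        assert common_traits([self._tbl(["b", "a"])]) == ["a", "b"]
        assert common_traits([self._tbl(["a"]), self._tbl(["b"])]) == []

    def test_trait_with_only_missing_values_excluded(self):
        t1 = self._tbl(["a", "b"])
        t2 = self._tbl(["a", "b"])
        t2.data["b"] = np.nan
        assert common_traits([t1, t2]) == ["a"]
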