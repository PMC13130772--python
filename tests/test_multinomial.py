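import numpy as np
import pandas as pd
import pytest

import diagmiss as dm
from diagmiss.errors import HandlerFailure, IncompleteDataError
from diagmiss.multinomial import (
    CatTable,
    mcar_missingness_rate,
    observed_loglik,
)


def random_cattable(rng, n_strata=4, max_count=20):
    strata = np.array(
        [[int(b) for b in format(s, f"0{int(np.log2(n_strata))}b")] for s in range(n_strata)]
    )
    full = rng.integers(1, max_count, size=(n_strata, 2)).astype(float)
    partial = rng.integers(0, max_count // 2, size=n_strata).astype(float)
    cols = tuple(f"S{i}" for i in range(strata.shape[1]))
    return CatTable(stratum_cols=cols, strata=strata, full=full, partial=partial)


def closed_form_allocation(cat):
    """Saturated-model EM fixed point: partial * full / stratum_total."""
    totals = cat.full.sum(axis=1, keepdims=True)
    cond = np.divide(cat.full, totals, out=np.full_like(cat.full, 0.5),
                     where=totals > 0)
    return cat.full + cat.partial[:, None] * cond


class TestToCatdata:
    def test_toy_dataset_tally(self, toy_table):
        cat = dm.to_catdata(toy_table, stratum_cols=("D", "X1"))
        # strata in lexicographic order: (0,0), (0,1), (1,0), (1,1)
        np.testing.assert_array_equal(cat.strata, [[0, 0], [0, 1], [1, 0], [1, 1]])
        np.testing.assert_allclose(cat.full, [[2, 0], [0, 1], [1, 0], [0, 2]])
        np.testing.assert_allclose(cat.partial, [1, 1, 1, 1])
        assert cat.n_total == 10

    def test_tally_matches_crosstab_oracle(self, study_table):
        cat = dm.to_catdata(study_table)
        obs = study_table[study_table["Y"].notna()]
        oracle = (
            obs.groupby(["D", "X1", "X2", "X3", "Y"]).size().to_dict()
        )
        for s, row in zip(cat.strata, cat.full):
            for y in (0, 1):
                key = (*s, float(y))
                assert row[y] == oracle.get(key, 0)
        assert cat.partial.sum() == study_table["Y"].isna().sum()
        assert cat.n_total == len(study_table)

    def test_empty_table(self):
        empty = pd.DataFrame({"D": [], "Y": [], "X1": [], "X2": [], "X3": []})
        cat = dm.to_catdata(empty)
        assert cat.n_total == 0
        assert (cat.full == 0).all() and (cat.partial == 0).all()

    def test_round_trip_preserves_2x2(self, complete_table):
        cat = dm.to_catdata(complete_table)
        counts = dm.from_catdata(cat)
        ref = dm.confusion_counts(complete_table)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (
            ref.tp, ref.fn, ref.tn, ref.fp,
        )


class TestSubstituteZeroCells:
    def test_zero_cells_replaced(self, toy_table):
        cat = dm.to_catdata(toy_table, stratum_cols=("D", "X1"))
        n_zero = int((cat.full == 0).sum())
        out = dm.substitute_zero_cells(cat, 1e-6)
        assert (out.full > 0).all()
        assert (out.full[cat.full > 0] == cat.full[cat.full > 0]).all()
        assert out.full.sum() == pytest.approx(cat.full.sum() + n_zero * 1e-6)
        np.testing.assert_array_equal(out.partial, cat.partial)
        # original untouched
        assert (cat.full == 0).sum() == n_zero

    def test_identity_without_zeros(self):
        cat = CatTable(("D",), np.array([[0], [1]]),
                       np.array([[3.0, 4.0], [5.0, 6.0]]), np.array([1.0, 0.0]))
        out = dm.substitute_zero_cells(cat)
        np.testing.assert_array_equal(out.full, cat.full)


class TestMLAllocation:
    def test_identity_without_partials(self, complete_table):
        cat = dm.to_catdata(complete_table)
        out = dm.ml_mar_allocate(cat)
        np.testing.assert_array_equal(out.full, cat.full)

    def test_printed_toy_allocation(self):
        # one stratum: 2 positive / 1 negative complete, 1 partial
        cat = CatTable(("D",), np.array([[1]]), np.array([[1.0, 2.0]]),
                       np.array([1.0]))
        out = dm.ml_mar_allocate(cat)
        np.testing.assert_allclose(out.full, [[1 + 1 / 3, 2 + 2 / 3]], atol=1e-8)

    def test_em_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            cat = random_cattable(rng)
            out = dm.ml_mar_allocate(dm.substitute_zero_cells(cat))
            np.testing.assert_allclose(
                out.full, closed_form_allocation(dm.substitute_zero_cells(cat)),
                atol=1e-6,
            )

    def test_mar_equals_mcar_allocation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            cat = dm.substitute_zero_cells(random_cattable(rng))
            a = dm.ml_mar_allocate(cat)
            b = dm.ml_mcar_allocate(cat)
            np.testing.assert_allclose(a.full, b.full, atol=1e-8)

    def test_loglik_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cat = dm.substitute_zero_cells(random_cattable(rng))
            for fn in (dm.ml_mar_allocate, dm.ml_mcar_allocate):
                trace = []
                fn(cat, loglik_trace=trace)
                assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_conservation_of_total(self):
        rng = np.random.default_rng(11)
        cat = random_cattable(rng)
        sub = dm.substitute_zero_cells(cat)
        out = dm.ml_mar_allocate(sub)
        assert out.full.sum() == pytest.approx(sub.n_total, abs=1e-8)
        assert out.partial.sum() == 0.0

    def test_massless_partial_stratum_fails(self):
        cat = CatTable(("D",), np.array([[0], [1]]),
                       np.array([[0.0, 0.0], [2.0, 3.0]]), np.array([2.0, 1.0]))
        with pytest.raises(HandlerFailure):
            dm.ml_mar_allocate(cat)
        # after zero-substitution the epsilon cells absorb the partials
        out = dm.ml_mar_allocate(dm.substitute_zero_cells(cat))
        np.testing.assert_allclose(out.full[0], [1.0, 1.0], atol=1e-5)

    def test_mcar_rate_is_partial_fraction(self, study_table):
        cat = dm.to_catdata(study_table)
        assert mcar_missingness_rate(cat) == pytest.approx(
            study_table["Y"].isna().mean()
        )


class TestWLSAllocation:
    def test_identity_without_partials(self, complete_table):
        cat = dm.to_catdata(complete_table)
        out = dm.wls_mcar_allocate(cat)
        np.testing.assert_array_equal(out.full, cat.full)

    def test_conservation(self, study_table):
        cat = dm.substitute_zero_cells(dm.to_catdata(study_table))
        out = dm.wls_mcar_allocate(cat)
        assert out.full.sum() == pytest.approx(cat.n_total, abs=1e-8)

    def test_asymptotic_agreement_with_ml(self):
        # large balanced MCAR table: WLS and ML estimates coincide to O(1/N)
        sc = dm.ScenarioSpec(0.8, 0.8, "MCAR", 0.3, 0.2, 100000)
        table = dm.generate_complete(sc, dm.build_latent_model(sc), 13)
        amputed = dm.ampute(table, dm.AmputationConfig("MCAR", 0.3), 13)
        cat = dm.substitute_zero_cells(dm.to_catdata(amputed))
        ml = dm.ml_mcar_allocate(cat)
        wls = dm.wls_mcar_allocate(cat)
        diff = np.max(np.abs(ml.full - wls.full)) / cat.n_total
        assert diff < 1e-3


class TestFromCatdata:
    def test_toy_complete_cells(self, toy_table):
        cat = dm.to_catdata(dm.cca(toy_table), stratum_cols=("D", "X1"))
        counts = dm.from_catdata(cat)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (2, 1, 1, 2)

    def test_partials_rejected(self, toy_table):
        cat = dm.to_catdata(toy_table, stratum_cols=("D", "X1"))
        with pytest.raises(IncompleteDataError):
            dm.from_catdata(cat)

    def test_all_zero(self):
        cat = CatTable(("D",), np.array([[0], [1]]), np.zeros((2, 2)), np.zeros(2))
        counts = dm.from_catdata(cat)
        assert counts.total == 0.0
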