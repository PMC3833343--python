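"""Antennal receptivity model: filtering, weighting, bands, Fisher tests."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from olfdiverge.receptivity import (
    BAND_SP1,
    BAND_SP2,
    BAND_UNDEFINED,
    BAND_WITHIN,
    class_enrichment,
    compute_receptivity,
    filter_matrix,
    fisher_exact_two_sided,
    map_orthologs,
    receptivity_change,
)


def matrix_of(values, receptors=None, odorants=None):
    values = np.asarray(values, dtype=float)
    receptors = receptors or [f"Or{i}" for i in range(values.shape[0])]
    odorants = odorants or [f"od{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=receptors, columns=odorants)


class TestFilterMatrix:
    def test_threshold_is_inclusive(self):
        m = matrix_of([[99.0], [100.0]])
        out = filter_matrix(m)
        assert list(out.index) == ["Or1"]

    def test_all_zero_matrix_empties(self):
        out = filter_matrix(matrix_of(np.zeros((3, 3))))
        assert out.empty

    def test_two_stage_order(self):
        # receptor maxima {120, 99, 150}; dropping the middle receptor
        # leaves odorant 1 with max 80 < 100, so it is dropped second
        m = matrix_of([[120.0, 10.0, 5.0], [50.0, 99.0, 10.0], [20.0, 80.0, 150.0]])
        out = filter_matrix(m)
        assert list(out.index) == ["Or0", "Or2"]
        assert list(out.columns) == ["od0", "od2"]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = matrix_of(rng.uniform(-50, 200, size=(6, 8)))
        once = filter_matrix(m)
        twice = filter_matrix(once)
        assert once.equals(twice)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_matrix(matrix_of([[1.0]]), threshold=-1)


class TestComputeReceptivity:
    def test_worked_example(self):
        m = matrix_of([[50.0], [100.0]], odorants=["X"])
        a = compute_receptivity(m, pd.Series({"Or0": 10.0, "Or1": 0.0}))
        assert a["X"] == pytest.approx(500.0)
        b = compute_receptivity(m, pd.Series({"Or0": 5.0, "Or1": 5.0}))
        assert b["X"] == pytest.approx(750.0)

    def test_negative_responses_contribute_zero(self):
        m = matrix_of([[-20.0, 120.0]])
        a = compute_receptivity(m, pd.Series({"Or0": 7.0}))
        assert a["od0"] == 0.0 and a["od1"] == pytest.approx(840.0)
        # replacing a negative response by a more negative one changes nothing
        m2 = matrix_of([[-2000.0, 120.0]])
        assert compute_receptivity(m2, pd.Series({"Or0": 7.0})).equals(a)

    def test_missing_rpkm_raises(self):
        with pytest.raises(KeyError):
            compute_receptivity(matrix_of([[1.0]]), pd.Series(dtype=float))

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError):
            compute_receptivity(matrix_of([[1.0]]), pd.Series({"Or0": -1.0}))


class TestReceptivityChange:
    def test_worked_example(self):
        ch = receptivity_change(pd.Series({"X": 500.0}), pd.Series({"X": 750.0}))
        row = ch.loc["X"]
        assert row["ratio"] == pytest.approx(2 / 3)
        assert row["signed_percent"] == pytest.approx(-50.0)
        assert row["band"] == BAND_SP2

    def test_identical_profiles_within_band(self):
        p = pd.Series({"X": 10.0, "Y": 3.0})
        ch = receptivity_change(p, p.copy())
        assert (ch["band"] == BAND_WITHIN).all()
        assert (ch["signed_percent"] == 0.0).all()

    def test_band_edges(self):
        ch = receptivity_change(
            pd.Series({"X": 1.05, "Y": 1.25}), pd.Series({"X": 1.0, "Y": 1.0})
        )
        assert ch.loc["X", "band"] == BAND_WITHIN  # 5% <= 10%
        assert ch.loc["Y", "band"] == BAND_SP1     # 25% > 10%

    def test_zero_handling(self):
        ch = receptivity_change(
            pd.Series({"X": 0.0, "Y": 5.0, "Z": 0.0}),
            pd.Series({"X": 0.0, "Y": 0.0, "Z": 3.0}),
        )
        assert ch.loc["X", "band"] == BAND_UNDEFINED
        assert ch.loc["Y", "band"] == BAND_SP1 and ch.loc["Y", "one_sided"]
        assert ch.loc["Z", "band"] == BAND_SP2
        assert list(ch.index)[-1] == "X"  # undefined sorts last

    def test_sorted_by_signed_percent(self):
        ch = receptivity_change(
            pd.Series({"X": 3.0, "Y": 1.0, "Z": 2.0}),
            pd.Series({"X": 1.0, "Y": 2.0, "Z": 2.0}),
        )
        sp = ch["signed_percent"]
        assert list(sp.index) == ["X", "Z", "Y"]

    def test_linearity_in_rpkm_scale(self):
        rng = np.random.default_rng(5)
        m = matrix_of(rng.uniform(-20, 200, size=(4, 6)))
        rpkm = pd.Series(rng.uniform(1, 50, 4), index=m.index)
        base = compute_receptivity(m, rpkm)
        scaled = compute_receptivity(m, 3.0 * rpkm)
        assert np.allclose(scaled.values, 3.0 * base.values)
        ch = receptivity_change(scaled, base)
        assert np.allclose(ch["ratio"].values, 3.0)

    def test_mismatched_odorants_rejected(self):
        with pytest.raises(ValueError):
            receptivity_change(pd.Series({"X": 1.0}), pd.Series({"Y": 1.0}))


class TestFisher:
    def test_diagonal_two_by_two(self):
        _, p = fisher_exact_two_sided([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3, abs=1e-15)

    def test_five_diagonal(self):
        _, p = fisher_exact_two_sided([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-15)

    def test_identical_proportions_give_one(self):
        _, p = fisher_exact_two_sided([[4, 6], [8, 12]])
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rnd = random.Random(99)
        for _ in range(150):
            cells = [rnd.randint(0, 12) for _ in range(4)]
            table = [cells[:2], cells[2:]]
            _, p = fisher_exact_two_sided(table)
            assert p == pytest.approx(oracles.fisher_two_sided(table), abs=1e-12)

    def test_matches_scipy_on_generic_tables(self):
        for table in ([[3, 9], [7, 2]], [[10, 2], [4, 12]], [[1, 5], [6, 1]]):
            _, p = fisher_exact_two_sided(table)
            assert p == pytest.approx(stats.fisher_exact(table)[1], rel=1e-9)


class TestClassEnrichment:
    def _changes(self, bands, percents=None):
        odorants = [f"od{i}" for i in range(len(bands))]
        percents = percents or [50.0 if b == BAND_SP1 else -50.0 for b in bands]
        return pd.DataFrame(
            {"band": bands, "signed_percent": percents, "ratio": 1.0},
            index=pd.Index(odorants, name="odorant"),
        )

    def _meta(self, classes):
        return pd.DataFrame(
            {"chemical_class": classes, "human_associated": False},
            index=pd.Index([f"od{i}" for i in range(len(classes))], name="odorant"),
        )

    def test_perfect_split_small_p(self):
        changes = self._changes([BAND_SP1] * 5 + [BAND_SP2] * 5)
        meta = self._meta(["ester"] * 5 + ["alcohol"] * 5)
        res = class_enrichment(changes, meta).set_index("group")
        assert res.loc["ester", "p"] == pytest.approx(2 / 252, abs=1e-12)

    def test_within_band_odorants_excluded(self):
        changes = self._changes([BAND_SP1, BAND_WITHIN, BAND_SP2, BAND_SP2])
        meta = self._meta(["ester", "ester", "alcohol", "alcohol"])
        res = class_enrichment(changes, meta).set_index("group")
        assert res.loc["ester", "table"] == [[1, 0], [0, 2]]

    def test_min_abs_percent_restriction(self):
        changes = self._changes(
            [BAND_SP1, BAND_SP1, BAND_SP2], percents=[50.0, 12.0, -60.0]
        )
        meta = self._meta(["ester", "ester", "alcohol"])
        res = class_enrichment(changes, meta, min_abs_percent=20.0).set_index("group")
        assert res.loc["ester", "table"] == [[1, 0], [0, 1]]

    def test_empty_stratum_flagged(self):
        changes = self._changes([BAND_SP1, BAND_SP2])
        meta = self._meta(["ester", "ester"])
        res = class_enrichment(changes, meta).set_index("group")
        assert bool(res.loc["ester", "untestable"])
        assert math.isnan(res.loc["ester", "p"])

    def test_missing_metadata_rejected(self):
        changes = self._changes([BAND_SP1])
        meta = self._meta(["ester"]).iloc[0:0]
        with pytest.raises(KeyError):
            class_enrichment(changes, meta)


class TestOrthologMapping:
    def test_rekeying(self):
        rpkm_q = pd.Series({"AQ1": 5.0, "AQ2": 2.0})
        omap = pd.Series({"AgOr1": "AQ1", "AgOr2": "AQ2", "AgOr3": "AQ9"})
        out = map_orthologs(rpkm_q, omap)
        assert out.to_dict() == {"AgOr1": 5.0, "AgOr2": 2.0}
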