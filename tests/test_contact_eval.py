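import math

import numpy as np
import pytest

from conthread import (
    ConfusionCounts,
    ContactMap,
    confusion,
    coverage,
    evaluate_map,
    filter_map,
    mcc,
    mean_fp_error,
    native_contact_map,
    precision,
    quality_bin,
    spread,
)
from conthread.contact_eval import EvalParams, pair_universe
from conthread.synthetic import gen_structure


def brute_force_eval(pred_pairs, native_pairs, length, sep_min=6):
    """Independent set-arithmetic oracle for the confusion-based measures."""
    universe = {(i, j) for i in range(1, length + 1)
                for j in range(i + sep_min, length + 1)}
    p = set(pred_pairs) & universe
    n = set(native_pairs) & universe
    tp = len(p & n)
    fp = len(p - n)
    fn = len(n - p)
    tn = len(universe) - tp - fp - fn
    prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    cov = 100.0 * tp / len(n) if n else None
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    m = num / math.sqrt(den) if den else 0.0
    sp = None
    if p and n:
        sp = np.mean([min(math.hypot(i - k, j - l) for (k, l) in p)
                      for (i, j) in n])
    return dict(tp=tp, fp=fp, tn=tn, fn=fn, precision=prec, coverage=cov,
                mcc=m, spread=sp)


class TestConfusion:
    def test_identity_prediction(self):
        native = ContactMap(length=20, contacts={(1, 8): 1.0, (2, 12): 1.0})
        c = confusion(native, native)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)
        assert c.tn == c.universe - 2

    def test_universe_size_L20(self):
        # brute-force enumeration of pairs with j - i >= 6 at L = 20
        assert pair_universe(20, 6) == sum(1 for i in range(1, 21)
                                           for j in range(i + 6, 21))
        assert pair_universe(20, 6) == 105

    def test_empty_prediction(self):
        native = ContactMap(length=20, contacts={(1, 8): 1.0, (2, 12): 1.0})
        c = confusion(ContactMap(length=20, contacts={}), native)
        assert (c.tp, c.fp, c.fn) == (0, 0, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(ContactMap(length=10, contacts={}),
                      ContactMap(length=11, contacts={}))


class TestScalarMeasures:
    @pytest.mark.parametrize("tp,fp,expected", [
        (3, 1, 75.0), (0, 0, 0.0), (5, 0, 100.0)])
    def test_precision(self, tp, fp, expected):
        assert precision(ConfusionCounts(tp=tp, fp=fp, tn=10, fn=0)) == expected

    def test_coverage(self):
        assert coverage(ConfusionCounts(tp=3, fp=0, tn=10, fn=9)) == 25.0
        assert coverage(ConfusionCounts(tp=0, fp=0, tn=10, fn=4)) == 0.0
        with pytest.raises(ValueError):
            coverage(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))

    def test_mcc_hand_value(self):
        c = ConfusionCounts(tp=3, fp=1, tn=94, fn=2)
        assert mcc(c) == pytest.approx(280 / math.sqrt(4 * 5 * 95 * 96))

    def test_mcc_degenerate_and_perfect(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=10, fn=2)) == 0.0
        assert mcc(ConfusionCounts(tp=5, fp=0, tn=95, fn=0)) == 1.0

    def test_mcc_sign_flip_on_balanced_complement(self):
        # complementing a prediction with tp = tn, fp = fn flips the sign
        c = ConfusionCounts(tp=10, fp=4, tn=10, fn=4)
        comp = ConfusionCounts(tp=c.fn, fp=c.tn, tn=c.fp, fn=c.tp)
        assert mcc(comp) == pytest.approx(-mcc(c))


class TestSpread:
    def test_identity_is_zero(self):
        m = ContactMap(length=30, contacts={(2, 10): 1.0, (5, 20): 1.0})
        assert spread(m, m) == 0.0

    def test_single_offset_pair(self):
        native = ContactMap(length=30, contacts={(2, 10): 1.0})
        pred = ContactMap(length=30, contacts={(2, 11): 1.0})
        assert spread(pred, native) == pytest.approx(1.0)

    def test_hand_computed_two_contacts(self):
        native = ContactMap(length=30, contacts={(2, 10): 1.0, (5, 20): 1.0})
        pred = ContactMap(length=30, contacts={(2, 10): 1.0})
        assert spread(pred, native) == pytest.approx((0 + math.sqrt(9 + 100)) / 2)

    def test_empty_prediction_errors(self):
        native = ContactMap(length=30, contacts={(2, 10): 1.0})
        with pytest.raises(ValueError):
            spread(ContactMap(length=30, contacts={}), native)


class TestMeanFPError:
    def test_no_false_positives(self, structure80, native80):
        assert mean_fp_error(native80, structure80) == 0.0

    def test_hand_value_on_known_geometry(self):
        from conthread.contact_io import ProteinStructure
        # residues 1 and 8 placed 10.5 apart -> FP error 2.5
        ca = np.zeros((8, 3))
        ca[:, 0] = np.arange(8) * 3.8
        ca[7] = [10.5, 0, 0]
        s = ProteinStructure(id="x", sequence="A" * 8, ca=ca)
        pred = ContactMap(length=8, contacts={(1, 8): 1.0}, atom_mode="CA")
        assert mean_fp_error(pred, s, atom_mode="CA") == pytest.approx(2.5)


class TestQualityBin:
    @pytest.mark.parametrize("value,expected", [
        (0.5, "high"), (0.35, "twilight"), (0.349, "low"),
        (0.9, "high"), (-0.2, "low"), (0.49, "twilight")])
    def test_boundaries(self, value, expected):
        assert quality_bin(value) == expected


class TestEvaluateMap:
    def test_perfect_prediction(self, structure80, native80):
        res = evaluate_map(native80, structure80)
        assert res.precision == 100.0
        assert res.coverage == 100.0
        assert res.mcc == pytest.approx(1.0)
        assert res.spread == 0.0
        assert res.mean_fp_error == 0.0
        assert res.bin == "high"

    def test_empty_filtered_prediction(self, structure80):
        weak = ContactMap(length=80, contacts={(1, 40): 0.3})
        res = evaluate_map(weak, structure80)
        assert res.precision == 0.0
        assert res.coverage == 0.0
        assert res.no_predicted_contacts
        assert math.isnan(res.spread)

    def test_monotonicity(self, structure80, native80):
        params = EvalParams()
        nat = sorted(native80.pairs)
        some = dict.fromkeys(nat[: len(nat) // 2], 1.0)
        base = evaluate_map(ContactMap(length=80, contacts=dict(some)),
                            structure80, params)
        # adding a correct contact never decreases coverage
        some2 = dict(some)
        some2[nat[-1]] = 1.0
        more_tp = evaluate_map(ContactMap(length=80, contacts=some2),
                               structure80, params)
        assert more_tp.coverage >= base.coverage
        # adding an incorrect contact never increases precision
        universe = {(i, j) for i in range(1, 81) for j in range(i + 6, 81)}
        wrong = sorted(universe - native80.pairs)[0]
        some3 = dict(some)
        some3[wrong] = 1.0
        more_fp = evaluate_map(ContactMap(length=80, contacts=some3),
                               structure80, params)
        assert more_fp.precision <= base.precision

    def test_sparse_high_precision_scores_below_denser_map(self, structure80,
                                                           native80):
        """A few perfect contacts give high precision but low MCC; a denser
        map with modest errors but real coverage scores higher MCC."""
        nat = sorted(native80.pairs)
        sparse = ContactMap(length=80, contacts=dict.fromkeys(nat[:3], 1.0))
        universe = sorted({(i, j) for i in range(1, 81)
                           for j in range(i + 6, 81)} - native80.pairs)
        dense_pairs = dict.fromkeys(nat[: int(0.7 * len(nat))], 1.0)
        dense_pairs.update(dict.fromkeys(universe[:10], 1.0))
        dense = ContactMap(length=80, contacts=dense_pairs)
        r_sparse = evaluate_map(sparse, structure80)
        r_dense = evaluate_map(dense, structure80)
        assert r_sparse.precision == 100.0
        assert r_sparse.precision >= r_dense.precision
        assert r_sparse.mcc < r_dense.mcc


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(10))
    def test_random_maps_match_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        L = int(rng.integers(30, 90))
        s = gen_structure(L, seed=trial + 500)
        native = native_contact_map(s)
        universe = [(i, j) for i in range(1, L + 1)
                    for j in range(i + 6, L + 1)]
        k = int(rng.integers(1, max(2, len(universe) // 4)))
        pred_pairs = [universe[i] for i in
                      rng.choice(len(universe), size=k, replace=False)]
        pred = ContactMap(length=L,
                          contacts=dict.fromkeys(pred_pairs, 1.0),
                          atom_mode="CB")
        res = evaluate_map(pred, s)
        exp = brute_force_eval(pred.pairs, native.pairs, L)
        assert (res.counts.tp, res.counts.fp, res.counts.tn, res.counts.fn) == \
            (exp["tp"], exp["fp"], exp["tn"], exp["fn"])
        assert res.precision == pytest.approx(exp["precision"], abs=1e-9)
        assert res.coverage == pytest.approx(exp["coverage"], abs=1e-9)
        assert res.mcc == pytest.approx(exp["mcc"], abs=1e-9)
        assert res.spread == pytest.approx(exp["spread"], abs=1e-9)
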