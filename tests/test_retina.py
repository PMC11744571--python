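"""Knudtson vessel-equivalent computations against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exercog.retina import (
    IncompleteMeasurementError,
    K_ARTERIOLE,
    K_VENULE,
    VesselMeasurementSet,
    compute_indices,
    icc_agreement,
    indices_table,
    iterative_reduce,
    pair_equivalent,
)

widths_strategy = st.lists(
    st.floats(min_value=10.0, max_value=400.0), min_size=1, max_size=12
)


def brute_force_reduce(widths, k):
    """Independent oracle: explicit largest-with-smallest pairing rounds."""
    vals = sorted(widths)
    while len(vals) > 1:
        paired = []
        lo, hi = 0, len(vals) - 1
        while lo < hi:
            paired.append(k * math.sqrt(vals[lo] ** 2 + vals[hi] ** 2))
            lo += 1
            hi -= 1
        if lo == hi:
            paired.append(vals[lo])
        vals = sorted(paired)
    return vals[0]


@pytest.mark.parametrize(
    "w1, w2, k, expected",
    [
        (10.0, 10.0, 0.88, 12.4451),
        (100.0, 100.0, 0.95, 134.3503),
    ],
)
def test_pair_equivalent_hand_values(w1, w2, k, expected):
    assert pair_equivalent(w1, w2, k) == pytest.approx(expected, abs=1e-4)


@given(w=st.floats(min_value=1.0, max_value=500.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_pair_equivalent_unit_k_closed_form(w):
    assert pair_equivalent(w, w, 1.0) == pytest.approx(w * math.sqrt(2))


@given(
    w1=st.floats(min_value=1.0, max_value=500.0),
    w2=st.floats(min_value=1.0, max_value=500.0),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_pair_equivalent_symmetric(w1, w2):
    assert pair_equivalent(w1, w2, 0.88) == pytest.approx(
        pair_equivalent(w2, w1, 0.88)
    )


def test_pair_equivalent_rejects_nonpositive():
    with pytest.raises(ValueError):
        pair_equivalent(-1.0, 10.0, 0.88)


def test_iterative_reduce_three_round_chain():
    # six equal widths: 12.4451 x3 -> {15.4882, 12.4451} -> 17.4843
    assert iterative_reduce([10.0] * 6, 0.88) == pytest.approx(17.4843, abs=1e-3)


def test_iterative_reduce_single_width_identity():
    assert iterative_reduce([123.4], 0.95) == 123.4


def test_iterative_reduce_empty_rejected():
    with pytest.raises(ValueError):
        iterative_reduce([], 0.88)


@given(widths=widths_strategy, k=st.floats(min_value=0.5, max_value=1.0))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_iterative_reduce_matches_brute_force(widths, k):
    assert iterative_reduce(widths, k) == pytest.approx(
        brute_force_reduce(widths, k), rel=1e-12
    )


@given(widths=widths_strategy, s=st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_scale_equivariance(widths, s):
    base = iterative_reduce(widths, 0.88)
    assert iterative_reduce([w * s for w in widths], 0.88) == pytest.approx(
        base * s, rel=1e-9
    )


@given(widths=st.lists(st.floats(min_value=10, max_value=400), min_size=6, max_size=6))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_permutation_invariance(widths):
    shuffled = widths[::-1][:3] + widths[:3][::-1]
    assert iterative_reduce(widths, 0.95) == pytest.approx(
        iterative_reduce(shuffled, 0.95), rel=1e-12
    )


@given(widths=st.lists(st.floats(min_value=10, max_value=400), min_size=2, max_size=8))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_monotonic_in_each_width(widths):
    base = iterative_reduce(widths, 0.88)
    bigger = list(widths)
    bigger[0] = bigger[0] + 10.0
    assert iterative_reduce(bigger, 0.88) > base


class TestComputeIndices:
    def test_equal_width_hand_values(self):
        m = VesselMeasurementSet([10.0] * 6, [10.0] * 6)
        idx = compute_indices(m)
        assert idx.crae == pytest.approx(brute_force_reduce([10] * 6, K_ARTERIOLE))
        assert idx.crve == pytest.approx(brute_force_reduce([10] * 6, K_VENULE))
        assert idx.crae == pytest.approx(17.4843, abs=1e-3)
        assert idx.crve == pytest.approx(21.3761, abs=1e-3)
        # equal input lists: the 0.88 chain lies below the 0.95 chain
        assert idx.avr == pytest.approx(idx.crae / idx.crve) and idx.avr < 1

    def test_avr_definition(self):
        # CRAE 150 / CRVE 200 under the standard convention
        m = VesselMeasurementSet([150.0], [200.0])
        with pytest.warns(UserWarning):
            idx = compute_indices(m)
        assert idx.avr == pytest.approx(0.75)
        assert idx.quality_flag

    def test_paper_literal_convention_is_reciprocal(self):
        m = VesselMeasurementSet([10.0] * 6, [12.0] * 6)
        std = compute_indices(m, "standard")
        lit = compute_indices(m, "paper_literal")
        assert lit.avr == pytest.approx(1.0 / std.avr)
        assert lit.avr_convention == "paper_literal"

    def test_missing_side_rejected(self):
        m = VesselMeasurementSet([10.0] * 6, [10.0] * 6)
        m.venule_widths = []
        with pytest.raises(IncompleteMeasurementError):
            compute_indices(m)

    def test_indices_table_roundtrip(self):
        rows = []
        for vt, w in (("arteriole", 100.0), ("venule", 140.0)):
            for _ in range(6):
                rows.append(
                    {"subject": "S1", "condition": "SIT", "timepoint": "pre",
                     "vessel_type": vt, "width_um": w}
                )
        table = indices_table(pd.DataFrame(rows))
        assert len(table) == 1
        assert table.loc[0, "crae"] == pytest.approx(
            brute_force_reduce([100] * 6, K_ARTERIOLE)
        )
        assert not table.loc[0, "quality_flag"]


class TestIcc:
    def test_identical_replicates(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3)) + 5
        assert icc_agreement(x) == pytest.approx(1.0)

    def test_independent_replicates_near_zero(self, rng):
        vals = [icc_agreement(rng.standard_normal((50, 3))) for _ in range(30)]
        assert abs(np.mean(vals)) < 0.05

    def test_constructed_icc_recovered(self, rng):
        # truth + noise with variance ratio giving ICC = 0.85
        sigma_t, icc = 10.0, 0.85
        sigma_e = sigma_t * math.sqrt((1 - icc) / icc)
        truth = rng.normal(0, sigma_t, size=(800, 1))
        x = truth + rng.normal(0, sigma_e, size=(800, 3))
        assert icc_agreement(x) == pytest.approx(icc, abs=0.05)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(0, 1, size=(25, 3)) + rng.normal(0, 2, size=(25, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(25), 3),
                "rater": np.tile(np.arange(3), 25),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        ref_val = ref.loc[
            ref["Type"].isin(["ICC(A,1)", "ICC2"]), "ICC"
        ].iloc[0]
        assert icc_agreement(x) == pytest.approx(ref_val, abs=1e-6)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            icc_agreement(np.ones((5, 1)))
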