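import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_experiment
from marbod.errors import DegenerateTrialError, ExtrapolationError, ValidationError
from marbod.io_experiment import BottleSeries, MaterialMeta, Role
from marbod.preprocess import (
    align_to_grid,
    blank_correct,
    pct_cplus,
    qa_gates,
    thod,
)

PHB = {"C": 4, "H": 6, "O": 2}


# -- align_to_grid ----------------------------------------------------------


def bottle(times, bod, bid="X", role=Role.SAMPLE, mid="M"):
    return BottleSeries(bid, role, mid, 1, times, bod)


def test_align_exact_at_observed_times():
    vals = align_to_grid([bottle([1.0, 2.0, 3.0], [5.0, 7.0, 9.0])], [2.0])
    assert vals["X"] == pytest.approx([7.0])


def test_align_linear_between_readings():
    vals = align_to_grid([bottle([1.0, 2.0], [10.0, 20.0])], [1.5])
    assert vals["X"] == pytest.approx([15.0])


def test_align_refuses_extrapolation():
    with pytest.raises(ExtrapolationError):
        align_to_grid([bottle([0.0, 28.0], [0.0, 5.0])], [29.0])


# -- blank correction -------------------------------------------------------


def test_blank_mean_is_subtracted():
    exp = make_experiment(
        sample_bod=[0.0, 50.0], cplus_bod=[0.0, 100.0], blank_bod=[0.0, 1.0],
        times=[0.0, 28.0],
    )
    # replace one blank with a different level so the mean is (1+3)/2 = 2
    exp.bottles[1] = BottleSeries("BLANK-2", Role.BLANK, "BLANK", 2,
                                  [0.0, 28.0], [0.0, 3.0])
    corr = blank_correct(exp)
    assert corr["S1"].value_at(28.0) == pytest.approx(48.0)
    assert corr["C+"].value_at(28.0) == pytest.approx(98.0)


def test_zero_blanks_leave_raw_unchanged():
    exp = make_experiment([0.0, 50.0], [0.0, 100.0], [0.0, 0.0], times=[0.0, 28.0])
    corr = blank_correct(exp)
    assert corr["S1"].bod_corrected == pytest.approx([0.0, 50.0])


def test_negative_corrected_values_are_retained():
    exp = make_experiment([0.0, 2.0], [0.0, 100.0], [0.0, 5.0], times=[0.0, 28.0])
    corr = blank_correct(exp)
    assert corr["S1"].value_at(28.0) == pytest.approx(-3.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(alpha=st.floats(0.1, 10.0))
def test_blank_correction_is_linear_with_zero_blanks(alpha):
    base = np.array([0.0, 10.0, 30.0])
    exp = make_experiment(base * alpha, base * 2, np.zeros(3), times=[0.0, 14.0, 28.0])
    corr = blank_correct(exp)
    assert corr["S1"].bod_corrected == pytest.approx(alpha * base)


# -- %C+ --------------------------------------------------------------------


def test_pct_cplus_values():
    exp = make_experiment([0.0, 21.0], [0.0, 100.0], [0.0, 0.0], times=[0.0, 28.0])
    corr = blank_correct(exp)
    assert pct_cplus(corr["S1"], corr["C+"], 28.0) == pytest.approx(21.0)


def test_pct_cplus_identity_and_zero():
    exp = make_experiment([0.0, 100.0], [0.0, 100.0], [0.0, 0.0], times=[0.0, 28.0])
    corr = blank_correct(exp)
    assert pct_cplus(corr["S1"], corr["C+"], 28.0) == pytest.approx(100.0)
    exp0 = make_experiment([0.0, 0.0], [0.0, 100.0], [0.0, 0.0], times=[0.0, 28.0])
    corr0 = blank_correct(exp0)
    assert pct_cplus(corr0["S1"], corr0["C+"], 28.0) == pytest.approx(0.0)


def test_pct_cplus_degenerate_control():
    exp = make_experiment([0.0, 21.0], [0.0, 3.0], [0.0, 5.0], times=[0.0, 28.0])
    corr = blank_correct(exp)  # corrected C+ is negative
    with pytest.raises(DegenerateTrialError):
        pct_cplus(corr["S1"], corr["C+"], 28.0)


def test_control_against_itself_is_100_percent_everywhere():
    exp = make_experiment([0.0, 10.0, 21.0], [0.0, 60.0, 100.0], [0.0, 0.5, 1.0],
                          times=[0.0, 14.0, 28.0])
    corr = blank_correct(exp)
    track = corr["C+"].pct_cplus
    assert np.allclose(track[np.isfinite(track)], 100.0)


# -- ThOD -------------------------------------------------------------------


def test_thod_phb_repeat_unit():
    # (4*32 + 6*8 - 2*16) / 86.09 by hand stoichiometry
    assert thod(PHB) == pytest.approx(1.673, abs=1e-3)


def test_thod_methane():
    assert thod({"C": 1, "H": 4}) == pytest.approx(64.0 / 16.043, rel=1e-4)


def test_thod_nitrogen_source():
    glycine = {"C": 2, "H": 5, "N": 1, "O": 2}
    mw = 2 * 12.011 + 5 * 1.008 + 14.007 + 2 * 15.999
    # oxidizing N to nitrate demands 2 mol O2 (64 g) per mol N more than NH3
    assert thod(glycine, "nitrate") - thod(glycine, "ammonium") == pytest.approx(64.0 / mw)


def test_thod_errors():
    with pytest.raises(ValidationError, match="carbon"):
        thod({"O": 2})
    with pytest.raises(ValidationError, match="unsupported"):
        thod({"C": 1, "Cl": 4})
    with pytest.raises(ValidationError, match="empty"):
        thod({})


# -- QA gates ---------------------------------------------------------------


def test_blank_gate_pass():
    exp = make_experiment([0.0, 21.0], [0.0, 100.0], [0.0, 1.0], times=[0.0, 28.0])
    qa = qa_gates(exp, blank_correct(exp))
    assert qa.blank_fraction_of_cplus == pytest.approx(0.01)
    assert qa.blank_pass


def test_cplus_gate_pass_and_fail():
    # corrected C+ of 110 mg/L against 100 mg/L PHB (ThOD 1.673) -> 0.657
    exp = make_experiment([0.0, 21.0], [0.0, 111.0], [0.0, 1.0], times=[0.0, 28.0])
    qa = qa_gates(exp, blank_correct(exp))
    assert qa.cplus_fraction_of_thod == pytest.approx(110.0 / 167.3, abs=2e-4)
    assert qa.cplus_pass
    # corrected C+ of 90 mg/L -> 0.538, below the 60% gate
    exp = make_experiment([0.0, 21.0], [0.0, 91.0], [0.0, 1.0], times=[0.0, 28.0])
    qa = qa_gates(exp, blank_correct(exp))
    assert qa.cplus_fraction_of_thod == pytest.approx(90.0 / 167.3, abs=2e-4)
    assert qa.cplus_pass is False


def test_unknown_formula_makes_cplus_gate_indeterminate():
    exp = make_experiment([0.0, 21.0], [0.0, 111.0], [0.0, 1.0],
                          times=[0.0, 28.0], cplus_formula=None)
    qa = qa_gates(exp, blank_correct(exp))
    assert qa.cplus_fraction_of_thod is None
    assert qa.cplus_pass is None
    assert qa.blank_pass  # blank gate still evaluated
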