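import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vigil.scoring import (
    ScoringError,
    ZeroVarianceWarning,
    accuracy,
    bin_assignments,
    bin_performance,
    bin_sizes,
    bin_trials,
    correlate_trend_with_accuracy,
    group_standardized_bis,
    label_epochs,
    participant_trend,
    score_trials,
    trends_table,
)
from vigil.data import LABEL_ATTENTIVE, LABEL_DECREMENT, LABEL_UNLABELED


# ---------------------------------------------------------------------------
# binning

@settings(deadline=None, derandomize=True)
@given(n=st.integers(8, 5000), k=st.integers(2, 8))
def test_bin_sizes_partition(n, k):
    sizes = bin_sizes(n, k)
    assert sum(sizes) == n
    assert max(sizes) - min(sizes) <= 1
    assert sorted(sizes, reverse=True) == sizes  # remainder to earliest bins


def test_bin_sizes_errors():
    with pytest.raises(ScoringError):
        bin_sizes(3, 4)
    with pytest.raises(ScoringError):
        bin_sizes(10, 1)


def test_bin_assignments_contiguous():
    a = bin_assignments(10, 4)
    assert a.tolist() == [1, 1, 1, 2, 2, 2, 3, 3, 4, 4]
    assert (np.diff(a) >= 0).all()


def test_bin_trials_preserves_order():
    df = pd.DataFrame({"trial_index": [3, 1, 0, 2], "x": list("dbac")})
    groups = bin_trials(df, 2)
    assert groups[0]["x"].tolist() == ["a", "b"]
    assert groups[1]["x"].tolist() == ["c", "d"]


# ---------------------------------------------------------------------------
# accuracy / BIS

def test_accuracy_formula():
    assert accuracy(3, 1, 2, 4) == pytest.approx(7 / 10)
    with pytest.raises(ScoringError):
        accuracy(0, 0, 0, 0)
    with pytest.raises(ScoringError):
        accuracy(-1, 0, 0, 1)


def _session(pcs, rts, n_per_bin=20, seed=0):
    """Build a trial log whose per-bin PC and mean hit RT are exact."""
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for b, (pc, rt) in enumerate(zip(pcs, rts)):
        n_hit = int(round(pc * n_per_bin))
        for j in range(n_per_bin):
            hit = j < n_hit
            rows.append(
                dict(
                    participant_id="p0", task_id="t", session_id=1,
                    trial_index=idx,
                    t_stimulus=idx * 2.0,
                    t_response=idx * 2.0 + rt if hit else np.nan,
                    is_critical=True,
                    outcome="hit" if hit else "miss",
                    rt=rt if hit else np.nan,
                )
            )
            idx += 1
    return pd.DataFrame(rows)


def test_bin_performance_zscores_and_bis():
    trials = _session([1.0, 0.9, 0.8, 0.7], [0.30, 0.35, 0.40, 0.45])
    bps = bin_performance(bin_trials(trials, 4), "p0", "t", 1)
    pcs = np.array([b.pc for b in bps])
    zpc = np.array([b.zpc for b in bps])
    zrt = np.array([b.zrt for b in bps])
    bis = np.array([b.bis for b in bps])
    assert pcs == pytest.approx([1.0, 0.9, 0.8, 0.7])
    # z-scores use sample SD (ddof=1) and sum to ~0
    assert abs(zpc.sum()) < 1e-9 and abs(zrt.sum()) < 1e-9
    assert abs(bis.sum()) < 1e-9
    expected_z0 = (1.0 - 0.85) / np.std([1.0, 0.9, 0.8, 0.7], ddof=1)
    assert zpc[0] == pytest.approx(expected_z0)
    assert np.allclose(bis, zpc - zrt)
    # declining PC and rising RT: BIS strictly decreasing
    assert (np.diff(bis) < 0).all()


def test_constant_pc_warns_and_zeroes():
    trials = _session([0.9] * 4, [0.30, 0.35, 0.40, 0.45])
    with pytest.warns(ZeroVarianceWarning):
        bps = bin_performance(bin_trials(trials, 4), "p0", "t", 1)
    assert all(b.zpc == 0.0 for b in bps)
    assert any(b.zrt != 0.0 for b in bps)


def test_no_hits_bin_gets_nan_rt():
    trials = _session([0.0, 0.5, 0.5, 0.5], [0.3, 0.3, 0.35, 0.4])
    with pytest.warns(ZeroVarianceWarning):
        bps = bin_performance(bin_trials(trials, 4), "p0", "t", 1)
    assert np.isnan(bps[0].rt)


def test_score_trials_tidy(micro_trials):
    bins = score_trials(micro_trials)
    grp = bins.groupby(["participant_id", "task_id", "session_id"])
    for _, g in grp:
        assert g["bin_index"].tolist() == [1, 2, 3, 4]
        # BIS sums to zero across a session's bins when defined everywhere
        # (a bin with no hits has undefined RT, hence undefined BIS)
        if g["bis"].notna().all():
            assert abs(g["bis"].sum()) < 1e-9
    assert bins["pc"].between(0, 1).all()


def test_group_standardized_bis(micro_trials):
    bins = score_trials(micro_trials)
    out = group_standardized_bis(bins)
    for _, g in out.groupby(["task_id", "session_id", "bin_index"]):
        if len(g) > 1 and g["pc"].nunique() > 1:
            assert abs(g["zpc"].sum()) < 1e-9


# ---------------------------------------------------------------------------
# trends

def test_participant_trend_slope_sign():
    trials = _session([1.0, 0.9, 0.8, 0.7], [0.30, 0.35, 0.40, 0.45])
    t = participant_trend(bin_performance(bin_trials(trials, 4), "p0", "t", 1))
    assert t.slope < 0
    assert t.bis_diff_1_4 > 0  # first bin scores higher than last
    # slope equals the least-squares fit
    y = np.array(t.bis_by_bin)
    assert t.slope == pytest.approx(np.polyfit([1, 2, 3, 4], y, 1)[0])


def test_trend_requires_two_bins():
    with pytest.raises(ScoringError):
        participant_trend([])


def test_trends_table(micro_trials):
    tt = trends_table(score_trials(micro_trials))
    sessions = micro_trials.groupby(
        ["participant_id", "task_id", "session_id"]
    ).ngroups
    assert len(tt) == sessions


# ---------------------------------------------------------------------------
# labeling

def test_label_epochs(micro_epochs):
    lab = micro_epochs
    b = lab.meta["bin_index"].to_numpy()
    y = lab.meta["label"].to_numpy()
    assert (y[b == 1] == LABEL_ATTENTIVE).all()
    assert (y[b == 4] == LABEL_DECREMENT).all()
    assert (y[(b == 2) | (b == 3)] == LABEL_UNLABELED).all()
    with pytest.raises(ScoringError):
        label_epochs(lab, n_bins=3)


def test_labels_are_class_balanced(micro_epochs):
    y = micro_epochs.meta["label"].to_numpy()
    n0 = (y == LABEL_ATTENTIVE).sum()
    n1 = (y == LABEL_DECREMENT).sum()
    # bins 1 and 4 differ by at most one trial per session
    assert abs(n0 - n1) <= micro_epochs.meta.groupby(
        ["participant_id", "task_id", "session_id"]
    ).ngroups


# ---------------------------------------------------------------------------
# correlation

def test_correlation_matches_scipy(rng):
    x = rng.normal(size=10)
    y = 0.5 * x + rng.normal(size=10)
    from scipy import stats as sps

    rho, p = correlate_trend_with_accuracy(x, y)
    ref = sps.pearsonr(x, y)
    assert rho == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_correlation_errors():
    with pytest.raises(ScoringError):
        correlate_trend_with_accuracy([1, 2, 3], [1, 2, 3])  # too few
    with pytest.raises(ScoringError):
        correlate_trend_with_accuracy([1, 1, 1, 1], [1, 2, 3, 4])
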