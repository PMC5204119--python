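"""Signal correction, probe statistics, BH, and the consensus DE call."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncestro import arrayde
from lncestro.errors import (
    CalibrationError,
    InvalidParameterError,
    MalformedGeneError,
)


def _probe_table(values: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """values[probe_id][condition] -> replicate intensities; one gene each."""
    rows = []
    for pid, conds in values.items():
        for cond, reps in conds.items():
            for i, v in enumerate(reps, 1):
                rows.append(
                    {
                        "probe_id": pid,
                        "gene_id": pid.rsplit("_", 1)[0],
                        "probe_index": 1,
                        "is_spike_in": False,
                        "condition": cond,
                        "replicate": i,
                        "intensity": v,
                    }
                )
    return pd.DataFrame(rows)


# -- signal correction -------------------------------------------------------

@pytest.mark.parametrize(
    "intensity,gamma,expected",
    [(100.0, 1.0, 100.0), (10.0, 1.125, 10.0 ** 1.125), (1.0, 2.3, 1.0)],
)
def test_correct_signal_power_law(intensity, gamma, expected):
    table = _probe_table({"g_p1": {"treated": [intensity], "control": [intensity]}})
    out = arrayde.correct_signal(table, gamma)
    assert out["intensity"].iloc[0] == pytest.approx(expected, rel=1e-12)
    assert (out["intensity"] > 0).all()


def test_correct_signal_rejects_nonpositive_gamma():
    table = _probe_table({"g_p1": {"treated": [1.0], "control": [1.0]}})
    with pytest.raises(InvalidParameterError):
        arrayde.correct_signal(table, 0.0)


def test_probe_log_fc_basic_ratios():
    table = _probe_table(
        {
            "a_p1": {"treated": [50.0, 50.0], "control": [50.0, 50.0]},
            "b_p1": {"treated": [200.0, 200.0], "control": [100.0, 100.0]},
        }
    )
    lfc = arrayde.probe_log_fc(table).set_index("probe_id")["log2_fc"]
    assert lfc["a_p1"] == pytest.approx(0.0, abs=1e-12)
    assert lfc["b_p1"] == pytest.approx(1.0, abs=1e-12)


# -- probe-level tests -------------------------------------------------------

def test_probe_pvalue_degenerate_and_separated():
    same = _probe_table({"g_p1": {"treated": [8.0, 8.0], "control": [8.0, 8.0]}})
    assert arrayde.probe_pvalue(same, "g_p1") == 1.0

    jitter = [5.0, 5.001, 4.999]
    apart = _probe_table({"g_p1": {"treated": [1.0, 1.001, 0.999], "control": jitter}})
    assert arrayde.probe_pvalue(apart, "g_p1") < 1e-3


def test_probe_pvalue_symmetric_in_condition_labels():
    t = _probe_table({"g_p1": {"treated": [3.0, 4.0, 5.0], "control": [7.0, 8.0, 10.0]}})
    swapped = t.copy()
    swapped["condition"] = swapped["condition"].map(
        {"treated": "control", "control": "treated"}
    )
    assert arrayde.probe_pvalue(t, "g_p1") == pytest.approx(
        arrayde.probe_pvalue(swapped, "g_p1")
    )


def test_pooled_anova_matches_welch_for_single_probe_gene():
    # with one probe the pooled error term is that probe's own variance,
    # so the ANOVA contrast equals the pooled-variance t-test
    t = _probe_table({"g_p1": {"treated": [4.0, 5.0, 6.0], "control": [7.0, 9.0, 8.0]}})
    p_anova = arrayde.probe_pvalues_anova(t)["p_value"].iloc[0]
    from scipy import stats

    tt = stats.ttest_ind(
        np.log2([4.0, 5.0, 6.0]), np.log2([7.0, 9.0, 8.0]), equal_var=True
    )
    assert p_anova == pytest.approx(tt.pvalue, rel=1e-9)


# -- FDR ---------------------------------------------------------------------

def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent O(m^2) step-up: q_i = min over p_(j) >= p_i of m p_(j)/j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    with np.errstate(invalid="ignore"):
        mat = np.full((m, m), np.inf)
        for i in range(m):
            for j in range(i, m):
                mat[i, j] = m * ps[j] / (j + 1)
    q_sorted = np.minimum(mat.min(axis=1), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_fdr_examples_match_hand_computation():
    q = arrayde.fdr_adjust([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03])
    assert arrayde.fdr_adjust([0.2])[0] == pytest.approx(0.2)
    assert np.allclose(arrayde.fdr_adjust([0.4, 0.4, 0.4]), 0.4)


def test_fdr_rejects_out_of_range():
    with pytest.raises(InvalidParameterError):
        arrayde.fdr_adjust([0.5, 1.5])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_fdr_matches_brute_force_oracle(p):
    p = np.asarray(p)
    assert np.allclose(arrayde.fdr_adjust(p), brute_force_bh(p), atol=1e-12)


def test_local_fdr_is_small_for_extreme_p(rng):
    p = np.concatenate([rng.uniform(size=500), np.full(20, 1e-8)])
    lf = arrayde.local_fdr(p)
    assert lf[-20:].max() < lf[:500].mean()


# -- the consensus call ------------------------------------------------------

def _stats_frame(lfcs, qs, gene="g"):
    return pd.DataFrame(
        {
            "gene_id": gene,
            "probe_id": [f"{gene}_p{i}" for i in range(len(lfcs))],
            "log2_fc": lfcs,
            "q_value": qs,
        }
    )


def test_unanimous_strong_probes_are_called_up():
    res = arrayde.call_de(_stats_frame([1.0] * 7, [0.01] * 7))
    assert res["de_call"].iloc[0] == "up"
    assert res[["passes_fc", "passes_fdr", "passes_concordance"]].all(axis=None)


def test_single_discordant_probe_vetoes_the_call():
    res = arrayde.call_de(_stats_frame([1.0] * 6 + [-1.0], [0.001] * 7))
    assert res["de_call"].iloc[0] == "none"
    assert res["direction"].iloc[0] == "mixed"


def test_subthreshold_fold_change_vetoes_the_call():
    lfc = float(np.log2(1.3))
    res = arrayde.call_de(_stats_frame([lfc] * 7, [0.001] * 7))
    assert res["de_call"].iloc[0] == "none"
    assert not res["passes_fc"].iloc[0]


def test_gene_log2_fc_is_probe_median():
    lfcs = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1]
    res = arrayde.call_de(_stats_frame(lfcs, [0.01] * 7))
    assert res["gene_log2_fc"].iloc[0] == pytest.approx(0.8)


def test_malformed_gene_is_rejected():
    frame = pd.concat(
        [_stats_frame([1.0] * 7, [0.01] * 7, "a"), _stats_frame([1.0] * 5, [0.01] * 5, "b")]
    )
    with pytest.raises(MalformedGeneError):
        arrayde.call_de(frame, probes_per_gene=7)


@given(
    st.lists(st.floats(min_value=0.5, max_value=3), min_size=7, max_size=7),
    st.lists(st.floats(min_value=0.0, max_value=0.05), min_size=7, max_size=7),
    st.integers(min_value=0, max_value=6),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_strengthening_evidence_never_flips_a_call_off(lfcs, qs, idx):
    base = arrayde.call_de(_stats_frame(lfcs, qs))
    stronger_lfc = list(lfcs)
    stronger_lfc[idx] = stronger_lfc[idx] + 1.0
    stronger_q = list(qs)
    stronger_q[idx] = 0.0
    after = arrayde.call_de(_stats_frame(stronger_lfc, stronger_q))
    if base["de_call"].iloc[0] == "up":
        assert after["de_call"].iloc[0] == "up"


# -- calibration -------------------------------------------------------------

def test_calibration_needs_informative_references():
    table = _probe_table({"g_p1": {"treated": [2.0], "control": [1.0]}})
    with pytest.raises(CalibrationError):
        arrayde.calibrate_exponent(table, pd.DataFrame(columns=["unit_id", "unit_type", "reference_log2_fc"]))
    degenerate = pd.DataFrame(
        {
            "unit_id": ["s1", "s2"],
            "unit_type": "spike_probe",
            "reference_log2_fc": [1.0, 1.0],
        }
    )
    with pytest.raises(CalibrationError):
        arrayde.calibrate_exponent(table, degenerate)


def test_de_fraction_is_whole_number_percent():
    assert arrayde.de_fraction_percent(127, 5586) == 2
    assert arrayde.de_fraction_percent(0, 10) == 0
    with pytest.raises(InvalidParameterError):
        arrayde.de_fraction_percent(11, 10)
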