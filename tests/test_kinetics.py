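"""Kinetics pipeline: calibration, turnover arithmetic, rank statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from sacph import kinetics as kin
from sacph import synth


# ---------------------------------------------------------------------------
# Standard curve
# ---------------------------------------------------------------------------

class TestStandardCurve:
    CONC = np.logspace(-1, 3, 9)  # 0.1 nM .. 1 uM
    TRUE = (100.0, 1.2, 30.0, 2000.0)  # a, b, c, d

    def _readings(self, noise_cv=0.0, seed=0):
        clean = kin._four_pl(self.CONC, *self.TRUE)
        if noise_cv == 0:
            return clean
        rng = np.random.default_rng(seed)
        return clean * rng.lognormal(0, noise_cv, clean.size)

    def test_noise_free_round_trip(self):
        curve = kin.fit_standard_curve(self.CONC, self._readings())
        for est, true in zip(curve.coefficients, self.TRUE):
            assert est == pytest.approx(true, rel=0.01)
        # identity: reading generated from c inverts to c
        for c in (1.0, 30.0, 300.0):
            assert curve.inverse(curve.predict(c)) == pytest.approx(c, rel=1e-6)

    def test_reading_at_asymptote_flagged(self):
        curve = kin.fit_standard_curve(self.CONC, self._readings())
        out = kin.reading_to_camp(curve, 99.0)  # below lower asymptote
        assert out["camp_nM"] is None and not out["in_range"]

    def test_noisy_inverse_within_ten_percent(self):
        curve = kin.fit_standard_curve(self.CONC, self._readings(0.05, seed=1))
        mid = 30.0
        reading = kin._four_pl(mid, *self.TRUE)
        est = curve.inverse(reading)
        assert est == pytest.approx(mid, rel=0.10)

    def test_bad_calibrators(self):
        with pytest.raises(kin.InputError):
            kin.fit_standard_curve([1, 2, 3], [1, 2, 3])
        with pytest.raises(kin.InputError):
            kin.fit_standard_curve([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])


# ---------------------------------------------------------------------------
# Activity / turnover arithmetic
# ---------------------------------------------------------------------------

def test_activity_and_turnover_arithmetic():
    assert kin.activity(0.0, 10.0) == 0.0
    assert kin.activity(1.2, 10.0) == pytest.approx(0.12)
    # constructed amounts landing on the measured turnover means
    assert kin.turnover(0.636, 600.0, 0.01) == pytest.approx(0.106)
    assert kin.turnover(0.21, 600.0, 0.01) == pytest.approx(0.035)
    with pytest.raises(kin.InputError):
        kin.turnover(1.0, 0.0, 0.01)
    with pytest.raises(kin.InputError):
        kin.turnover(1.0, 600.0, 0.0)


def test_turnover_linearity_scaling():
    rng = np.random.default_rng(2)
    camp, t, e = rng.uniform(0.1, 2, 20), 600.0, 0.01
    base = kin.turnover(camp, t, e)
    np.testing.assert_allclose(kin.turnover(3 * camp, t, e), 3 * base)
    np.testing.assert_allclose(kin.turnover(camp, 2 * t, e), base / 2)
    np.testing.assert_allclose(kin.turnover(camp, t, 4 * e), base / 4)
    # batch mean equals mean of singles (linearity)
    assert kin.activity(camp, 10.0).mean() == pytest.approx(
        np.mean([kin.activity(c, 10.0) for c in camp]))


def test_fold_change():
    assert kin.fold_change([1, 1, 1], [1, 1, 1]) == 1.0
    assert kin.fold_change([1, 1, 1], [5.4, 5.4, 5.4]) == pytest.approx(5.4)
    with pytest.raises(kin.InputError):
        kin.fold_change([], [1.0])
    with pytest.raises(kin.InputError):
        kin.fold_change([0.0, 0.0], [1.0])


def test_fold_change_recovers_preset_ratio():
    plate = synth.gen_plate("apsac_fl_mg", seed=12)
    wells = plate.wells
    a = wells[wells["condition"] == "pH7"]["camp_pmol"]
    b = wells[wells["condition"] == "pH8"]["camp_pmol"]
    assert kin.fold_change(a, b) == pytest.approx(5.4, rel=0.15)


def test_ph_profile_shape_flags():
    flat = kin.ph_profile([6.5, 7.0, 8.0], [1.0, 1.0, 1.0])
    assert flat["peaks"] == [] and flat["max_min_ratio"] == 1.0
    mono = kin.ph_profile([6.5, 7.0, 8.0], [1.0, 2.0, 3.0])
    assert mono["peaks"] == []
    # the measured biphasic shape: peak at 7.0, trough at 7.2, surge at 8.0
    biphasic = kin.ph_profile([6.5, 6.7, 7.0, 7.2, 7.8, 8.0],
                              [0.035, 0.05, 0.07, 0.035, 0.045, 0.106])
    assert biphasic["peaks"] == [7.0]
    assert biphasic["troughs"] == [7.2]
    assert biphasic["max_min_ratio"] > 3.0


def test_turnover_recovery_from_preset_plates():
    """Batch mean of seeded synthetic turnover plates recovers the preset
    mean within one generator SD in >= 90% of runs."""
    hits = 0
    runs = 50
    for seed in range(runs):
        plate = synth.gen_plate("apsac_t_ph8_mg", seed=seed)
        table = kin.turnover_table(plate)
        hits += abs(table["k_mean"].iloc[0] - 0.106) <= 0.041
    assert hits / runs >= 0.9


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_oracle(x, y):
    """Exact two-sided p by full enumeration (independent of the package)."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean = n1 * len(y) / 2
    us = []
    for comb in itertools.combinations(range(len(combined)), n1):
        us.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    return (np.abs(us - mean) >= abs(u_obs - mean) - 1e-12).mean()


def test_mwu_small_sample_exact():
    res = kin.mann_whitney_u([1, 2], [3, 4])
    assert res["U"] == 0.0
    assert res["p"] == pytest.approx(2 / 6)
    assert res["method"] == "exact"


def test_mwu_identical_samples():
    res = kin.mann_whitney_u([1.0, 1.0], [1.0, 1.0])
    assert res["p"] == 1.0 and res["degenerate"]
    res2 = kin.mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res2["p"] == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_mwu_exact_matches_permutation_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=4)
    y = rng.normal(loc=rng.uniform(0, 2), size=4)
    res = kin.mann_whitney_u(x, y)
    assert res["method"] == "exact"
    assert res["p"] == pytest.approx(_mwu_oracle(x, y))


def test_mwu_large_sample_matches_scipy_asymptotic():
    rng = np.random.default_rng(7)
    x = rng.normal(size=15)
    y = rng.normal(loc=0.8, size=15)
    res = kin.mann_whitney_u(x, y)
    assert res["method"] == "normal-approx"
    ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic")
    assert res["p"] == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def test_kruskal_identical_groups():
    res = kin.kruskal_wallis([[1, 1], [1, 1], [1, 1]])
    assert res["H"] == 0.0 and res["p"] == 1.0
    with pytest.raises(kin.InputError):
        kin.kruskal_wallis([[1, 2]])


def test_kruskal_statistic_matches_scipy_and_exact_p():
    rng = np.random.default_rng(3)
    groups = [rng.normal(size=2), rng.normal(size=2) + 1, rng.normal(size=2)]
    res = kin.kruskal_wallis(groups)
    assert res["method"] == "exact"
    assert res["H"] == pytest.approx(sps.kruskal(*groups).statistic)
    # independent permutation oracle on the H statistic
    combined = np.concatenate(groups)
    h_obs = sps.kruskal(*groups).statistic
    count = total = 0
    for perm in itertools.permutations(combined):
        g = [perm[0:2], perm[2:4], perm[4:6]]
        total += 1
        count += sps.kruskal(*g).statistic >= h_obs - 1e-12
    assert res["p"] == pytest.approx(count / total)


def test_kruskal_power_on_shifted_groups():
    """A 3-SD shift is detected at alpha=0.05 with power >= 0.9."""
    rejections = 0
    runs = 200
    for seed in range(runs):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(0, 1, 6), rng.normal(0, 1, 6),
                  rng.normal(3, 1, 6)]
        rejections += kin.kruskal_wallis(groups)["p"] < 0.05
    assert rejections / runs >= 0.9


def test_dunn_posthoc_flags_shifted_group():
    rng = np.random.default_rng(4)
    groups = [rng.normal(0, 1, 10), rng.normal(0, 1, 10),
              rng.normal(4, 1, 10)]
    table = kin.dunn_posthoc(groups, labels=["a", "b", "c"])
    assert set(table.columns) >= {"a", "b", "z", "p_raw", "p_adj"}
    sig = table[table["p_adj"] < 0.05]
    assert set(map(tuple, sig[["a", "b"]].values)) == {("a", "c"), ("b", "c")}
    assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_step_up_hand_example():
    np.testing.assert_allclose(
        kin.benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=30))
def test_bh_properties_hold_for_arbitrary_p_vectors(pvals):
    adj = kin.benjamini_hochberg(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0)
    # monotone nondecreasing in rank order of the raw p values
    order = np.argsort(pvals, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_edge_cases_and_invariances():
    assert kin.benjamini_hochberg([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(kin.benjamini_hochberg([1, 1, 1]), [1, 1, 1])
    rng = np.random.default_rng(8)
    p = rng.uniform(size=20)
    adj = kin.benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1)
    # order invariance
    perm = rng.permutation(20)
    np.testing.assert_allclose(kin.benjamini_hochberg(p[perm]), adj[perm])
    # independent cross-check
    from statsmodels.stats.multitest import multipletests
    np.testing.assert_allclose(
        adj, multipletests(p, method="fdr_bh")[1], atol=1e-12)
    with pytest.raises(kin.InputError):
        kin.benjamini_hochberg([0.5, 1.5])


# ---------------------------------------------------------------------------
# Mutant panel
# ---------------------------------------------------------------------------

def test_mutant_panel_null_and_empty():
    import pandas as pd
    plate = synth.gen_mutant_panel(seed=1)
    # a mutant literally identical to WT in every stratum
    wt = plate.wells[plate.wells["construct"] == "WT"]
    plate.wells = pd.concat([wt, wt.assign(construct="M1")])
    res = kin.compare_mutant_panel(plate)
    assert np.allclose(res.table["fold"], 1.0)
    assert np.allclose(res.table["p_adj"], 1.0)

    empty = kin.compare_mutant_panel(kin.PlateAssay(wells=pd.DataFrame(
        columns=["ph", "metal", "construct", "replicate", "camp_pmol"])))
    assert empty.table.empty


def test_mutant_panel_detects_planted_knockdown():
    """A 20-fold-down mutant is flagged at FDR 0.05 and unchanged mutants
    are not, in >= 95% of seeded runs."""
    detected = false_pos = 0
    runs = 60
    for seed in range(runs):
        plate = synth.gen_mutant_panel(
            seed=seed, mutant_folds={"down": 0.05, "same1": 1.0,
                                     "same2": 1.0})
        res = kin.compare_mutant_panel(plate)
        tab = res.table
        down_sig = (tab[tab["construct"] == "down"]["p_adj"] < 0.05).all()
        others_ns = (tab[tab["construct"] != "down"]["p_adj"] >= 0.05).all()
        detected += down_sig
        false_pos += not others_ns
    assert detected / runs >= 0.95
    assert false_pos / runs <= 0.25


def test_mutant_panel_skips_stratum_without_wt():
    import pandas as pd
    wells = pd.DataFrame([
        {"ph": 6.7, "metal": "Mg", "construct": "WT", "replicate": 0,
         "camp_pmol": 1.0},
        {"ph": 6.7, "metal": "Mg", "construct": "M", "replicate": 0,
         "camp_pmol": 1.1},
        {"ph": 8.0, "metal": "Mg", "construct": "M", "replicate": 0,
         "camp_pmol": 2.0},
    ])
    with pytest.warns(UserWarning, match="lacks wild-type"):
        res = kin.compare_mutant_panel(kin.PlateAssay(wells=wells))
    assert res.skipped_strata == [(8.0, "Mg")]
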