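"""Agreement statistics: ANOVA, ICC, Bland-Altman, pairing, strata."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfiquart.errors import DegenerateDataError, InsufficientDataError
from mfiquart.reliability import (
    AgreementStudy,
    RatingsMatrix,
    anova_two_way,
    bland_altman,
    classify_icc,
    icc_agreement,
    implied_mean_difference,
    pair_inter,
    pair_intra,
    stratified_reliability,
)
from mfiquart.tables import MeasurementTable


def full_design_table(n_subjects=10, quartiles=("Q1", "Q2", "Q3", "Q4"),
                      raters=("R1", "R2"), sessions=("S1", "S2"),
                      noise_sd=0.0, seed=0):
    """Complete factorial table: subjects x L1-L5 x sides x quartiles x raters x sessions."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        base = 20 + 10 * rng.standard_normal()
        for level, side, q in itertools.product(
            ("L1", "L2", "L3", "L4", "L5"), ("left", "right"), quartiles
        ):
            true = abs(base + 5 * rng.standard_normal())
            for rater, session in itertools.product(raters, sessions):
                rows.append({
                    "subject_id": f"P{s:03d}", "level": level, "side": side,
                    "quartile": q, "rater_id": rater, "session_id": session,
                    "mfi_percent": abs(true + noise_sd * rng.standard_normal()),
                })
    return MeasurementTable(pd.DataFrame(rows))


class TestAnova:
    def test_hand_decomposition(self):
        msr, msc, mse = anova_two_way(np.array([[1, 1], [2, 2], [3, 3.]]))
        assert (msr, msc, mse) == pytest.approx((2.0, 0.0, 0.0), abs=1e-14)

    def test_column_shift_changes_only_msc(self, rng):
        y = rng.normal(50, 5, (8, 3))
        msr, msc, mse = anova_two_way(y)
        y2 = y.copy()
        y2[:, 1] += 4.0
        msr2, msc2, mse2 = anova_two_way(y2)
        assert msr2 == pytest.approx(msr, rel=1e-12)
        assert mse2 == pytest.approx(mse, rel=1e-12)
        assert msc2 > msc

    def test_matches_double_loop_accumulation(self, rng):
        y = rng.normal(30, 4, (6, 2))
        n, k = y.shape
        grand = y.mean()
        ssr = ssc = sse = 0.0
        for i in range(n):
            ssr += k * (y[i].mean() - grand) ** 2
        for j in range(k):
            ssc += n * (y[:, j].mean() - grand) ** 2
        for i in range(n):
            for j in range(k):
                sse += (y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
        msr, msc, mse = anova_two_way(y)
        assert msr == pytest.approx(ssr / (n - 1), rel=1e-12)
        assert msc == pytest.approx(ssc / (k - 1), rel=1e-12)
        assert mse == pytest.approx(sse / ((n - 1) * (k - 1)), rel=1e-12)

    def test_too_small_grid_rejected(self):
        with pytest.raises(InsufficientDataError):
            anova_two_way(np.array([[1.0, 2.0]]))


class TestIcc:
    def test_identical_columns_icc_one_degenerate_ci(self):
        y = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        res = icc_agreement(y)
        assert res.icc == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)
        assert res.label == "excellent"

    def test_constant_matrix_undefined(self):
        with pytest.raises(DegenerateDataError):
            icc_agreement(np.full((5, 2), 7.0))

    def test_point_estimate_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(5):
            n, k = int(rng.integers(5, 30)), int(rng.integers(2, 4))
            y = rng.normal(50, 8, (n, 1)) + rng.normal(0, 2, (1, k)) \
                + rng.normal(0, 3, (n, k))
            df = pd.DataFrame({
                "t": np.repeat(np.arange(n), k),
                "r": np.tile(np.arange(k), n),
                "y": y.ravel(),
            })
            ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
            ref = ref.reset_index(drop=True)
            want_a1 = float(ref.iloc[1]["ICC"])   # single-measure absolute agreement
            want_c1 = float(ref.iloc[2]["ICC"])   # single-measure consistency
            assert icc_agreement(y).icc == pytest.approx(want_a1, abs=1e-10)
            assert icc_agreement(y, form="consistency").icc \
                == pytest.approx(want_c1, abs=1e-10)

    def test_constant_offset_to_all_cells_invariant(self, rng):
        y = rng.normal(40, 6, (12, 2))
        a = icc_agreement(y)
        b = icc_agreement(y + 17.3)
        assert b.icc == pytest.approx(a.icc, rel=1e-12)
        assert b.ci_low == pytest.approx(a.ci_low, rel=1e-10)

    def test_column_offset_lowers_agreement_icc(self, rng):
        # starting from aligned column means and genuine agreement
        # (MSR > MSE, i.e. a positive ICC numerator), a systematic rater
        # offset can only reduce absolute agreement; with a negative
        # numerator the larger denominator would pull the ICC toward zero,
        # and an offset could also cancel a pre-existing one
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = r.normal(0, 6, (15, 1)) + r.normal(40, 2, (15, 2))
            y = y - y.mean(axis=0, keepdims=True)
            y2 = y.copy()
            y2[:, 1] += 5.0
            assert icc_agreement(y2).icc <= icc_agreement(y).icc + 1e-12
            # the consistency form ignores the offset entirely
            assert icc_agreement(y2, form="consistency").icc == pytest.approx(
                icc_agreement(y, form="consistency").icc, rel=1e-12
            )

    def test_ci_brackets_point_estimate(self, rng):
        for _ in range(50):
            n, k = int(rng.integers(4, 40)), int(rng.integers(2, 5))
            y = rng.normal(0, 1, (n, 1)) * 3 + rng.normal(0, 1, (n, k))
            res = icc_agreement(y)
            assert res.ci_low <= res.icc <= res.ci_high

    def test_coverage_at_nominal_conditions(self):
        """95% CI covers a true ICC of 0.8 in 93-97% of 2000 two-way tables
        (n=30, k=2, variance components 4/0.25/0.75)."""
        true = 4 / 5.0
        rng = np.random.default_rng(77)
        hits = 0
        reps = 2000
        for _ in range(reps):
            y = 50 + rng.normal(0, 2.0, (30, 1)) \
                + rng.normal(0, 0.5, (1, 2)) + rng.normal(0, np.sqrt(0.75), (30, 2))
            res = icc_agreement(y)
            hits += res.ci_low <= true <= res.ci_high
        assert 0.93 <= hits / reps <= 0.97


class TestClassify:
    @pytest.mark.parametrize("value,label", [
        (0.82, "good"),        # the study's inter-rater headline value
        (0.90, "excellent"),
        (0.49999, "poor"),
        (0.50, "moderate"),
        (0.75, "good"),
        (1.0, "excellent"),
        (-0.2, "poor"),
    ])
    def test_bands(self, value, label):
        assert classify_icc(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.2)


class TestBlandAltman:
    def test_identical_pairs_zero_limits(self):
        res = bland_altman([(3.0, 3.0), (8.0, 8.0), (1.5, 1.5)])
        assert res.mean_diff == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)

    def test_plus_minus_one_differences(self):
        res = bland_altman([(1.0, 2.0), (2.0, 1.0)])
        assert res.mean_diff == 0.0
        assert res.sd_diff == pytest.approx(np.sqrt(2))
        assert res.loa_low == pytest.approx(-1.96 * np.sqrt(2))
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(2))

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([(1.0, 2.0)])

    @given(st.lists(
        st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=2, max_size=40,
    ))
    def test_structural_invariants(self, pairs):
        res = bland_altman(pairs)
        assert res.loa_low == pytest.approx(res.mean_diff - 1.96 * res.sd_diff)
        assert res.loa_high == pytest.approx(res.mean_diff + 1.96 * res.sd_diff)
        assert (res.loa_low + res.loa_high) / 2 == pytest.approx(res.mean_diff, abs=1e-9)

    def test_implied_mean_difference_from_printed_limits(self):
        assert implied_mean_difference(-5.48, 4.92, ndigits=2) == -0.28
        assert implied_mean_difference(-6.85, 5.90, ndigits=2) == -0.48


class TestPairing:
    def test_intra_two_raters_two_sessions_single_unit(self):
        rows = []
        for rater in ("R1", "R2"):
            for session, v in (("S1", 10.0), ("S2", 12.0)):
                rows.append(dict(subject_id="P1", level="L3", side="left",
                                 quartile="Q1", rater_id=rater,
                                 session_id=session, mfi_percent=v))
        m = pair_intra(MeasurementTable(pd.DataFrame(rows)))
        assert m.values.shape == (2, 2)
        assert m.design == "intra"
        assert m.n_dropped == 0

    def test_intra_incomplete_unit_dropped_per_rater(self):
        rows = []
        for rater in ("R1", "R2"):
            for session in ("S1", "S2"):
                if rater == "R2" and session == "S2":
                    continue  # R2 never did session 2
                rows.append(dict(subject_id="P1", level="L3", side="left",
                                 quartile="Q1", rater_id=rater,
                                 session_id=session, mfi_percent=10.0))
        # need a second complete unit so the matrix is valid
        for rater in ("R1", "R2"):
            for session in ("S1", "S2"):
                if rater == "R2" and session == "S2":
                    continue
                rows.append(dict(subject_id="P2", level="L3", side="left",
                                 quartile="Q1", rater_id=rater,
                                 session_id=session, mfi_percent=20.0))
        m = pair_intra(MeasurementTable(pd.DataFrame(rows)))
        assert m.values.shape == (2, 2)     # only R1's two units survive
        assert m.n_dropped == 2             # R2's two incomplete units

    def test_intra_full_design_row_count(self):
        table = full_design_table()
        m = pair_intra(table)
        assert m.values.shape == (800, 2)   # 10 x 5 x 2 x 4 units x 2 raters

    def test_inter_full_design_row_count(self):
        table = full_design_table()
        m = pair_inter(table)
        assert m.values.shape == (400, 2)
        assert m.design == "inter"

    def test_inter_single_rater_rejected(self):
        table = full_design_table(raters=("R1",))
        with pytest.raises(InsufficientDataError):
            pair_inter(table)

    def test_inter_session_selector(self):
        table = full_design_table(noise_sd=1.0)
        m1 = pair_inter(table, session="S1")
        m2 = pair_inter(table, session="S2")
        assert not np.allclose(m1.values, m2.values)
        df = table.df
        want = df[(df.session_id == "S2") & (df.subject_id == "P000")
                  & (df.level == "L1") & (df.side == "left")
                  & (df.quartile == "Q1")].set_index("rater_id")["mfi_percent"]
        idx = m2.unit_keys.index(("P000", "L1", "left", "Q1"))
        assert m2.values[idx, 0] == pytest.approx(want["R1"])
        assert m2.values[idx, 1] == pytest.approx(want["R2"])


class TestStratified:
    def test_noise_free_table_all_icc_one(self):
        table = full_design_table(n_subjects=4, noise_sd=0.0)
        out = stratified_reliability(table, "intra")
        ok = out[out.status == "ok"]
        assert len(ok) > 0
        assert np.allclose(ok["icc"], 1.0)

    def test_q1_pooled_stratum_unit_count(self):
        table = full_design_table()
        out = stratified_reliability(table, "intra")
        row = out[(out.quartile == "Q1") & (out.level == "L1-5")
                  & (out.side == "both")].iloc[0]
        assert row["n_units"] == 200        # 10 x 5 x 2 units x 2 raters

    def test_insufficient_strata_flagged_not_dropped(self):
        table = full_design_table(n_subjects=4, quartiles=("Q1",), noise_sd=0.5)
        out = stratified_reliability(table, "intra")
        q2 = out[(out.quartile == "Q2") & (out.level == "L1-5")].iloc[0]
        assert q2["status"].startswith("insufficient")
        assert np.isnan(q2["icc"])

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            stratified_reliability(full_design_table(n_subjects=3), "between")


class TestAgreementStudy:
    def test_fit_matches_direct_calls(self):
        table = full_design_table(n_subjects=6, noise_sd=1.0, seed=4)
        res = AgreementStudy(table, design="inter").fit()
        direct = icc_agreement(pair_inter(
            MeasurementTable(table.filter(quartile=["Q1", "Q2", "Q3", "Q4"]))
        ))
        assert res.overall.icc == pytest.approx(direct.icc, rel=1e-12)
        assert res.overall.ci_low == pytest.approx(direct.ci_low, rel=1e-10)

    def test_summary_contains_key_quantities(self):
        table = full_design_table(n_subjects=5, noise_sd=1.0, seed=2)
        res = AgreementStudy(table, design="intra").fit()
        text = res.summary()
        assert "ICC" in text and "Bland-Altman" in text
        assert f"{res.overall.icc:.3f}" in text

    def test_plot_draws_mean_and_loa_lines(self, tmp_path):
        table = full_design_table(n_subjects=5, noise_sd=1.0, seed=3)
        res = AgreementStudy(table, design="intra").fit()
        ax = res.plot_bland_altman(title="check")
        assert len(ax.lines) == 3  # mean + two LoA
        out = tmp_path / "ba.png"
        ax.figure.savefig(out)
        assert out.stat().st_size > 0


def test_ratings_matrix_rejects_missing_cells():
    with pytest.raises(InsufficientDataError):
        RatingsMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]), [(0,), (1,)], "intra")
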