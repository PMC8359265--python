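"""Group statistics: worked examples, oracles, and calibration spot-checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nmsn import stats as st

from conftest import SEED


def _null_baseline_table(rng, n=200):
    return pd.DataFrame(
        dict(
            group=rng.choice(["HV", "PD"], size=n),
            sex=rng.choice(["M", "F"], size=n),
            age=rng.normal(61, 9, size=n),
            y=rng.normal(0, 1, size=n),
        )
    )


class TestChiSquare:
    def test_sex_imbalance_worked_example(self):
        chi2, p = st.chi_square_proportions([[66, 33], [17, 24]])
        assert round(chi2, 3) == 7.630
        assert p == pytest.approx(0.005, abs=0.001)

    def test_proportional_table_gives_zero(self):
        chi2, _ = st.chi_square_proportions([[40, 60], [20, 30]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_cellwise_formula(self, rng):
        """Oracle: sum over cells of (O - E)^2 / E."""
        for _ in range(20):
            table = rng.integers(1, 60, size=(2, 2)).astype(float)
            chi2, _ = st.chi_square_proportions(table)
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row @ col / table.sum()
            assert chi2 == pytest.approx(((table - expected) ** 2 / expected).sum())

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            st.chi_square_proportions([[0, 0], [5, 10]])


class TestTTest:
    def test_identical_groups(self):
        t, p = st.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, _ = st.two_sample_t(a, b)
        pooled = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(pooled * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand)
        assert round(t, 3) == -3.674

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=6)
        t_ab, p_ab = st.two_sample_t(a, b)
        t_ba, p_ba = st.two_sample_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestNormalityGate:
    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            st.normality_gate([2.0] * 10)

    def test_size_limits(self):
        with pytest.raises(ValueError):
            st.normality_gate([1.0, 2.0])

    def test_gaussian_passes_most_seeds(self):
        passes = 0
        for s in range(100):
            x = np.random.default_rng(SEED + s).normal(size=500)
            _, _, ok = st.normality_gate(x)
            passes += ok
        assert passes >= 90

    def test_bimodal_fails(self):
        rng = np.random.default_rng(SEED)
        x = np.concatenate([rng.normal(-5, 1, 100), rng.normal(5, 1, 100)])
        _, p, ok = st.normality_gate(x)
        assert p < 0.05 and not ok


class TestCrossSectional:
    def test_location_invariance(self, rng):
        df = _null_baseline_table(rng)
        base = st.cross_sectional_model(df, "y")
        df2 = df.assign(y=df["y"] + 100.0)
        shifted = st.cross_sectional_model(df2, "y")
        np.testing.assert_allclose(base["f_stat"], shifted["f_stat"])

    def test_detects_one_sd_group_deficit(self):
        detected = 0
        reps = 50
        for s in range(reps):
            rng = np.random.default_rng(SEED + s)
            df = _null_baseline_table(rng, n=100)
            df.loc[df.group == "PD", "y"] -= 1.0
            res = st.cross_sectional_model(df, "y")
            p = float(res.loc[res.term == "group", "p_value"].iloc[0])
            detected += p < 0.001
        assert detected >= int(0.95 * reps)

    def test_effect_direction_sign(self, rng):
        df = _null_baseline_table(rng)
        df.loc[df.group == "PD", "y"] -= 2.0
        res = st.cross_sectional_model(df, "y")
        assert res.loc[res.term == "group", "effect_direction"].iloc[0] == -1.0

    def test_single_level_factor_rejected(self, rng):
        df = _null_baseline_table(rng)
        df["sex"] = "M"
        with pytest.raises(ValueError):
            st.cross_sectional_model(df, "y")


def _paired_table(rng, n_pd=40, n_hv=20, pd_change=0.0, hv_change=0.0, noise=1.0):
    rows = []
    for i in range(n_pd + n_hv):
        grp = "PD" if i < n_pd else "HV"
        v1 = rng.normal(10, 2)
        change = (pd_change if grp == "PD" else hv_change) + rng.normal(0, noise)
        rows.append(dict(subject_id=i, visit="V1", group=grp,
                         sex=("M" if i % 2 else "F"), age=rng.normal(60, 8), y=v1))
        rows.append(dict(subject_id=i, visit="V2", group=grp,
                         sex=("M" if i % 2 else "F"), age=rng.normal(60, 8), y=v1 + change))
    return pd.DataFrame(rows)


class TestLongitudinal:
    def test_no_change_gives_null_visit_effect(self, rng):
        df = _paired_table(rng, noise=1.0)
        wide = df.pivot(index="subject_id", columns="visit", values="y")
        df.loc[df.visit == "V2", "y"] = df.loc[df.visit == "V2", "subject_id"].map(wide["V1"]).to_numpy()
        res, _ = st.longitudinal_model(df, "y")
        visit = res[res.term == "visit"].iloc[0]
        assert visit["f_stat"] == 0.0
        assert visit["p_value"] == 1.0

    def test_missing_visit_excluded_and_counted(self, rng):
        df = _paired_table(rng)
        drop_ids = [0, 1, 2]
        df = df[~((df.subject_id.isin(drop_ids)) & (df.visit == "V2"))]
        _, n_excluded = st.longitudinal_model(df, "y")
        assert n_excluded == 3

    def test_detects_group_specific_decline(self):
        hits = 0
        reps = 40
        for s in range(reps):
            rng = np.random.default_rng(SEED + s)
            df = _paired_table(rng, n_pd=79, n_hv=32, pd_change=-1.0, hv_change=0.0, noise=1.0)
            res, _ = st.longitudinal_model(df, "y")
            row = res[res.term == "visit:group"].iloc[0]
            hits += row["p_value"] < 0.05
            assert row["effect_direction"] in (-1.0, 0.0, 1.0)
        assert hits >= int(0.8 * reps)

    def test_matches_pingouin_mixed_anova(self):
        """Oracle: established mixed-ANOVA implementation on a balanced toy
        without the age covariate (2 x 2: sex between, visit within)."""
        import pingouin as pg

        rng = np.random.default_rng(SEED)
        rows = []
        for i in range(12):
            sex = "M" if i < 6 else "F"
            v1, v2 = rng.integers(5, 20, size=2).astype(float)
            rows.append(dict(subject_id=i, visit="V1", sex=sex, y=v1))
            rows.append(dict(subject_id=i, visit="V2", sex=sex, y=v2))
        df = pd.DataFrame(rows)
        res, _ = st.longitudinal_model(df, "y", design="cohort2")
        ref = pg.mixed_anova(df, dv="y", within="visit", subject="subject_id", between="sex")
        for mine, theirs in [("sex", "sex"), ("visit", "visit"), ("visit:sex", "Interaction")]:
            f_mine = float(res.loc[res.term == mine, "f_stat"].iloc[0])
            f_ref = float(ref.loc[ref.Source == theirs, "F"].iloc[0])
            assert f_mine == pytest.approx(f_ref, rel=1e-6), mine

    def test_cell_with_too_few_subjects_rejected(self, rng):
        df = _paired_table(rng, n_pd=4, n_hv=4)
        df = df[~((df.group == "HV") & (df.sex == "F"))]
        with pytest.raises(ValueError, match="cell"):
            st.longitudinal_model(df, "y")


class TestScannerEffect:
    def test_equals_squared_t_on_two_groups(self, rng):
        df = pd.DataFrame(
            dict(scanner=np.repeat(["A", "B"], 15), y=rng.normal(size=30))
        )
        res = st.scanner_effect(df, "y")
        t, p_t = st.two_sample_t(df[df.scanner == "A"].y, df[df.scanner == "B"].y)
        assert res["f_stat"].iloc[0] == pytest.approx(t**2)
        assert res["p_value"].iloc[0] == pytest.approx(p_t)

    def test_detects_programmed_offset_in_majority(self):
        hits = 0
        reps = 100
        for s in range(reps):
            rng = np.random.default_rng(SEED + s)
            a = rng.normal(273.2, 48.4, size=41)
            b = rng.normal(273.2 * (1 - 0.094), 37.0, size=23)
            df = pd.DataFrame(dict(scanner=["A"] * 41 + ["B"] * 23, y=np.r_[a, b]))
            hits += st.scanner_effect(df, "y")["p_value"].iloc[0] < 0.05
        assert hits > reps / 2

    def test_single_scanner_rejected(self, rng):
        df = pd.DataFrame(dict(scanner=["A"] * 10, y=rng.normal(size=10)))
        with pytest.raises(ValueError):
            st.scanner_effect(df, "y")


class TestROC:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = ["HV"] * 3 + ["PD"] * 3
        assert st.roc_auc(scores, labels, "PD").auc == 1.0

    def test_uninformative_scores(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.choice(["PD", "HV"], size=4000)
        assert st.roc_auc(scores, labels, "PD").auc == pytest.approx(0.5, abs=0.05)

    def test_flip_disclosed_for_lower_pd_scores(self, rng):
        scores = np.r_[rng.normal(0, 1, 50), rng.normal(2, 1, 50)]
        labels = np.array(["PD"] * 50 + ["HV"] * 50)
        res = st.roc_auc(scores, labels, "PD")
        assert res.flipped
        assert res.auc > 0.5

    def test_matches_pairwise_enumeration(self, rng):
        """Oracle: Mann–Whitney identity by exhaustive (pos, neg) pairs, with ties."""
        for _ in range(20):
            n = int(rng.integers(6, 50))
            scores = rng.integers(0, 8, size=n).astype(float)  # force ties
            labels = rng.choice(["PD", "HV"], size=n)
            if len(set(labels)) < 2:
                continue
            pos = scores[labels == "PD"]
            neg = scores[labels == "HV"]
            wins = sum(
                1.0 if p > n_ else 0.5 if p == n_ else 0.0
                for p, n_ in itertools.product(pos, neg)
            )
            brute = wins / (len(pos) * len(neg))
            brute = max(brute, 1 - brute)
            assert st.roc_auc(scores, labels, "PD").auc == pytest.approx(brute)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            st.roc_auc([1.0, 2.0], ["PD", "PD"], "PD")


class TestPermutationCorrelation:
    def _table(self, rng, n=20):
        x = rng.normal(size=n)
        return pd.DataFrame(
            dict(m1=x, m2=rng.normal(size=n), m3=rng.normal(size=n), clin=x)
        )

    def test_perfect_correlation_minimal_p(self, rng):
        df = self._table(rng)
        res = st.correlation_with_permutation(df, ["m1", "m2"], ["clin"], n_perm=2000, seed=SEED)
        row = res[res.measure == "m1"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p_corrected"] <= 5 / 2001

    def test_corrected_dominates_raw(self, rng):
        df = self._table(rng)
        df["clin"] = rng.normal(size=len(df))
        res = st.correlation_with_permutation(
            df, ["m1", "m2", "m3"], ["clin"], n_perm=3000, seed=SEED
        )
        assert (res["p_corrected"] >= res["p_raw"] - 0.02).all()

    def test_matches_exhaustive_enumeration_at_n6(self):
        """Oracle: full 720-permutation enumeration."""
        rng = np.random.default_rng(SEED)
        df = pd.DataFrame(
            dict(m1=rng.normal(size=6), m2=rng.normal(size=6), clin=rng.normal(size=6))
        )
        res = st.correlation_with_permutation(df, ["m1", "m2"], ["clin"], n_perm=1000, seed=SEED)
        y = df["clin"].to_numpy()
        xs = [df[m].to_numpy() for m in ("m1", "m2")]
        null_max = [
            max(abs(sps.pearsonr(x, np.array(perm))[0]) for x in xs)
            for perm in itertools.permutations(y)
        ]
        for m, x in zip(("m1", "m2"), xs):
            obs = abs(sps.pearsonr(x, y)[0])
            p_enum = np.mean([v >= obs - 1e-12 for v in null_max])
            got = float(res.loc[res.measure == m, "p_corrected"].iloc[0])
            assert got == pytest.approx(p_enum)

    def test_constant_column_skipped_with_warning(self, rng):
        df = self._table(rng)
        df["m2"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            res = st.correlation_with_permutation(df, ["m1", "m2"], ["clin"], n_perm=1000, seed=SEED)
        assert set(res.measure) == {"m1"}

    def test_row_order_invariance(self, rng):
        df = self._table(rng)
        df["clin"] = df["m1"] * 0.5 + rng.normal(size=len(df))
        res1 = st.correlation_with_permutation(df, ["m1", "m2"], ["clin"], n_perm=2000, seed=SEED)
        res2 = st.correlation_with_permutation(
            df.sample(frac=1.0, random_state=0), ["m1", "m2"], ["clin"], n_perm=2000, seed=SEED
        )
        np.testing.assert_allclose(res1["r"], res2["r"], atol=1e-12)
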