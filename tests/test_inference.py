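"""Mixed models, ANOVA, group tests, clearance arithmetic."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from threatphys.design import Phase, generate_trial_sequence
from threatphys.inference import (ModelSpec, RankDeficientDesign,
                                  build_contrasts, clearance_fraction,
                                  compare_groups, effect_tables_both_contrasts,
                                  fit_lme, fit_rm_anova)


def _trial_table(n_per_group=10, cs_effect=0.0, drug_cs=0.0, noise=0.4,
                 subject_sd=0.5, trend=0.0, seed=0, phase=Phase.RETENTION):
    """Trialwise amplitudes over realistic randomized sequences."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(2 * n_per_group):
        grp = "drug" if p >= n_per_group else "placebo"
        b = rng.normal(0, subject_sd)
        seq = generate_trial_sequence(phase, seed * 7919 + p, with_timing=False)
        for t in seq:
            plus = t.cs.value != "CS-"
            mu = (1.0 + b + cs_effect * plus
                  + (drug_cs if grp == "drug" and plus else 0.0)
                  + trend * t.index)
            rows.append(dict(participant=f"s{p:03d}", group=grp,
                             trial=t.index, cs=t.cs.value,
                             amplitude=mu + rng.normal(0, noise)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contrasts

def test_contrast_values_on_toy_means():
    df = pd.DataFrame(dict(cs=["CSr+", "CSn+", "CS-"], amplitude=[2., 2., 1.]))
    out = build_contrasts(df)
    X = np.column_stack([np.ones(3), out["cs_plus_vs_minus"],
                         out["csr_vs_csn"]])
    beta = np.linalg.solve(X, out["amplitude"].to_numpy())
    # coded slopes recover mean(CS+) - CS- = 1 and CSr+ - CSn+ = 0
    assert beta[1] * 1.5 == pytest.approx(1.0)
    assert beta[2] == pytest.approx(0.0)


def test_contrast_columns_orthogonal_on_balanced_data():
    df = build_contrasts(pd.DataFrame(dict(cs=["CSr+", "CSn+", "CS-"] * 15)))
    assert df["cs_plus_vs_minus"] @ df["csr_vs_csn"] == pytest.approx(0.0)
    assert df["cs_plus_vs_minus"].sum() == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# LME

def test_lme_reproduces_table_row_structure():
    tab = _trial_table(n_per_group=20)
    eff = effect_tables_both_contrasts(tab, ModelSpec())
    names = set(eff["effect"])
    for want in ("drug", "CS+ vs CS-", "time", "drug:CS+ vs CS-",
                 "drug:time", "CS+ vs CS-:time", "drug:CS+ vs CS-:time",
                 "CSr+ vs CSn+", "drug:CSr+ vs CSn+"):
        assert want in names
    assert (eff["F"] >= 0).all()
    assert eff["p"].between(0, 1).all()


def test_lme_matches_lmerTest_oracle():
    """Independent oracle: lme4 + lmerTest Satterthwaite F table."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    tab = _trial_table(n_per_group=6, cs_effect=0.3, drug_cs=0.3, seed=3)
    spec = ModelSpec(include_time=False)
    eff = fit_lme(build_contrasts(tab), spec, "cs_plus_vs_minus")
    script = r"""
suppressMessages({library(lme4); library(lmerTest)})
d <- read.delim("%s")
d$c1 <- ifelse(d$cs=="CS-", -1, 0.5)
d$drugc <- ifelse(d$group=="placebo", -0.5, 0.5)
m <- lmer(amplitude ~ drugc*c1 + (1|participant), data=d)
a <- anova(m)
write.csv(data.frame(F=a$`F value`, df=a$DenDF), "%s", row.names=FALSE)
"""
    import tempfile, os
    with tempfile.TemporaryDirectory() as td:
        dpath = os.path.join(td, "d.tsv")
        rpath = os.path.join(td, "out.csv")
        tab.to_csv(dpath, sep="\t", index=False)
        subprocess.run(["Rscript", "-e", script % (dpath, rpath)], check=True,
                       capture_output=True)
        r = pd.read_csv(rpath)
    ours = eff.set_index("effect")
    for i, name in enumerate(["drug", "cs", "drug:cs"]):
        assert ours.loc[name, "F"] == pytest.approx(r["F"][i], rel=1e-3)
        assert ours.loc[name, "df_den"] == pytest.approx(r["df"][i], rel=0.01)


def test_lme_recovers_known_drug_cs_effect():
    tab = _trial_table(n_per_group=12, cs_effect=0.3, drug_cs=0.4, seed=5)
    eff = fit_lme(build_contrasts(tab), ModelSpec(include_time=False),
                  "cs_plus_vs_minus")
    row = eff.set_index("effect").loc["drug:cs"]
    assert row["p"] < 0.001


def test_lme_tolerates_unbalanced_missing_trials():
    tab = _trial_table(n_per_group=20, cs_effect=0.3, seed=6)
    tab = tab.drop(tab.sample(frac=0.15, random_state=1).index)
    tab.loc[tab.sample(frac=0.05, random_state=2).index, "amplitude"] = np.nan
    eff = effect_tables_both_contrasts(tab, ModelSpec())
    assert np.isfinite(eff["F"]).all()


def test_lme_rank_deficiency_detected():
    tab = _trial_table(n_per_group=2)
    with pytest.raises(RankDeficientDesign):
        fit_lme(build_contrasts(tab), ModelSpec(include_time=True),
                "cs_plus_vs_minus")


def test_lme_balanced_equals_rm_anova_for_same_contrast():
    """Degenerate equivalence: balanced complete two-condition data, random
    intercept only — the LME F reproduces the split-plot ANOVA F."""
    rng = np.random.default_rng(2)
    rows = []
    for p in range(20):
        grp = "drug" if p >= 10 else "placebo"
        b = rng.normal(0, 0.8)
        for c, mu in (("CS-", 0.0), ("CSr+", 0.4)):
            rows.append(dict(participant=f"s{p}", group=grp, cs=c, trial=1,
                             amplitude=1 + b + mu + rng.normal(0, 0.3)))
    tab = pd.DataFrame(rows)
    tab["c"] = np.where(tab["cs"] == "CS-", -0.5, 0.5)   # centered code
    eff = fit_lme(tab, ModelSpec(include_time=False), "c").set_index("effect")
    aov = fit_rm_anova(tab).set_index("effect")
    assert eff.loc["cs", "F"] == pytest.approx(aov.loc["c1", "F"], rel=0.01)
    assert eff.loc["drug:cs", "F"] == pytest.approx(
        aov.loc["group x c1", "F"], rel=0.01)
    assert eff.loc["drug", "F"] == pytest.approx(aov.loc["group", "F"],
                                                 rel=0.01)


def test_covariate_leaves_drug_cs_effect_qualitatively_unchanged():
    tab = _trial_table(n_per_group=12, cs_effect=0.3, drug_cs=0.4, seed=8)
    rng = np.random.default_rng(9)
    cov = {p: rng.normal(0, 1) for p in tab["participant"].unique()}
    tab["psr_covariate"] = tab["participant"].map(cov)
    base = fit_lme(build_contrasts(tab), ModelSpec(include_time=False),
                   "cs_plus_vs_minus").set_index("effect")
    with_cov = fit_lme(build_contrasts(tab),
                       ModelSpec(include_time=False,
                                 covariates=["psr_covariate"]),
                       "cs_plus_vs_minus").set_index("effect")
    assert (base.loc["drug:cs", "p"] < 0.05) == \
        (with_cov.loc["drug:cs", "p"] < 0.05)
    assert with_cov.loc["drug:cs", "F"] == pytest.approx(
        base.loc["drug:cs", "F"], rel=0.25)


# ---------------------------------------------------------------------------
# rm-ANOVA

def test_two_condition_paired_f_equals_squared_t():
    rng = np.random.default_rng(4)
    n = 14
    a = rng.normal(0, 1, n)
    b = a + 0.5 + rng.normal(0, 0.5, n)
    rows = [dict(participant=i, cs=c, amplitude=v)
            for i, (x, y) in enumerate(zip(a, b))
            for c, v in (("A", x), ("B", y))]
    res = fit_rm_anova(pd.DataFrame(rows), group_col=None)
    t = stats.ttest_rel(a, b)
    assert res.loc[0, "F"] == pytest.approx(t.statistic ** 2)
    assert res.loc[0, "p"] == pytest.approx(t.pvalue)


def test_mixed_anova_cross_checked_against_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    rows = []
    for p in range(30):
        grp = "drug" if p >= 15 else "placebo"
        b = rng.normal(0, 1)
        for c, mu in (("CS-", 0.0), ("CSr+", 0.5), ("CSn+", 0.6)):
            rows.append(dict(participant=p, group=grp, cs=c,
                             amplitude=b + mu + rng.normal(0, 0.4)))
    df = pd.DataFrame(rows)
    ours = fit_rm_anova(df).set_index("effect")
    ref = pg.mixed_anova(data=df, dv="amplitude", within="cs",
                         subject="participant", between="group")
    # group main effect identical; our two 1-df contrasts partition the
    # omnibus within-subject effect (sum of contrast SS = omnibus SS)
    assert ours.loc["group", "F"] == pytest.approx(
        float(ref.loc[ref.Source == "group", "F"].iloc[0]))
    omnibus = float(ref.loc[ref.Source == "cs", "F"].iloc[0])
    partition = (ours.loc["CS+ vs CS-", "F"] + ours.loc["CSr+ vs CSn+", "F"]) / 2
    assert partition == pytest.approx(omnibus, rel=1e-6)


def test_rm_anova_table_mirrors_conditionwise_layout():
    rng = np.random.default_rng(1)
    rows = [dict(participant=p, group="drug" if p % 2 else "placebo", cs=c,
                 amplitude=rng.normal())
            for p in range(78) for c in ("CS-", "CSr+", "CSn+")]
    res = fit_rm_anova(pd.DataFrame(rows))
    assert list(res["effect"]) == ["group", "CS+ vs CS-",
                                   "group x CS+ vs CS-", "CSr+ vs CSn+",
                                   "group x CSr+ vs CSn+"]
    assert res.set_index("effect").loc["group", "df_den"] == 76
    assert res.set_index("effect").loc["CS+ vs CS-", "df_den"] == 152


# ---------------------------------------------------------------------------
# t tests and clearance

def test_identical_groups_give_t_zero_p_one():
    v = np.r_[np.ones(5), np.ones(5)]
    t, df, p = compare_groups(v, np.r_[["a"] * 5, ["b"] * 5])
    assert t == 0.0 and p == 1.0 and df == 8


def test_two_sample_t_matches_hand_computation():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
    t, df, p = compare_groups(np.r_[a, b], np.r_[["x"] * 3, ["y"] * 3])
    sp = np.sqrt(((a.var(ddof=1) + b.var(ddof=1)) / 2) * (2 / 3))
    assert t == pytest.approx((a.mean() - b.mean()) / sp)
    assert df == 4
    assert p == pytest.approx(2 * stats.t.sf(abs(t), 4))


def test_paired_t_variant():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = a + np.array([0.5, 0.7, 0.4, 0.6])
    vals = np.r_[a, b]
    labs = np.r_[["pre"] * 4, ["post"] * 4]
    t, df, p = compare_groups(vals, labs, paired=True)
    ref = stats.ttest_rel(a, b)
    assert t == pytest.approx(ref.statistic) and df == 3


@pytest.mark.parametrize("half_life,elapsed,want", [
    (16.0, 0.0, 0.0),
    (16.0, 16.0, 0.5),
    (16.0, 32.0, 0.75),
])
def test_clearance_exact_values(half_life, elapsed, want):
    assert clearance_fraction(half_life, elapsed) == pytest.approx(want)


def test_clearance_week_after_ingestion_exceeds_999_per_mille():
    assert clearance_fraction(16.0, 168.0) > 0.999


def test_clearance_invalid_inputs():
    with pytest.raises(ValueError):
        clearance_fraction(0.0, 10.0)
    with pytest.raises(ValueError):
        clearance_fraction(16.0, -1.0)
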