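"""Read counting, median-of-ratios normalization, and the test battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retrocensus.expression import (
    boxcox_transform,
    count_reads,
    normalize_counts,
    nrc_rel,
    size_factors,
    stage_profile,
)
from retrocensus.expression import test_element as run_battery
from retrocensus.simulate import CountSimSpec, simulate_counts, simulate_reads


def _random_elements(rng, n, length=1500):
    return {f"e{i}": "".join(rng.choice(list("ACGT"), length)) for i in range(n)}


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def test_error_free_reads_count_on_their_element(rng):
    els = _random_elements(rng, 3)
    reads = simulate_reads(els, {"e0": 1.0}, read_len=50, n_reads=200, seed=1)
    counts = count_reads(reads, els)
    assert counts["e0"] == 200
    assert counts["e1"] == 0 and counts["e2"] == 0


def test_multi_hit_policy_increments_all_equal_hits(rng):
    shared = "".join(rng.choice(list("ACGT"), 400))
    els = {"a": shared, "b": shared}  # identical elements
    reads = simulate_reads({"a": shared}, {"a": 1.0}, read_len=50, n_reads=10, seed=2)
    counts = count_reads(reads, els)
    assert counts["a"] == 10 and counts["b"] == 10  # each hit incremented
    frac = count_reads(reads, els, fractional=True)
    assert frac["a"] == pytest.approx(5.0) and frac["b"] == pytest.approx(5.0)


def test_max_hits_cap(rng):
    shared = "".join(rng.choice(list("ACGT"), 300))
    els = {f"e{i:02d}": shared for i in range(25)}
    reads = [("r0", shared[:50])]
    counts = count_reads(reads, els, max_hits=20)
    assert counts.sum() == 20  # capped at the 20 best


def test_count_proportions_follow_abundances(rng):
    els = _random_elements(rng, 3, length=2000)
    props = {"e0": 0.5, "e1": 0.3, "e2": 0.2}
    n = 5000
    reads = simulate_reads(els, props, read_len=50, n_reads=n, error_rate=0.005, seed=3)
    counts = count_reads(reads, els)
    for k, p in props.items():
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts[k] - n * p) < 3 * sigma


def test_unmatched_reads_ignored(rng):
    els = _random_elements(rng, 1)
    reads = [("junk", "".join(rng.choice(list("ACGT"), 50)))]
    assert count_reads(reads, els).sum() == 0


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_size_factors_scaling(rng):
    base = rng.integers(10, 200, size=50)
    counts = pd.DataFrame({"s1": base, "s2": 2 * base})
    s = size_factors(counts)
    assert s["s2"] / s["s1"] == pytest.approx(2.0)


def test_size_factors_identical_samples(rng):
    base = rng.integers(10, 200, size=30)
    counts = pd.DataFrame({"s1": base, "s2": base, "s3": base})
    s = size_factors(counts)
    assert np.allclose(s, s.iloc[0])


def test_size_factors_require_positive_reference():
    counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
    with pytest.raises(ValueError, match="size factors"):
        size_factors(counts)


def test_size_factor_recovery_from_nb_simulation(rng):
    planted = np.array([1.0, 1.5, 0.7])
    means = rng.uniform(20, 300, size=(2000, 1))
    spec = CountSimSpec(means=means, groups=[0, 0, 0], size_factors=planted, alpha=0.05)
    counts, _ = simulate_counts(spec, seed=13)
    s = size_factors(counts)
    ratios = (s / s.iloc[0]).to_numpy()
    expected = planted / planted[0]
    assert np.all(np.abs(ratios - expected) / expected < 0.05)


def test_size_factors_match_pydeseq2(rng):
    from pydeseq2.preprocessing import deseq2_norm

    counts = pd.DataFrame(rng.integers(1, 500, size=(100, 4)),
                          columns=list("abcd"))
    ours = size_factors(counts)
    _, theirs = deseq2_norm(counts.T)  # pydeseq2 wants samples x genes
    assert np.allclose(ours.to_numpy(), np.asarray(theirs), rtol=1e-9)


def test_normalization_idempotent(rng):
    base = rng.integers(50, 500, size=40).astype(float)
    counts = pd.DataFrame({"s1": base, "s2": 3 * base, "s3": 0.5 * base})
    norm = normalize_counts(counts)
    s_again = size_factors(norm.nrc)
    assert np.allclose(s_again, 1.0, atol=1e-9)


def test_nrc_rel_arithmetic():
    assert np.allclose(nrc_rel(np.array([2.0, 4.0, 6.0])), [0.5, 1.0, 1.5])
    assert np.allclose(nrc_rel(np.array([7.0, 7.0])), 1.0)
    assert np.allclose(nrc_rel(np.zeros(3)), 0.0)


@given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=10))
def test_nrc_rel_mean_is_one(values):
    out = nrc_rel(np.array(values))
    assert out.mean() == pytest.approx(1.0)


def test_normalize_counts_flags_zero_rows(rng):
    base = rng.integers(10, 100, size=(20, 3))
    base[5, :] = 0
    counts = pd.DataFrame(base, columns=list("xyz"))
    norm = normalize_counts(counts)
    assert norm.nrc_rel.index[5] in norm.zero_elements
    expressed = norm.nrc_rel.drop(index=norm.zero_elements)
    assert np.allclose(expressed.mean(axis=1), 1.0)


# ---------------------------------------------------------------------------
# Transform-then-test battery
# ---------------------------------------------------------------------------

def test_identical_groups_anova_f_zero():
    res = run_battery({"g1": np.array([1.0, 2.0, 3.0]),
                        "g2": np.array([1.0, 2.0, 3.0])})
    assert res.test_used == "ANOVA"
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_constant_data_degenerate():
    res = run_battery({"g1": np.array([5.0, 5.0]), "g2": np.array([5.0, 5.0])})
    assert res.p_value == 1.0


def test_battery_validates_input():
    with pytest.raises(ValueError):
        run_battery({"g1": np.array([1.0, 2.0])})
    with pytest.raises(ValueError):
        run_battery({"g1": np.array([1.0]), "g2": np.array([2.0, 3.0])})


def test_boxcox_lambda_recovery_on_lognormal():
    rng = np.random.default_rng(17)
    x = np.exp(rng.normal(2.0, 0.6, size=500))
    _y, lam, shift = boxcox_transform(x)
    assert shift == 0.0
    assert abs(lam - 0.0) <= 0.15


def test_boxcox_shift_records_nonpositive_handling():
    x = np.array([-1.0, 0.0, 1.0, 2.0, 5.0])
    _y, _lam, shift = boxcox_transform(x)
    assert shift == pytest.approx(2.0)  # 1 - min


def _f_stat(groups):
    """Textbook one-way ANOVA F from sums of squares."""
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, n = len(groups), len(all_v)
    return (ssb / (k - 1)) / (ssw / (n - k))


def _kw_stat(groups):
    """Textbook Kruskal-Wallis H (no ties in the examples used)."""
    from scipy.stats import rankdata

    all_v = np.concatenate(groups)
    ranks = rankdata(all_v)
    n = len(all_v)
    h, at = 0.0, 0
    for g in groups:
        r = ranks[at:at + len(g)]
        at += len(g)
        h += r.sum() ** 2 / len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def test_statistics_agree_with_textbook_closed_forms():
    g1 = np.array([1.0, 2.0, 3.0, 4.0])
    g2 = np.array([6.0, 7.0, 9.0, 13.0])
    res = run_battery({"g1": g1, "g2": g2})
    pooled = np.concatenate([g1, g2])
    transformed, lam, _shift = boxcox_transform(pooled)
    assert lam == res.boxcox_lambda
    tg = [transformed[:4], transformed[4:]]
    if res.test_used == "ANOVA":
        assert res.statistic == pytest.approx(_f_stat(tg))
    else:
        assert res.statistic == pytest.approx(_kw_stat(tg))
    assert 0 <= res.shapiro_p <= 1 and 0 <= res.levene_p <= 1
    assert res.p_value < 0.05


def test_kruskal_type_one_error_calibrated():
    rng = np.random.default_rng(2024)
    n_sims = 400
    rejections = 0
    for _ in range(n_sims):
        groups = {g: rng.exponential(1.0, size=8) for g in ("a", "b", "c")}
        res = run_battery(groups)
        rejections += res.p_value < 0.05
    rate = rejections / n_sims
    assert 0.02 <= rate <= 0.08  # looser band at n_sims=400; tight band in acceptance


def test_planted_group_shift_detected():
    rng = np.random.default_rng(7)
    groups = {"a": rng.normal(10, 1, 6), "b": rng.normal(10, 1, 6),
              "c": rng.normal(50, 5, 6)}
    res = run_battery(groups)
    assert res.p_value < 0.01


# ---------------------------------------------------------------------------
# Stage profiles
# ---------------------------------------------------------------------------

def test_single_type_share_is_one():
    nrc = pd.DataFrame([[3.0, 5.0, 0.5]], index=["only"], columns=["s1", "s2", "s3"])
    prof = stage_profile(nrc, ["s1", "s2", "s3"])
    assert np.allclose(prof["only"], 1.0)


def test_stage_switch_plant_recovered():
    stages = [f"st{i}" for i in range(1, 24)]
    a = [10.0 if i <= 10 else 0.5 for i in range(1, 24)]
    b = [0.5 if i <= 10 else 10.0 for i in range(1, 24)]
    nrc = pd.DataFrame([a, b], index=["A", "B"], columns=stages)
    prof = stage_profile(nrc, stages)
    argmax = prof.idxmax(axis=1)
    for i, st_name in enumerate(stages, start=1):
        assert argmax[st_name] == ("A" if i <= 10 else "B")
    assert np.allclose(prof.sum(axis=1), 1.0)


def test_all_zero_stage_flagged_as_zeros():
    nrc = pd.DataFrame([[1.0, 0.0], [3.0, 0.0]], index=["A", "B"],
                       columns=["s1", "s2"])
    prof = stage_profile(nrc, ["s1", "s2"])
    assert np.allclose(prof.loc["s2"], 0.0)


def test_unknown_stage_rejected():
    nrc = pd.DataFrame([[1.0]], index=["A"], columns=["s1"])
    with pytest.raises(ValueError, match="stages"):
        stage_profile(nrc, ["s1", "s9"])
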