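"""Fixed-fixed sampler, sharedness profiles, HDCIs, null comparison."""

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

import sharedzotu as sz
from sharedzotu.nullmodel import (hdci, null_compare, quasi_swap,
                                  sample_fixed_fixed, sharedness)


def test_margins_always_preserved():
    rng = np.random.default_rng(4)
    for k in range(300):
        arr = (rng.random((25, 18)) < 0.25).astype(np.int64)
        m = sample_fixed_fixed(arr, k + 1)
        assert (m.sum(axis=1) == arr.sum(axis=1)).all()
        assert (m.sum(axis=0) == arr.sum(axis=0)).all()
        assert m.max() <= 1


def test_forced_configurations_returned_unchanged():
    """An all-ones row (or a single row/column) is forced by its margins."""
    arr = np.array([[1, 1, 1], [1, 0, 0]], dtype=np.int64)
    for s in range(20):
        m = sample_fixed_fixed(arr, s + 1)
        assert (m[0] == 1).all()
    single = np.array([[1, 0, 1]], dtype=np.int64)
    assert (sample_fixed_fixed(single, 3) == single).all()


def test_two_by_two_identity_is_a_fair_coin():
    """Margins (1,1)/(1,1) admit exactly two matrices; each appears with
    frequency 0.5 within Monte-Carlo tolerance."""
    arr = np.eye(2, dtype=np.int64)
    hits = sum(sample_fixed_fixed(arr, s + 1)[0, 0] == 1 for s in range(10000))
    assert abs(hits / 10000 - 0.5) < 0.05


@pytest.mark.parametrize("method", ["quasiswap", "curveball"])
def test_sampler_uniform_on_enumerable_margins(method, margin_enumerator):
    """On 3x3 margins (2,1,1)/(2,1,1) all satisfying matrices appear with
    equal frequency (chi-square)."""
    mats = margin_enumerator([2, 1, 1], [2, 1, 1])
    keys = {m.tobytes(): i for i, m in enumerate(mats)}
    counts = np.zeros(len(mats), dtype=int)
    n = 12000
    for s in range(n):
        m = sample_fixed_fixed(mats[0].astype(np.int64), s + 1, method=method)
        counts[keys[m.tobytes()]] += 1
    assert chisquare(counts).pvalue > 0.001


def test_quasi_swap_wrapper_preserves_labels(occurrence_builder):
    occ = occurrence_builder([[1, 0, 1], [0, 1, 1], [1, 1, 0]],
                             ["sp1", "sp1", "sp2"])
    out = quasi_swap(occ, seed=5)
    assert out.zotu_ids == occ.zotu_ids
    assert out.individual_ids == occ.individual_ids
    assert (out.presence.sum(axis=1) == occ.presence.sum(axis=1)).all()
    with pytest.raises(sz.ValidationError):
        bad = occ.presence.copy()
        sample_fixed_fixed(bad.to_numpy() * 2, 1)


def test_sharedness_profile_hand_tally(occurrence_builder):
    """6-ZOTU toy with hand-tallied span and Venn counts."""
    occ = occurrence_builder(
        [[1, 0, 0, 0],   # sp1 only
         [1, 1, 1, 0],   # sp1+sp2
         [0, 0, 1, 1],   # sp2+sp3
         [1, 0, 0, 1],   # sp1+sp3
         [1, 1, 1, 1],   # all three
         [0, 0, 0, 1]],  # sp3 only
        ["sp1", "sp2", "sp2", "sp3"])
    prof = sharedness(occ)
    assert prof.span_counts.tolist() == [2, 3, 1]
    assert prof.venn_counts[("sp1",)] == 1
    assert prof.venn_counts[("sp3",)] == 1
    assert prof.venn_counts[("sp1", "sp2")] == 1
    assert prof.venn_counts[("sp2", "sp3")] == 1
    assert prof.venn_counts[("sp1", "sp3")] == 1
    assert prof.venn_counts[("sp1", "sp2", "sp3")] == 1
    assert prof.total == 6
    # span totals equal venn totals aggregated by subset size
    for k in range(1, 4):
        agg = sum(v for s, v in prof.venn_counts.items() if len(s) == k)
        assert agg == prof.span_counts[k - 1]


def test_sharedness_extremes(occurrence_builder):
    allp = occurrence_builder(np.ones((5, 4), dtype=int),
                              ["a", "b", "c", "d"])
    assert sharedness(allp).span_counts.tolist() == [0, 0, 0, 5]
    singles = occurrence_builder(np.eye(4, dtype=int), ["a", "b", "c", "d"])
    assert sharedness(singles).span_counts.tolist() == [4, 0, 0, 0]


def test_hdci_examples_and_oracle():
    assert hdci([7.0] * 12) == (7.0, 7.0)
    assert hdci(np.arange(1, 101), mass=0.95) == (1.0, 95.0)
    with pytest.raises(ValueError):
        hdci([])

    def brute(values, mass):
        v = np.sort(np.asarray(values, float))
        n = len(v)
        m = int(np.ceil(mass * n))
        best = None
        for i in range(n - m + 1):
            w = v[i + m - 1] - v[i]
            if best is None or w < best[0] - 1e-15:
                best = (w, v[i], v[i + m - 1])
        return best[1], best[2]

    rng = np.random.default_rng(8)
    for n in (1, 2, 5, 37, 200):
        vals = rng.lognormal(0, 1, n)
        for mass in (0.5, 0.8, 0.95):
            assert hdci(vals, mass) == pytest.approx(brute(vals, mass))


def test_singleton_rows_make_null_degenerate(occurrence_builder):
    """Rows of sum 1 always land in exactly one species under any
    fixed-margin randomization: every HDCI collapses onto the observed."""
    rng = np.random.default_rng(3)
    arr = np.zeros((40, 12), dtype=int)
    arr[np.arange(40), rng.integers(0, 12, 40)] = 1
    arr = arr[:, arr.sum(axis=0) > 0]
    occ = occurrence_builder(arr, ["sp1", "sp2", "sp3"] * (arr.shape[1] // 3)
                             + ["sp1"] * (arr.shape[1] % 3))
    res = null_compare(occ, n_rand=200, seed=9)
    for name, rec in res.statistics.items():
        assert rec["lower"] == rec["upper"] == rec["observed"] == rec["mean"]
        assert not rec["exceeds"]


def test_single_species_observed_equals_null(occurrence_builder):
    occ = occurrence_builder([[1, 0, 1], [1, 1, 0]], ["one", "one", "one"])
    res = null_compare(occ, n_rand=50, seed=1)
    rec = res.statistics["span_1"]
    assert rec["observed"] == rec["mean"] == 2.0 and not rec["exceeds"]


def test_null_means_match_enumeration(occurrence_builder, margin_enumerator):
    """Null span means agree with the exhaustive uniform average over all
    margin-satisfying 6x6 matrices within 3 Monte-Carlo SEs."""
    arr = np.array([
        [1, 1, 0, 0, 0, 0],
        [0, 1, 1, 0, 0, 0],
        [0, 0, 1, 1, 0, 0],
        [0, 0, 0, 1, 1, 0],
        [0, 0, 0, 0, 1, 1],
        [1, 0, 0, 0, 0, 1],
    ])
    species = ["sp1", "sp1", "sp2", "sp2", "sp3", "sp3"]
    mats = margin_enumerator(arr.sum(axis=1).tolist(), arr.sum(axis=0).tolist())
    codes = np.array([0, 0, 1, 1, 2, 2])
    exact = np.zeros(3)
    for m in mats:
        span = np.zeros(m.shape[0], dtype=int)
        for s in range(3):
            span += m[:, codes == s].any(axis=1)
        exact += np.bincount(span, minlength=4)[1:4]
    exact /= len(mats)

    occ = occurrence_builder(arr, species)
    res = null_compare(occ, n_rand=1000, seed=17)
    for k in range(3):
        rec = res.statistics[f"span_{k + 1}"]
        se = rec["sd"] / np.sqrt(rec["n_rand"])
        assert abs(rec["mean"] - exact[k]) <= 3 * max(se, 1e-12), (k, rec, exact[k])


def test_quasiswap_and_curveball_agree_in_distribution():
    """Span-count distributions from the two samplers on a fixed 20x20
    matrix are statistically indistinguishable (two-sample KS)."""
    rng = np.random.default_rng(14)
    arr = (rng.random((20, 20)) < 0.3).astype(np.int64)
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    codes = np.arange(arr.shape[1]) % 4
    draws = {}
    for method in ("quasiswap", "curveball"):
        span1 = []
        for s in range(300):
            m = sample_fixed_fixed(arr, 1000 + s, method=method)
            span = np.zeros(m.shape[0], dtype=int)
            for g in range(4):
                span += m[:, codes == g].any(axis=1)
            span1.append((span == 1).sum())
        draws[method] = np.array(span1)
    assert ks_2samp(draws["quasiswap"], draws["curveball"]).pvalue > 0.01


def test_null_compare_proportions_mirror_counts(occurrence_builder):
    rng = np.random.default_rng(2)
    arr = (rng.random((30, 9)) < 0.3).astype(int)
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    ncol = arr.shape[1]
    occ = occurrence_builder(arr, [f"sp{j % 3}" for j in range(ncol)])
    res = null_compare(occ, n_rand=150, seed=6)
    total = sum(res.statistics[f"span_{k}"]["observed"] for k in (1, 2, 3))
    for k in (1, 2, 3):
        cnt = res.statistics[f"span_{k}"]
        prop = res.statistics[f"prop_{k}"]
        assert prop["observed"] == pytest.approx(cnt["observed"] / total)
        assert prop["exceeds"] == cnt["exceeds"]
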