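"""Histograms, Shannon and fuzzy entropies, and per-image feature records."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import drentropy as de
from drentropy.entropy import DegenerateHistogram


def shannon_oracle(p, base=2.0):
    """Term-by-term summation, independent of the vectorised implementation."""
    total = 0.0
    for pi in p:
        if pi > 0:
            total -= pi * math.log(pi, base)
    return total


def fuzzy_oracle(p, sigma, epsilon=0.0):
    """Straight-line re-implementation of the membership reweighting."""
    mean_level = sum(i * pi for i, pi in enumerate(p))
    weighted = []
    for i, pi in enumerate(p):
        if pi > epsilon:
            mu = math.exp(-((i - mean_level) ** 2) / (2 * sigma**2))
            weighted.append(pi * mu)
    total = sum(weighted)
    out = 0.0
    for w in weighted:
        q = w / total
        if q > 0:
            out -= q * math.log(q)
    return out


def random_histogram(rng, n=256, support=16):
    p = np.zeros(n)
    idx = rng.choice(n, size=support, replace=False)
    w = rng.random(support)
    p[idx] = w / w.sum()
    # exact renormalisation to satisfy the sum-to-one invariant
    p = p / p.sum()
    return de.Histogram(p=p, N=n)


class TestGrayHistogram:
    def test_four_pixel_example(self):
        img = np.array([[0, 0], [1, 1]])
        h = de.gray_histogram(img)
        assert h.p[0] == 0.5 and h.p[1] == 0.5
        assert h.p[2:].sum() == 0

    def test_counts_match_tally_loop(self, rng):
        img = rng.integers(0, 256, size=(8, 8))
        h = de.gray_histogram(img)
        tally = [0] * 256
        for v in img.ravel():
            tally[int(v)] += 1
        expected = [c / 64 for c in tally]
        np.testing.assert_allclose(h.p, expected, atol=0)

    def test_sums_to_one(self, rng):
        img = rng.integers(0, 256, size=(13, 7))
        assert de.gray_histogram(img).p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            de.gray_histogram(np.zeros((0, 4)))


class TestShannonEntropy:
    def test_known_values(self):
        two = de.Histogram(p=np.array([0.5, 0.5]), N=2)
        assert de.shannon_entropy(two) == pytest.approx(1.0, abs=1e-15)
        single = np.zeros(256)
        single[7] = 1.0
        assert de.shannon_entropy(de.Histogram(p=single, N=256)) == 0.0
        uniform = de.Histogram(p=np.full(256, 1 / 256), N=256)
        assert de.shannon_entropy(uniform) == pytest.approx(8.0, abs=1e-12)

    def test_matches_oracle(self, rng):
        for _ in range(20):
            h = random_histogram(rng)
            assert de.shannon_entropy(h) == pytest.approx(
                shannon_oracle(h.p), abs=1e-12
            )

    def test_natural_log_base(self, rng):
        h = random_histogram(rng)
        assert de.shannon_entropy(h, base=math.e) == pytest.approx(
            shannon_oracle(h.p, base=math.e), abs=1e-12
        )

    def test_uniform_is_maximal(self, rng):
        """Perturbing the uniform histogram can only lower the entropy."""
        n = 64
        uniform = de.Histogram(p=np.full(n, 1 / n), N=n)
        h_max = de.shannon_entropy(uniform)
        for _ in range(10):
            p = np.full(n, 1 / n) + rng.normal(0, 1e-3, n)
            p = np.abs(p)
            p /= p.sum()
            assert de.shannon_entropy(de.Histogram(p=p, N=n)) <= h_max + 1e-12


class TestFuzzyEntropy:
    def test_constant_image_is_zero(self):
        img = np.full((8, 8), 42)
        assert de.fuzzy_entropy(de.gray_histogram(img)) == 0.0

    def test_uniform_membership_reduces_to_shannon_nats(self, rng):
        m = de.MembershipSpec(kind="uniform", epsilon=0.0)
        for _ in range(20):
            h = random_histogram(rng)
            assert de.fuzzy_entropy(h, m) == pytest.approx(
                de.shannon_entropy(h, base=math.e), abs=1e-12
            )

    def test_matches_oracle_gaussian_membership(self, rng):
        m = de.MembershipSpec(sigma=255 / 4)
        for _ in range(20):
            h = random_histogram(rng)
            assert de.fuzzy_entropy(h, m) == pytest.approx(
                fuzzy_oracle(h.p, sigma=255 / 4), abs=1e-12
            )

    def test_epsilon_excludes_low_probability_bins(self, rng):
        h = random_histogram(rng, support=8)
        eps = float(np.sort(h.p[h.p > 0])[1])  # exclude the two smallest bins
        m = de.MembershipSpec(epsilon=eps)
        assert de.fuzzy_entropy(h, m) == pytest.approx(
            fuzzy_oracle(h.p, sigma=255 / 4, epsilon=eps), abs=1e-12
        )

    def test_all_bins_excluded_is_degenerate(self):
        p = np.zeros(256)
        p[10] = 1.0
        h = de.Histogram(p=p, N=256)
        with pytest.raises(DegenerateHistogram):
            de.fuzzy_entropy(h, de.MembershipSpec(epsilon=1.0))

    def test_membership_scale_invariance(self, rng):
        """Multiplying all memberships by a constant cancels in q_i."""
        h = random_histogram(rng)
        base = de.fuzzy_entropy(h, de.MembershipSpec(kind="uniform"))

        # uniform membership scaled by any c > 0 gives the same q_i, hence
        # the same entropy; emulate by noting mu_i = c cancels identically
        mu = np.full(h.N, 3.7)
        w = h.p * mu
        q = w[w > 0] / w.sum()
        manual = float(-(q * np.log(q)).sum())
        assert base == pytest.approx(manual, abs=1e-12)


class TestFeatureRecord:
    def test_standard_triple_yields_eight_values(self, rng):
        img = rng.integers(0, 256, size=(16, 16))
        rec = de.extract_feature_record(img)
        assert set(rec.values) == {"O", "g1", "g2", "g3"}
        row = rec.as_row()
        feature_cols = [k for k in row if k.startswith(("SE_", "FE_"))]
        assert len(feature_cols) == 8

    def test_constant_image_all_zero(self):
        rec = de.extract_feature_record(np.full((8, 8), 200))
        for se, fe in rec.values.values():
            assert se == 0.0 and fe == 0.0

    def test_level_g2_is_composition(self, rng):
        img = rng.integers(0, 256, size=(16, 16))
        rec = de.extract_feature_record(img)
        h = de.gray_histogram(de.gamma_transform(img, 1.65))
        assert rec.values["g2"][0] == pytest.approx(de.shannon_entropy(h), abs=1e-15)
        assert rec.values["g2"][1] == pytest.approx(de.fuzzy_entropy(h), abs=1e-15)

    def test_pixel_permutation_invariance(self, rng):
        img = rng.integers(0, 256, size=(16, 16))
        perm = rng.permutation(img.ravel()).reshape(img.shape)
        a = de.extract_feature_record(img).values
        b = de.extract_feature_record(perm).values
        for level in a:
            assert a[level] == b[level]

    def test_entropy_responds_to_gamma(self, two_class_set):
        rec = de.extract_feature_record(two_class_set.images[0])
        assert rec.values["g1"] != rec.values["g3"]

    def test_empty_or_invalid_gammas_rejected(self, rng):
        img = rng.integers(0, 256, size=(8, 8))
        with pytest.raises(ValueError):
            de.extract_feature_record(img, gammas=())
        with pytest.raises(ValueError):
            de.extract_feature_record(img, gammas=(0.9, -1.0))

    def test_feature_table_layout(self, two_class_set):
        table = de.build_feature_table(two_class_set)
        assert list(table.columns) == [
            "image_id", "label",
            "SE_O", "FE_O", "SE_g1", "FE_g1", "SE_g2", "FE_g2", "SE_g3", "FE_g3",
        ]
        assert len(table) == len(two_class_set)
        assert table.notna().all().all()
        assert (table["SE_O"] <= 8.0 + 1e-12).all() and (table["SE_O"] >= 0).all()
        assert (table["FE_O"] >= 0).all()


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=32))
def test_shannon_entropy_bounds_property(weights):
    """0 <= SE <= log2(N) for any normalized histogram."""
    p = np.zeros(256)
    w = np.asarray(weights)
    p[: len(w)] = w / w.sum()
    p /= p.sum()
    se = de.shannon_entropy(de.Histogram(p=p, N=256))
    assert -1e-12 <= se <= 8.0 + 1e-12
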