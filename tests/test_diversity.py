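"""Heterozygosity and Weir–Cockerham F_ST against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdstat.diversity import (
    expected_heterozygosity,
    observed_heterozygosity,
    pairwise_fst,
    weir_cockerham_components,
)
from herdstat.io import AlleleFrequencySet, allele_frequencies

from conftest import make_dataset


def wc_components_oracle(n, p, h):
    """Straight scalar transcription of the Weir–Cockerham a/b/c formulas
    for one marker over r groups — independent of the vectorized path."""
    r = len(n)
    nbar = sum(n) / r
    n_c = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / n_c) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


# -- heterozygosity ---------------------------------------------------------


@pytest.mark.parametrize("p,expected", [(0.5, 0.5), (0.1, 0.18), (0.0, 0.0), (1.0, 0.0)])
def test_expected_heterozygosity_closed_form(p, expected):
    freqs = AlleleFrequencySet([p, 0.5], [10, 10], scope="g")
    he = expected_heterozygosity(freqs)
    assert he.per_marker_expected[0] == pytest.approx(expected, abs=1e-15)
    assert (he.per_marker_expected <= 0.5 + 1e-15).all()


def test_observed_heterozygosity_examples():
    all_het = make_dataset([[1, 0], [1, 0], [1, 2], [1, 0]])
    ho = observed_heterozygosity(all_het)
    assert ho.per_marker_observed[0] == 1.0
    no_het = make_dataset([[0], [2], [0], [2]])
    assert observed_heterozygosity(no_het).per_marker_observed[0] == 0.0


def test_observed_heterozygosity_matches_hardy_weinberg(rng):
    # p = 0.3, n = 10,000 under HWE: mean H_obs ~ 2p(1-p) = 0.42
    data = make_dataset(rng.binomial(2, 0.3, (10_000, 50)).astype(float))
    ho = observed_heterozygosity(data)
    assert ho.mean_observed == pytest.approx(0.42, abs=0.005)


def test_observed_heterozygosity_excludes_all_missing_markers():
    data = make_dataset([[np.nan, 1], [np.nan, 0]])
    ho = observed_heterozygosity(data)
    assert ho.markers_excluded == 1
    assert len(ho.per_marker_observed) == 1


# -- Weir–Cockerham components ---------------------------------------------


def test_wc_matches_oracle_on_worked_example():
    n = np.array([[10.0, 10.0]])
    p = np.array([[0.6, 0.4]])
    h = np.array([[0.48, 0.48]])
    comp = weir_cockerham_components(n, p, h)
    a, b, c = wc_components_oracle([10, 10], [0.6, 0.4], [0.48, 0.48])
    assert comp.per_marker_a[0] == pytest.approx(a, abs=1e-12)
    assert comp.per_marker_b[0] == pytest.approx(b, abs=1e-12)
    assert comp.per_marker_c[0] == pytest.approx(c, abs=1e-12)
    assert comp.theta_w == pytest.approx(a / (a + b + c), abs=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.integers(2, 50),  # n per group
            st.floats(0.02, 0.98),  # p per group
        ),
        min_size=2,
        max_size=4,
    ),
)
def test_wc_matches_oracle_on_random_fixtures(data):
    n = [float(ni) for ni, _ in data]
    p = [pi for _, pi in data]
    # heterozygote proportion bounded by feasibility: h <= min(2p, 2(1-p))
    h = [min(2 * pi, 2 * (1 - pi)) * 0.7 for pi in p]
    comp = weir_cockerham_components(
        np.array([n]), np.array([p]), np.array([h])
    )
    a, b, c = wc_components_oracle(n, p, h)
    assert comp.per_marker_a[0] == pytest.approx(a, abs=1e-12)
    assert comp.per_marker_b[0] == pytest.approx(b, abs=1e-12)
    assert comp.per_marker_c[0] == pytest.approx(c, abs=1e-12)


@pytest.mark.parametrize("n_per_group", [2, 10, 37])
def test_fixed_difference_gives_theta_one(n_per_group):
    n = np.array([[float(n_per_group)] * 2])
    p = np.array([[1.0, 0.0]])
    h = np.array([[0.0, 0.0]])
    comp = weir_cockerham_components(n, p, h)
    assert comp.theta_w == 1.0


def test_monomorphic_markers_skipped_and_counted():
    n = np.array([[10.0, 10.0], [10.0, 10.0]])
    p = np.array([[0.0, 0.0], [0.3, 0.5]])
    h = np.array([[0.0, 0.0], [0.4, 0.5]])
    comp = weir_cockerham_components(n, p, h)
    assert comp.markers_used == 1 and comp.markers_skipped == 1
    with pytest.raises(ValueError):
        weir_cockerham_components(n[:1], p[:1], h[:1])


def test_theta_is_ratio_of_sums_not_mean_of_ratios():
    # two markers chosen so the two aggregation rules disagree
    n = np.array([[20.0, 20.0], [20.0, 20.0]])
    p = np.array([[0.9, 0.1], [0.55, 0.45]])
    h = np.array([[0.1, 0.1], [0.5, 0.5]])
    comp = weir_cockerham_components(n, p, h)
    per_marker = []
    for k in range(2):
        a, b, c = wc_components_oracle(list(n[k]), list(p[k]), list(h[k]))
        per_marker.append((a, b, c))
    sums = [sum(x) for x in zip(*per_marker)]
    ratio_of_sums = sums[0] / sum(sums)
    mean_of_ratios = np.mean([a / (a + b + c) for a, b, c in per_marker])
    assert abs(ratio_of_sums - mean_of_ratios) > 1e-3  # the rules differ here
    assert comp.theta_w == pytest.approx(ratio_of_sums, abs=1e-12)
    assert comp.theta_w != pytest.approx(mean_of_ratios, abs=1e-3)


def test_theta_invariant_to_allele_relabeling(rng):
    m = 30
    n = np.full((m, 2), 25.0)
    p = rng.uniform(0.1, 0.9, (m, 2))
    h = np.minimum(2 * p, 2 * (1 - p)) * rng.uniform(0.3, 0.9, (m, 2))
    base = weir_cockerham_components(n, p, h).theta_w
    flip = rng.random(m) < 0.5
    p2 = np.where(flip[:, None], 1.0 - p, p)
    assert weir_cockerham_components(n, p2, h).theta_w == pytest.approx(base, abs=1e-12)


# -- pairwise matrix --------------------------------------------------------


def test_pairwise_fst_symmetric_and_order_invariant(rng):
    dosA = rng.binomial(2, 0.7, (25, 300))
    dosB = rng.binomial(2, 0.3, (35, 300))
    data = make_dataset(np.vstack([dosA, dosB]), groups=["A"] * 25 + ["B"] * 35)
    mat = pairwise_fst(data)
    assert mat.values.loc["A", "B"] == mat.values.loc["B", "A"]
    shuffled = data.subset_samples(rng.permutation(data.n_samples))
    mat2 = pairwise_fst(shuffled, groups=["A", "B"])
    assert mat2.values.loc["A", "B"] == pytest.approx(
        mat.values.loc["A", "B"], abs=1e-12
    )


def test_duplicated_group_has_near_zero_theta(rng):
    dosages = rng.binomial(2, rng.uniform(0.1, 0.9, 2000), (120, 2000)).astype(float)
    labels = np.array(["X"] * 60 + ["Y"] * 60)
    data = make_dataset(dosages, groups=rng.permutation(labels))
    theta = pairwise_fst(data).values.loc["X", "Y"]
    assert -0.01 < theta < 0.005  # unbiased around 0; small negative allowed


def test_hierarchical_divergence_preserves_ordering(rng):
    # A and B split recently from one ancestor; C is distant: theta_AB < theta_AC
    from herdstat.simulate import DivergenceSimSpec, simulate_divergent_populations

    near = simulate_divergent_populations(
        DivergenceSimSpec(theta=0.02, n_per_population=100, n_markers=3000, seed=8)
    )
    far = simulate_divergent_populations(
        DivergenceSimSpec(theta=0.15, n_per_population=100, n_markers=3000, seed=9)
    )
    mat_near = pairwise_fst(near).values.iloc[0, 1]
    mat_far = pairwise_fst(far).values.iloc[0, 1]
    assert mat_near < mat_far


def test_singleton_group_pair_undefined(rng):
    dosages = rng.binomial(2, 0.5, (11, 100)).astype(float)
    data = make_dataset(dosages, groups=["A"] * 10 + ["B"])
    mat = pairwise_fst(data)
    assert np.isnan(mat.values.loc["A", "B"])


def test_fst_matrix_table_layout(rng):
    dosages = rng.binomial(2, 0.5, (30, 50)).astype(float)
    data = make_dataset(dosages, groups=["A"] * 10 + ["B"] * 10 + ["C"] * 10)
    tab = pairwise_fst(data).to_table(decimals=2)
    assert np.isnan(tab.loc["A", "A"])  # blank diagonal
    assert np.isnan(tab.loc["C", "A"])  # lower triangle blank
    assert not np.isnan(tab.loc["A", "C"])
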