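"""Pairwise LD, decay curves, non-syntenic floors and Ne trajectories."""

import numpy as np
import pandas as pd
import pytest

from herdstat.ld import (
    LDDecayCurve,
    full_depth_syntenic_markers,
    haplotype_r_squared,
    hill_robertson_correction,
    mean_adjacent_spacing,
    ne_from_ld,
    nonsyntenic_ld,
    pairwise_ld,
    sample_size_experiment,
    syntenic_decay,
)

from conftest import make_dataset


def test_identical_markers_give_r2_one(rng):
    col = rng.binomial(2, 0.5, 30).astype(float)
    data = make_dataset(np.column_stack([col, col]))
    rec = pairwise_ld(data, max_depth=1)
    assert rec.records["r_squared"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_r2_symmetric_and_relabel_invariant(rng):
    a = rng.binomial(2, 0.4, 80).astype(float)
    b = rng.binomial(2, 0.6, 80).astype(float)
    r_ab = pairwise_ld(make_dataset(np.column_stack([a, b])), 1).records["r_squared"][0]
    r_ba = pairwise_ld(make_dataset(np.column_stack([b, a])), 1).records["r_squared"][0]
    r_flip = pairwise_ld(make_dataset(np.column_stack([2 - a, b])), 1).records[
        "r_squared"
    ][0]
    assert r_ab == pytest.approx(r_ba, abs=1e-12)
    assert r_ab == pytest.approx(r_flip, abs=1e-12)


def test_monomorphic_pairs_skipped_and_counted(rng):
    X = np.column_stack(
        [rng.binomial(2, 0.5, 20), np.ones(20), rng.binomial(2, 0.5, 20)]
    ).astype(float)
    X[:, 1] = 2.0  # monomorphic marker
    rec = pairwise_ld(make_dataset(X), max_depth=2)
    assert rec.n_skipped == 2  # pairs (1,2) and (2,3)
    assert len(rec.records) == 1


def test_haplotype_formula_worked_example():
    # haplotype counts AB=40, Ab=10, aB=10, ab=40 over 100 gametes
    hapA = np.array([1] * 50 + [0] * 50)
    hapB = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
    assert haplotype_r_squared(hapA, hapB) == pytest.approx(0.36, abs=1e-12)


def test_dosage_estimator_converges_to_haplotype_r2(rng):
    # genotypes formed by random pairing of gametes drawn from the
    # AB=0.4/Ab=0.1/aB=0.1/ab=0.4 haplotype distribution
    n = 20_000
    hap_idx = rng.choice(4, size=2 * n, p=[0.4, 0.1, 0.1, 0.4])
    alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    gametes = alleles[hap_idx]
    genos = gametes[:n] + gametes[n:]
    data = make_dataset(genos.astype(float))
    r2 = pairwise_ld(data, 1).records["r_squared"][0]
    assert r2 == pytest.approx(0.36, abs=0.02)


def test_independent_loci_r2_near_zero(rng):
    n = 5000
    X = rng.binomial(2, 0.5, (n, 2)).astype(float)
    r2 = pairwise_ld(make_dataset(X), 1).records["r_squared"][0]
    assert r2 < 5.0 / n


# -- syntenic subsetting ----------------------------------------------------


def test_full_depth_count_matches_brute_force(rng):
    sizes = [7, 450, 23, 401, 120]
    chrom = np.concatenate([[f"c{i}"] * s for i, s in enumerate(sizes)])
    markers = pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(len(chrom))],
            "chrom": chrom,
            "pos": np.concatenate([1000 * (1 + np.arange(s)) for s in sizes]),
        }
    )
    for depth in (5, 100, 400):
        got = full_depth_syntenic_markers(markers, depth)
        brute = [
            i
            for i in range(len(chrom) - depth)
            if (chrom[i : i + depth + 1] == chrom[i]).all()
        ]
        np.testing.assert_array_equal(got, brute)
        expected = sum(max(0, s - depth) for s in sizes)
        assert len(got) == expected


def test_single_chromosome_boundary_arithmetic(rng):
    data = make_dataset(
        rng.binomial(2, 0.5, (24, 401)).astype(float),
        pos=55_000 * (1 + np.arange(401)),
    )
    rec = pairwise_ld(data, max_depth=400)
    curve = syntenic_decay(rec, data.markers)
    assert curve.n_full_depth_markers == 1
    assert len(curve.table) == 400
    assert curve.mean_adjacent_spacing == 55_000
    assert (np.diff(curve.table["distance_bp"]) > 0).all()


def test_decay_monotone_on_wright_fisher_panel():
    from herdstat.simulate import WrightFisherSimSpec, simulate_wright_fisher

    data, _ = simulate_wright_fisher(
        WrightFisherSimSpec(
            diploid_size=100, markers_per_chromosome=400, n_chromosomes=1,
            n_generations=100, seed=6,
        )
    )
    rec = pairwise_ld(data, max_depth=60)
    curve = syntenic_decay(rec, data.markers)
    r2 = curve.table["mean_r2"].to_numpy()
    # noisy per-depth means: compare smoothed thirds of the curve
    thirds = np.array_split(r2, 3)
    assert thirds[0].mean() > thirds[1].mean() > thirds[2].mean()
    assert thirds[2].mean() > 1.0 / data.n_samples / 2


# -- non-syntenic LD --------------------------------------------------------


def test_nonsyntenic_undefined_on_single_chromosome(rng):
    data = make_dataset(rng.binomial(2, 0.5, (10, 50)).astype(float))
    with pytest.raises(ValueError, match="undefined"):
        nonsyntenic_ld(pairwise_ld(data, 10))


def _independent_panel(rng, n, n_chrom=20, per_chrom=40):
    p = rng.uniform(0.1, 0.9, n_chrom * per_chrom)
    X = rng.binomial(2, p, (n, n_chrom * per_chrom)).astype(float)
    chrom = np.concatenate([[f"c{i}"] * per_chrom for i in range(n_chrom)])
    pos = np.tile(1000 * (1 + np.arange(per_chrom)), n_chrom)
    return make_dataset(X, chrom=list(chrom), pos=pos)


def test_nonsyntenic_floor_scales_inversely_with_n(rng):
    res = {}
    for n in (16, 64):
        data = _independent_panel(rng, n)
        res[n] = nonsyntenic_ld(pairwise_ld(data, 50)).mean_r2
    assert res[16] == pytest.approx(1 / 16, rel=0.2)
    assert res[64] == pytest.approx(1 / 64, rel=0.2)
    assert res[16] > res[64]


def test_sample_size_experiment_contract(rng):
    data = _independent_panel(rng, 64, n_chrom=10, per_chrom=30)
    tab1 = sample_size_experiment(data, [4, 5, 6], seed=3, max_depth=40)
    tab2 = sample_size_experiment(data, [4, 5, 6], seed=3, max_depth=40)
    pd.testing.assert_frame_equal(tab1, tab2)  # fixed seed -> identical table
    assert list(tab1["N"]) == [16, 32, 64]
    # N = full panel: no subsampling, equals the whole-panel non-syntenic mean
    full = nonsyntenic_ld(pairwise_ld(data, 40)).mean_r2
    assert tab1["mean_r2"].iloc[-1] == pytest.approx(full, abs=1e-12)
    with pytest.raises(ValueError):
        sample_size_experiment(data, [0.5], seed=3)
    with pytest.raises(ValueError):
        sample_size_experiment(data, [7], seed=3)


def test_hill_robertson_correction_modes():
    val, floored = hill_robertson_correction(0.30, 10)
    assert val == pytest.approx(0.20, abs=1e-12) and not floored
    val, floored = hill_robertson_correction(0.01, 10)
    assert val == 0.0 and floored
    raw, expect = hill_robertson_correction(0.30, 10, mode="report")
    assert raw == 0.30 and expect == pytest.approx(0.1)
    with pytest.raises(ValueError):
        hill_robertson_correction(0.3, 1)


def test_correction_removes_sampling_bias(rng):
    for n in (16, 64):
        data = _independent_panel(rng, n, n_chrom=10, per_chrom=30)
        res = nonsyntenic_ld(pairwise_ld(data, 40))
        corrected, _ = hill_robertson_correction(res.mean_r2, n)
        assert abs(corrected) < 0.6 / n  # bias gone to within sampling noise


# -- Ne ---------------------------------------------------------------------


def _curve(depths, r2, spacing):
    tab = pd.DataFrame(
        {
            "depth": depths,
            "distance_bp": np.asarray(depths) * spacing,
            "mean_r2": r2,
            "n_pairs": 100,
        }
    )
    return LDDecayCurve(table=tab, mean_adjacent_spacing=spacing, n_full_depth_markers=100)


def test_ne_worked_arithmetic():
    # r2 = 0.2 at 2.5 Mb -> c = 0.025 M, t = 20, Ne = 40
    traj = ne_from_ld(_curve([1], [0.2], 2_500_000))
    assert traj.current_t == pytest.approx(20.0)
    assert traj.current_ne == pytest.approx(40.0, abs=1e-10)
    # adjacent bin at 55 kb, r2 = 0.5 -> c = 5.5e-4, t ~ 909, Ne ~ 454.5
    traj2 = ne_from_ld(_curve([1], [0.5], 55_000), t_range=(2.0, 1000.0))
    assert traj2.table["t_generations"].iloc[0] == pytest.approx(909.0909, abs=0.01)
    assert traj2.table["ne"].iloc[0] == pytest.approx(454.5454, abs=0.01)


def test_ne_t_strictly_decreasing_and_flags():
    curve = _curve([1, 2, 5, 10], [0.5, 0.3, 1.0, 0.0], 1_000_000)
    traj = ne_from_ld(curve, t_range=(2.0, 1000.0))
    t = traj.table["t_generations"].to_numpy()
    assert (np.diff(t) < 0).all()
    flags = dict(zip(traj.table["depth"], traj.table["flag"]))
    assert flags[5] == "r2_one" and flags[10] == "r2_zero"
    assert traj.table.loc[traj.table["depth"] == 5, "ne"].iloc[0] == 0.0
    assert np.isnan(traj.table.loc[traj.table["depth"] == 10, "ne"].iloc[0])


def test_current_ne_bin_ties_to_smaller_t():
    # t = 25 and 15 are equidistant from 20: the smaller t wins
    spacing = 100_000
    depths = [20, 100 / 3]
    c = np.array(depths) * spacing * 1e-8
    t = 1 / (2 * c)  # 25 and 15
    curve = _curve(depths, [0.2, 0.1], spacing)
    traj = ne_from_ld(curve)
    assert traj.current_t == pytest.approx(min(t))


def test_mean_adjacent_spacing_ignores_chromosome_gaps():
    markers = pd.DataFrame(
        {
            "id": list("abcd"),
            "chrom": ["c1", "c1", "c2", "c2"],
            "pos": [100, 200, 1000, 1300],
        }
    )
    assert mean_adjacent_spacing(markers) == pytest.approx((100 + 300) / 2)
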