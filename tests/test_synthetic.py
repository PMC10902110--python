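import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from pondnet.raster import CLASS_CODES
from pondnet.resistance import classify, resistance_proportions
from pondnet.stats import abundance, fit_glm
from pondnet.synthetic import (
    INDICATOR_SPECIES,
    CommunityConfig,
    LandscapeConfig,
    default_class_mixture,
    generate_community,
    generate_landscape,
    generate_site_metrics,
    generate_sites,
    mixture_from_resistance_ratio,
)


# ------------------------------------------------------------- landscape


def test_degenerate_mixture_is_uniform():
    cfg = LandscapeConfig(50, 50, class_mixture={"grassland": 1.0}, seed=0)
    lc = generate_landscape(cfg)
    assert np.all(lc.values == CLASS_CODES["grassland"])


def test_mixture_reproduces_study_resistance_ratio():
    cfg = LandscapeConfig(200, 200, seed=1)
    lc = generate_landscape(cfg)
    rr = classify(lc)
    low, med, high = resistance_proportions(rr)
    assert abs(low - 0.142) < 0.03
    assert abs(med - 0.348) < 0.03
    assert abs(high - 0.510) < 0.03


def test_class_proportions_converge_on_large_grid():
    cfg = LandscapeConfig(500, 500, seed=2)
    lc = generate_landscape(cfg)
    mix = default_class_mixture()
    for cls, target in mix.items():
        emp = np.mean(lc.values == CLASS_CODES[cls])
        assert abs(emp - target) < 0.01, cls


def test_landscape_seeded_determinism():
    cfg = LandscapeConfig(80, 80, seed=5)
    a = generate_landscape(cfg)
    b = generate_landscape(cfg)
    np.testing.assert_array_equal(a.values, b.values)


def test_wetlands_form_contiguous_clusters():
    from scipy import ndimage

    cfg = LandscapeConfig(150, 150, wetland_cluster_count=4, seed=3)
    lc = generate_landscape(cfg)
    wet = lc.values == CLASS_CODES["wetlands"]
    labels, n = ndimage.label(wet, structure=np.ones((3, 3), int))
    sizes = np.sort(np.bincount(labels.ravel())[1:])[::-1]
    # a handful of large clusters rather than salt-and-pepper scatter
    assert n <= 12
    assert sizes[:4].sum() / wet.sum() > 0.8


def test_invalid_mixtures_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        LandscapeConfig(50, 50, class_mixture={"grassland": 0.5})
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        LandscapeConfig(50, 50, class_mixture={"grassland": -0.5, "water": 1.5})
    with pytest.raises(ValueError, match=">= 3"):
        LandscapeConfig(2, 50)


def test_mixture_from_ratio_sums_within_tiers():
    mix = mixture_from_resistance_ratio(0.2, 0.3, 0.5)
    assert mix["wetlands"] + mix["water"] == pytest.approx(0.2)
    assert mix["settlement"] + mix["transportation"] == pytest.approx(0.5)
    assert sum(mix.values()) == pytest.approx(1.0)


# ----------------------------------------------------------------- sites


def test_site_counts_and_types():
    lc = generate_landscape(LandscapeConfig(150, 150, seed=7))
    sites = generate_sites(lc, n_stormwater=41, n_natural=8, seed=8)
    assert len(sites) == 49
    assert (sites["type"] == "stormwater").sum() == 41
    assert (sites["type"] == "natural").sum() == 8
    assert sites["id"].is_unique
    assert len(sites[["x", "y"]].drop_duplicates()) == 49


def test_single_natural_site():
    lc = generate_landscape(LandscapeConfig(100, 100, seed=9))
    sites = generate_sites(lc, n_stormwater=0, n_natural=1, seed=10)
    assert len(sites) == 1
    assert sites.iloc[0]["type"] == "natural"


def test_sites_seeded_determinism():
    lc = generate_landscape(LandscapeConfig(100, 100, seed=11))
    a = generate_sites(lc, 10, 3, seed=12)
    b = generate_sites(lc, 10, 3, seed=12)
    pd.testing.assert_frame_equal(a, b)


def test_natural_sites_near_wetlands():
    from scipy import ndimage

    lc = generate_landscape(LandscapeConfig(150, 150, seed=13))
    sites = generate_sites(lc, 0, 8, seed=14)
    wet = lc.values == CLASS_CODES["wetlands"]
    near = ndimage.binary_dilation(wet, np.ones((3, 3), bool))
    nrows = lc.shape[0]
    for _, s in sites.iterrows():
        col = int(s["x"] / lc.cell_size)
        row = nrows - 1 - int(s["y"] / lc.cell_size)
        assert near[row, col]


def test_insufficient_room_raises_named_constraint():
    lc = generate_landscape(LandscapeConfig(20, 20, class_mixture={"grassland": 1.0}, seed=0))
    with pytest.raises(ValueError, match="wetland-adjacent"):
        generate_sites(lc, 0, 5, seed=1)
    with pytest.raises(ValueError, match="settlement-dominated"):
        generate_sites(lc, 5, 0, seed=1)


# ------------------------------------------------------------- community


def _null_config(n, seed):
    return CommunityConfig(
        n_sites=n,
        dragonfly_abundance_slope=0.0,
        damselfly_richness_slope=0.0,
        indicator_species_slope=0.0,
        seed=seed,
    )


def test_null_configuration_uncorrelated_with_connectivity():
    rng = np.random.default_rng(15)
    rejections = 0
    for _ in range(60):
        conn = rng.normal(size=60)
        cm = generate_community(conn, _null_config(60, int(rng.integers(2**31 - 1))))
        total = cm.counts.sum(axis=1).to_numpy(dtype=float)
        rejections += sps.pearsonr(total, conn).pvalue < 0.05
    assert rejections <= 9  # ~5% nominal; binomial upper band


def test_positive_slope_is_recoverable():
    rng = np.random.default_rng(16)
    conn = rng.normal(size=200)
    cfg = CommunityConfig(n_sites=200, dragonfly_abundance_slope=1.0, seed=17)
    cm = generate_community(conn, cfg)
    fit = fit_glm(abundance(cm, "Anisoptera"), conn)
    assert fit.slope > 0
    assert fit.p_value < 0.001


def test_poisson_limit_variance_to_mean():
    cfg = CommunityConfig(
        n_sites=2000,
        dragonfly_abundance_slope=0.0,
        damselfly_richness_slope=0.0,
        indicator_species_slope=0.0,
        dispersion=1e8,
        seed=18,
    )
    cm = generate_community(np.zeros(2000), cfg)
    counts = cm.counts.to_numpy(dtype=float)
    ratio = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
    assert np.all(np.abs(ratio - 1.0) < 0.15)


def test_low_dispersion_is_overdispersed():
    cfg = CommunityConfig(
        n_sites=2000,
        dragonfly_abundance_slope=0.0,
        damselfly_richness_slope=0.0,
        indicator_species_slope=0.0,
        dispersion=0.5,
        seed=19,
    )
    cm = generate_community(np.zeros(2000), cfg)
    counts = cm.counts.to_numpy(dtype=float)
    ratio = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
    assert np.all(ratio > 1.5)


def test_community_determinism_and_structure():
    conn = np.linspace(-1, 1, 30)
    cfg = CommunityConfig(n_sites=30, seed=20)
    a = generate_community(conn, cfg)
    b = generate_community(conn, cfg)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    assert INDICATOR_SPECIES in a.counts.columns
    assert a.suborder[INDICATOR_SPECIES] == "Anisoptera"
    assert (a.suborder == "Anisoptera").sum() == cfg.n_dragonfly_species
    assert (a.suborder == "Zygoptera").sum() == cfg.n_damselfly_species


def test_community_rejects_bad_inputs():
    cfg = CommunityConfig(n_sites=5, seed=0)
    with pytest.raises(ValueError, match="non-finite"):
        generate_community(np.array([0.0, 1.0, np.nan, 2.0, 3.0]), cfg)
    with pytest.raises(ValueError, match="n_sites"):
        generate_community(np.zeros(4), cfg)
    with pytest.raises(ValueError, match="dispersion"):
        CommunityConfig(n_sites=5, dispersion=0.0)


def test_visit_counts_sum_to_matrix():
    conn = np.linspace(-1, 1, 12)
    cfg = CommunityConfig(n_sites=12, seed=21)
    cm, visits = generate_community(conn, cfg, return_visits=True)
    assert visits.shape[0] == 2
    np.testing.assert_array_equal(visits.sum(axis=0), cm.counts.to_numpy())


# ---------------------------------------------------------- site metrics


def test_generate_site_metrics_structure():
    sites, metrics = generate_site_metrics(49, seed=22)
    assert len(sites) == 49
    assert len(metrics) == 98  # two scales
    m9 = metrics[metrics["scale_m"] == 900.0]
    nat = m9[m9["type"] == "natural"]
    sto = m9[m9["type"] == "stormwater"]
    assert nat["mean_current"].mean() > sto["mean_current"].mean()
    assert nat["n_neighbours"].mean() > sto["n_neighbours"].mean()
    r = sps.pearsonr(m9["mean_current"], m9["n_neighbours"]).statistic
    assert r > 0.3  # predictors are collinear, as in the field data
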