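"""Synthetic population, network, registry and RDS recruitment generators."""

import numpy as np
import pytest

from rdscompare import (
    AttributeSpec,
    PopulationConfig,
    RDSConfig,
    RegistryConfig,
    build_forest,
    filter_analysis_set,
    generate_network,
    generate_population,
    generate_study,
    load_config,
    munich2017,
    rds_weighted_proportion,
    rds_weights,
    records_from_frame,
    sample_registry,
    simulate_rds,
)
from rdscompare.errors import ConfigError, SamplingError
from rdscompare.synthetic import reported_network_size


def small_config(**kw):
    defaults = dict(
        size=3000,
        attributes=(
            AttributeSpec("grp", ("a", "b"), (0.6, 0.4), homophily=kw.pop("homophily", 0.0)),
        ),
        degree_mean_log=1.6,
        degree_sd_log=0.7,
        registry=RegistryConfig(draw=300, invalid_address_fraction=0.05,
                                response_intercept=kw.pop("response_intercept", 0.0)),
        rds=RDSConfig(n_seeds=8, acceptance_prob=kw.pop("acceptance_prob", 0.9),
                      target_size=kw.pop("target_size", 150)),
        random_seed=kw.pop("random_seed", 0),
    )
    defaults.update(kw)
    return PopulationConfig(**defaults)


class TestPopulation:
    def test_prevalence_concentrates(self):
        cfg = small_config(size=10_000, target_size=150, random_seed=1)
        pop = generate_population(cfg)
        share = (pop["grp"] == "a").mean()
        assert share == pytest.approx(0.6, abs=0.02)

    def test_certain_category(self):
        cfg = small_config(
            attributes=(AttributeSpec("grp", ("a", "b"), (1.0, 0.0)),)
        )
        pop = generate_population(cfg)
        assert (pop["grp"] == "a").all()

    def test_zero_size_rejected(self):
        with pytest.raises(ConfigError):
            small_config(size=0).validate()

    def test_bad_prevalences_rejected(self):
        with pytest.raises(ConfigError):
            small_config(
                attributes=(AttributeSpec("grp", ("a", "b"), (0.6, 0.6)),)
            ).validate()

    def test_integration_loading_orders_categories(self):
        cfg = small_config(
            attributes=(AttributeSpec("grp", ("lo", "hi"), (0.5, 0.5),
                                      integration_loading=1.5),),
            random_seed=3,
        )
        pop = generate_population(cfg)
        z_hi = pop.loc[pop["grp"] == "hi", "integration"].mean()
        z_lo = pop.loc[pop["grp"] == "lo", "integration"].mean()
        assert z_hi > z_lo + 0.3

    def test_population_size_floor_vs_target(self):
        with pytest.raises(ConfigError, match="10x"):
            small_config(size=1000, target_size=150).validate()


class TestNetwork:
    def test_every_node_has_degree_at_least_one(self):
        cfg = small_config(random_seed=2)
        pop = generate_population(cfg)
        net = generate_network(pop, cfg)
        assert min(dict(net.degree).values()) >= 1

    def _same_group_edge_fraction(self, net, pop):
        grp = pop["grp"].to_numpy()
        same = sum(grp[u] == grp[v] for u, v in net.edges)
        return same / net.number_of_edges()

    @pytest.mark.parametrize("seed", range(5))
    def test_no_homophily_matches_random_mixing(self, seed):
        cfg = small_config(homophily=0.0, random_seed=seed)
        pop = generate_population(cfg)
        net = generate_network(pop, cfg)
        # random stub matching: same-group fraction ~ sum of squared
        # *stub* shares (degree-weighted group shares)
        deg = pop["degree"].to_numpy()
        shares = np.array(
            [deg[(pop["grp"] == g).to_numpy()].sum() for g in ("a", "b")]
        ) / deg.sum()
        expected = float((shares**2).sum())
        assert self._same_group_edge_fraction(net, pop) == pytest.approx(
            expected, abs=0.04
        )

    def test_full_homophily_concentrates_edges_within_group(self):
        cfg = small_config(
            attributes=(AttributeSpec("grp", ("a", "b"), (0.5, 0.5),
                                      homophily=1.0),),
            random_seed=6,
        )
        pop = generate_population(cfg)
        net = generate_network(pop, cfg)
        assert self._same_group_edge_fraction(net, pop) > 0.9

    def test_reported_degree_noise_floor(self):
        cfg = small_config(degree_report_noise_sd=0.5, random_seed=4)
        pop = generate_population(cfg)
        net = generate_network(pop, cfg)
        rep = reported_network_size(net, cfg)
        assert rep.min() >= 1
        true = np.array([net.degree(v) for v in range(len(pop))])
        assert not np.array_equal(rep, true)


class TestRegistry:
    def test_zero_response_probability(self):
        cfg = small_config(response_intercept=-50.0)
        pop = generate_population(cfg)
        pr = sample_registry(pop, pop["degree"].to_numpy(), cfg)
        assert pr["responded"].sum() == 0
        assert len(pr) == 300

    def test_invited_count_in_expectation(self):
        # draw 400, invalid fraction 26/400: invited ~ 374 on average
        cfg = small_config(
            size=5000,
            registry=RegistryConfig(draw=400, invalid_address_fraction=26 / 400),
        )
        pop = generate_population(cfg)
        rep = pop["degree"].to_numpy()
        invited = [
            sample_registry(pop, rep, cfg, np.random.default_rng(s))["invited"].sum()
            for s in range(200)
        ]
        assert np.mean(invited) == pytest.approx(374, abs=2)

    def test_constant_response_rate_calibrates(self):
        # constant response probability 0.131: across replicates the mean
        # realised response sits within one point of 13.1%
        cfg = small_config(
            size=5000,
            registry=RegistryConfig(
                draw=400,
                invalid_address_fraction=0.0,
                response_intercept=float(np.log(0.131 / (1 - 0.131))),
            ),
        )
        pop = generate_population(cfg)
        rep = pop["degree"].to_numpy()
        rates = [
            sample_registry(pop, rep, cfg, np.random.default_rng(s))["responded"].mean()
            for s in range(1000)
        ]
        assert 100 * np.mean(rates) == pytest.approx(13.1, abs=1.0)

    def test_draw_larger_than_frame_rejected(self):
        cfg = small_config(
            registry=RegistryConfig(draw=2999, coverage_base=0.5,
                                    coverage_integration_loading=0.0)
        )
        pop = generate_population(cfg)
        with pytest.raises(SamplingError):
            sample_registry(pop, pop["degree"].to_numpy(), cfg)


class TestRDSRecruitment:
    def test_zero_acceptance_leaves_seeds_only(self):
        cfg = small_config(acceptance_prob=0.0)
        study = generate_study(cfg)
        assert len(study.rds) == cfg.rds.n_seeds
        assert (study.rds["recruiter_id"] == "").all()

    def test_out_degree_never_exceeds_coupon_limit(self):
        study = generate_study(small_config(random_seed=9))
        counts = study.rds["recruiter_id"].value_counts()
        counts = counts[counts.index != ""]
        assert counts.max() <= 3

    def test_nobody_recruited_twice(self):
        study = generate_study(small_config(random_seed=10))
        assert study.rds["participant_id"].is_unique

    def test_recruitment_is_degree_biased(self):
        """Mean true degree of recruited participants exceeds the population
        mean degree — the premise motivating inverse-degree weighting."""
        cfg = small_config(random_seed=11)
        pop = generate_population(cfg)
        net = generate_network(pop, cfg)
        rep = reported_network_size(net, cfg)
        pop_mean = np.mean([net.degree(v) for v in range(len(pop))])
        sample_means = []
        for s in range(20):
            rds = simulate_rds(pop, net, rep, cfg, np.random.default_rng(s))
            idx = pop.set_index("id").index.get_indexer(rds["participant_id"])
            sample_means.append(np.mean([net.degree(int(v)) for v in idx]))
        assert np.mean(sample_means) > pop_mean


class TestDeterminism:
    def test_identical_config_and_seed_give_identical_outputs(self):
        a = generate_study(small_config(random_seed=5))
        b = generate_study(small_config(random_seed=5))
        assert a.pr.to_csv(index=False) == b.pr.to_csv(index=False)
        assert a.rds.to_csv(index=False) == b.rds.to_csv(index=False)
        assert a.population.to_csv(index=False) == b.population.to_csv(index=False)

    def test_different_seed_changes_outputs(self):
        a = generate_study(small_config(random_seed=5))
        b = generate_study(small_config(random_seed=6))
        assert a.rds.to_csv(index=False) != b.rds.to_csv(index=False)


class TestMunichPreset:
    def test_topline_structure(self, munich_study):
        cfg = munich_study.config
        assert cfg.size == 4160
        assert len(munich_study.pr) == 400
        forest = build_forest(records_from_frame(munich_study.rds))
        assert forest.size == 195
        assert len(forest.seeds) == 16
        assert max(dict(forest.graph.out_degree).values()) <= 3

    def test_registry_selection_shifts_toward_integrated(self):
        """Attribute-dependent nonresponse: registry responders are more
        integrated than the population, shifting PR-arm estimates toward
        German citizenship and older age (directional check)."""
        shifts_citizen, shifts_age = [], []
        for s in range(5):
            study = generate_study(munich2017(random_seed=100 + s))
            resp = study.pr[study.pr["responded"]]
            pop_g = study.true_prevalences["citizenship"]["german"]
            shifts_citizen.append((resp["citizenship"] == "german").mean() - pop_g)
            pop_old = 1 - study.true_prevalences["age_group"]["18-34"]
            shifts_age.append((resp["age_group"] != "18-34").mean() - pop_old)
        assert np.mean(shifts_citizen) > 0
        assert np.mean(shifts_age) > 0

    def test_preset_loadable_from_config_stanza(self):
        cfg = load_config({"preset": "munich2017", "random_seed": 42})
        assert cfg.random_seed == 42
        assert cfg.rds.target_size == 195


def test_end_to_end_weighted_recovery():
    """Full pipeline on a fixed network: over 200 replicate RDS runs of
    n=500, the inverse-degree weighted prevalence of a degree-independent
    attribute stays within 3 points of the population truth."""
    cfg = small_config(size=6000, homophily=0.5, target_size=500,
                       rds=RDSConfig(n_seeds=10, acceptance_prob=0.9,
                                     target_size=500),
                       random_seed=13)
    pop = generate_population(cfg)
    net = generate_network(pop, cfg)
    rep = reported_network_size(net, cfg)
    truth = (pop["grp"] == "a").mean()
    ids = pop["id"].to_numpy()
    grp = dict(zip(ids, pop["grp"]))
    estimates = []
    for s in range(200):
        rds = simulate_rds(pop, net, rep, cfg, np.random.default_rng(1000 + s))
        forest = build_forest(records_from_frame(rds))
        kept = filter_analysis_set(forest)
        if len(kept) < 50:
            continue
        degrees = {p: forest.records[p].network_size for p in kept}
        chains = {p: forest.chain[p] for p in kept}
        wv = rds_weights(degrees, chains)
        est = rds_weighted_proportion({p: grp[p] for p in kept}, wv)
        estimates.append(est["a"].estimate if "a" in est else 0.0)
    assert len(estimates) >= 190
    assert np.mean(estimates) == pytest.approx(100 * truth, abs=3.0)
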