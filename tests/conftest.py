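import pytest

import netenrich as ne


SMALL_CONFIG = ne.FixtureConfig(
    seed=7,
    n_genomes=6,
    n_bgcs_per_genome=(5, 9),
    n_true_families=12,
    frac_families_with_mibig_link=0.25,  # 3 of 12 families MIBiG-linked
    n_bigfam_models=8,
    n_arts_profiles=3,
    planted_unknown_profile_group=5,
    n_kcb_merge_pairs=1,
    n_model_merge_pairs=1,
    n_phylogroups=3,
)


@pytest.fixture(scope="session")
def small_fixture():
    """Small planted dataset: 12 true families, 3 MIBiG-linked, one
    KCB-merge pair, one model-merge pair, a 5-member unknown-profile group."""
    return ne.generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_fixture():
    """Study-scale planted dataset (26 genomes, 300 families, 17-member
    unknown-profile group)."""
    return ne.generate(ne.FixtureConfig(seed=1))


def run_pipeline(data):
    """Full enrichment pipeline on a fixture; returns (baseline graph,
    baseline assignments, enriched graph, enriched assignments)."""
    cfg = data.config
    graph = ne.build_baseline(data.edges, data.bgcs, cfg.cutoff, data.mibig_members)
    baseline = ne.baseline_gcfs(graph)
    decisions = ne.filter_models(ne.model_diversity(data.genus_counts))
    enriched_graph = ne.enrich(
        graph,
        kcb=data.kcb_hits,
        kcb_min_similarity=cfg.kcb_min_similarity,
        bigfam=data.bigfam_membership,
        model_filter=decisions,
        arts=data.arts_hits,
    )
    enriched = ne.enriched_gcfs(enriched_graph)
    return graph, baseline, enriched_graph, enriched


@pytest.fixture(scope="session")
def small_pipeline(small_fixture):
    return run_pipeline(small_fixture)


@pytest.fixture(scope="session")
def default_pipeline(default_fixture):
    return run_pipeline(default_fixture)
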