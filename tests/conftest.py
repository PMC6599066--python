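import numpy as np
import pytest

import coreg


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale planted study: 10 factors over 300 genes, 30 diseases."""
    return coreg.simulate_study("small", seed=7)


@pytest.fixture(scope="session")
def small_space(small_study):
    return coreg.build_component_space(
        small_study.compendium.expression, seed=7
    )


@pytest.fixture(scope="session")
def small_matrix(small_study, small_space):
    return coreg.build_prediction_matrix(
        small_space, small_study.collection
    )


@pytest.fixture(scope="session")
def spread_compendium():
    """600-gene compendium whose 12 factors span weak to strong
    co-regulation (SNR 0.3..6), for robustness and stability checks that
    need between-term / between-gene signal variation."""
    return coreg.simulate_compendium(
        n_genes=600, n_samples=1500, n_factors=12,
        snr=np.geomspace(0.3, 6.0, 12), seed=17,
        block_size=coreg.synthetic.geometric_blocks(12, 25, 1.1),
    )


@pytest.fixture(scope="session")
def spread_space(spread_compendium):
    return coreg.build_component_space(spread_compendium.expression, seed=17)


@pytest.fixture(scope="session")
def spread_disease_study(spread_compendium):
    """Disease-style annotations on the spread compendium: 8 terms per
    factor of mixed quality, 108 diseases with distinct causal genes."""
    collection, term_factor, reserved = coreg.simulate_annotations(
        spread_compendium, n_terms_per_factor=8, set_size=12,
        label_noise=0.2, seed=18, reserve_per_block=9,
    )
    return coreg.simulate_ontology_and_catalog(
        spread_compendium, collection, term_factor, reserved,
        diseases_per_factor=9, seed=19,
    )


@pytest.fixture(scope="session")
def spread_disease_matrix(spread_space, spread_disease_study):
    return coreg.build_prediction_matrix(
        spread_space, spread_disease_study.collection
    )


@pytest.fixture(scope="session")
def tiny_space():
    """A 20-gene, 6-component space with random orthonormal eigenvectors,
    for exact oracle comparisons."""
    rng = np.random.default_rng(99)
    q, _ = np.linalg.qr(rng.standard_normal((20, 6)))
    space = coreg.ComponentSpace(
        [f"g{i:02d}" for i in range(20)], q,
        np.linspace(6.0, 1.0, 6),
    )
    space.n_retained = 6
    return space


FIXTURE_OBO = """\
format-version: 1.2
ontology: fixture

[Term]
id: FX:0000001
name: root phenotype

[Term]
id: FX:0000002
name: abnormality of the large intestine
is_a: FX:0000001 ! root phenotype

[Term]
id: FX:0000003
name: increased inflammatory response
is_a: FX:0000001 ! root phenotype

[Term]
id: FX:0000004
name: functional abnormality of the gastrointestinal tract
is_a: FX:0000001 ! root phenotype

[Term]
id: FX:0000005
name: inflammation of the large intestine
is_a: FX:0000002 ! abnormality of the large intestine
is_a: FX:0000003 ! increased inflammatory response
is_a: FX:0000004 ! functional abnormality of the gastrointestinal tract

[Term]
id: FX:0000006
name: diamond left
is_a: FX:0000002 ! abnormality of the large intestine

[Term]
id: FX:0000007
name: diamond right
is_a: FX:0000002 ! abnormality of the large intestine

[Term]
id: FX:0000008
name: diamond bottom
alt_id: FX:0000108
is_a: FX:0000006 ! diamond left
is_a: FX:0000007 ! diamond right

[Term]
id: FX:0000009
name: obsolete phenotype
is_obsolete: true
is_a: FX:0000001 ! root phenotype
"""


@pytest.fixture(scope="session")
def fixture_obo_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("obo") / "fixture.obo"
    path.write_text(FIXTURE_OBO)
    return path


@pytest.fixture(scope="session")
def fixture_graph(fixture_obo_path):
    return coreg.parse_obo(fixture_obo_path)
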