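import pytest

import trilayer as tl


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study shared by unit tests (fast to analyse)."""
    cfg = tl.SynthConfig(
        n_genes=800,
        n_processes=40,
        process_size_range=(15, 120),
        n_planted_processes=3,
        n_regulons=20,
        regulon_size_range=(10, 40),
        n_planted_regulons=3,
        n_physio_params=5,
        n_linked_params=2,
        link_module_size=30,
        seed=7,
    )
    return tl.generate_study(cfg)


@pytest.fixture(scope="session")
def de_5d(small_study):
    em = tl.ExpressionMatrix(
        small_study.expression, small_study.samples
    ).subset("5d")
    return tl.moderated_ttest(em)
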