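import pytest

from mapkascade import simulate as sim


@pytest.fixture(scope="session")
def default_family():
    """One synthetic gene family under the default study design."""
    spec = sim.SimulationSpec(seed=11)
    return sim.simulate_gene_family(spec)


@pytest.fixture(scope="session")
def family_domains(default_family):
    _, _, _, truth = default_family
    return {r.gene_id: (int(r.dom_start), int(r.dom_end))
            for r in truth.itertuples()}
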