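import numpy as np
import pytest

from vepeval import (
    AssessmentConfig,
    default_simulation_spec,
    generate_activity,
    generate_predictions,
    write_fixture_bundle,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def variant_table(tmp_path):
    """A hand-written curated micro-table with ClinVar annotations."""
    text = "\n".join(
        [
            "variant\tactivity\tclinvar_significance\tclinvar_review",
            "p.A1V\t5\t\t",
            "p.A2V\t50\tUncertain significance\tcriteria provided",
            "p.A3V\t0.45\tPathogenic\tcriteria provided, multiple submitters",
            "p.A4V\t90\tBenign\tConflicting interpretations of pathogenicity",
            "p.A5V\t13.0\tLikely benign\tcriteria provided",
            "p.A6V\t27.6\t\t",
            "p.A7V\t2.9\tPathogenic/Likely pathogenic\tno assertion criteria",
        ]
    )
    path = tmp_path / "variants.tsv"
    path.write_text(text + "\n")
    return path


@pytest.fixture(scope="session")
def sim_spec():
    return default_simulation_spec(seed=7)


@pytest.fixture(scope="session")
def sim_dataset(sim_spec):
    return generate_activity(sim_spec)


@pytest.fixture(scope="session")
def sim_predictions(sim_spec, sim_dataset):
    return generate_predictions(sim_spec, sim_dataset)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, sim_spec):
    """A written-out synthetic bundle plus its assessment config."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = write_fixture_bundle(sim_spec, out)
    config = AssessmentConfig.from_yaml(out / "config.yaml")
    config.B = 200  # small resample count keeps the suite fast
    return out, config, manifest
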