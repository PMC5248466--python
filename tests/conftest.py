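import pytest

from pitkit.cli import write_run_config
from pitkit.pipeline import RunConfig, run_pipeline
from pitkit.simulate import SynthConfig, generate


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """The default synthetic study, generated once and run end to end.

    Returns (ground_truth, run_config, report_bundle).
    """
    d = tmp_path_factory.mktemp("scenario")
    truth = generate(SynthConfig(seed=1), d)
    cfg_path = d / "run_config.yaml"
    write_run_config(truth, d, cfg_path, 1)
    cfg = RunConfig.from_yaml(cfg_path)
    bundle = run_pipeline(cfg)
    return truth, cfg, bundle


def group_transcripts(bundle):
    """group_id -> set of transcript ids contributing ORFs to the group."""
    return {
        g.group_id: {oid.rsplit(".orf", 1)[0] for oid in g.orf_ids} for g in bundle.groups
    }
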