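import numpy as np
import pytest

from bindscape.simulate import SimConfig, generate_bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small generated input bundle shared by read-only tests."""
    out = tmp_path_factory.mktemp("bundle")
    config = SimConfig(seed=11, n_compounds=40)
    truth = generate_bundle(config, out)
    return config, out, truth


def pipeline_config_for(bundle_dir, out_dir, seed=0):
    from bindscape.workflow import PipelineConfig
    return PipelineConfig(
        structures_dir=str(bundle_dir / "structures"),
        compounds_sdf=str(bundle_dir / "compounds.sdf"),
        drug_libs=[str(bundle_dir / "drugs.sdf")],
        metabolite_libs=[str(bundle_dir / "metabolites.sdf")],
        descriptor_table=str(bundle_dir / "descriptors.tsv"),
        pathway_table=str(bundle_dir / "pathways.tsv"),
        ec_table=str(bundle_dir / "ec_annotations.tsv"),
        out_dir=str(out_dir),
        seed=seed,
    )
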