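import os

import pytest

from autogvp import fixtures, pipeline

BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def catalog():
    return fixtures.default_catalog()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, catalog):
    """The default synthetic input bundle, generated once per session."""
    out_dir = str(tmp_path_factory.mktemp("bundle"))
    paths = fixtures.generate_bundle(catalog, seed=BUNDLE_SEED, out_dir=out_dir)
    return paths


def make_config(bundle_paths, out_prefix, tiebreak="latest", concepts=True,
                filter_criteria=""):
    return pipeline.RunConfig(
        vep_vcf=bundle_paths["vep_vcf"],
        multianno=bundle_paths["multianno"],
        intervar=bundle_paths["intervar"],
        autopvs1=bundle_paths["autopvs1"],
        clinvar_vcf=bundle_paths["clinvar_vcf"],
        variant_summary=bundle_paths["variant_summary"],
        submission_summary=bundle_paths["submission_summary"],
        concept_id_list=bundle_paths["concept_ids"] if concepts else None,
        tiebreak=tiebreak,
        filter_criteria=filter_criteria,
        out_prefix=out_prefix,
    )


@pytest.fixture(scope="session")
def run_latest(bundle, tmp_path_factory):
    out = os.path.join(str(tmp_path_factory.mktemp("run_latest")), "out")
    return pipeline.run(make_config(bundle, out))


@pytest.fixture(scope="session")
def run_most_severe(bundle, tmp_path_factory):
    out = os.path.join(str(tmp_path_factory.mktemp("run_ms")), "out")
    return pipeline.run(make_config(bundle, out, tiebreak="most_severe"))


@pytest.fixture(scope="session")
def run_no_concept(bundle, tmp_path_factory):
    out = os.path.join(str(tmp_path_factory.mktemp("run_nc")), "out")
    return pipeline.run(make_config(bundle, out, concepts=False))
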