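import pathlib

import pytest

from fusemble import pipeline, synth
from fusemble.models import FusionCall


def make_call(
    caller="arriba",
    gene5="RBPMS",
    gene3="MET",
    chrom5="8",
    pos5=30_500_000,
    strand5="+",
    chrom3="7",
    pos3=116_700_000,
    strand3="+",
    reads=20,
    **kwargs,
):
    return FusionCall(
        caller=caller,
        gene5=gene5,
        gene3=gene3,
        chrom5=chrom5,
        pos5=pos5,
        strand5=strand5,
        chrom3=chrom3,
        pos3=pos3,
        strand3=strand3,
        reads=reads,
        **kwargs,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> synth.FixtureBundle:
    """A default-shaped fixture bundle shared across read-only tests."""
    out = tmp_path_factory.mktemp("bundle")
    return synth.generate_fixture(synth.FixtureSpec(seed=7), out)


@pytest.fixture(scope="session")
def bundle_report(bundle, tmp_path_factory) -> pipeline.EnsembleReport:
    out = tmp_path_factory.mktemp("bundle-run")
    config = pipeline.PipelineConfig(
        caller_files=bundle.caller_files,
        out_dir=out,
        freq_db=bundle.store_path,
        known_list=bundle.known_list_path,
    )
    return pipeline.run_pipeline(config)


def run_bundle(bundle, out_dir: pathlib.Path, **config_kwargs) -> pipeline.EnsembleReport:
    config = pipeline.PipelineConfig(
        caller_files=bundle.caller_files,
        out_dir=out_dir,
        freq_db=bundle.store_path,
        known_list=bundle.known_list_path,
        **config_kwargs,
    )
    return pipeline.run_pipeline(config)
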