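import pathlib

import pytest

from refaln.pipeline import RunConfig, run_pipeline
from refaln.seq_io import GeneticCode
from refaln.synth_data import SimulationDesign, build_contaminated_dataset


@pytest.fixture(scope="session")
def code():
    return GeneticCode.from_ncbi(1)


#: small study design used by the end-to-end tests (fewer loci than the
#: acceptance-scale design, same clade structure)
SMALL_DESIGN = dict(n_loci=6, n_removed_loci=1, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    return build_contaminated_dataset(SimulationDesign(**SMALL_DESIGN))


@pytest.fixture(scope="session")
def clean_dataset():
    return build_contaminated_dataset(SimulationDesign(**SMALL_DESIGN),
                                      contamination=False)


def write_and_configure(dataset, tmp_path: pathlib.Path, **overrides) -> RunConfig:
    """Materialise a dataset under tmp_path and build a matching RunConfig."""
    dataset.write(tmp_path)
    kwargs = dict(
        mode="codon",
        references=sorted(str(p) for p in (tmp_path / "references").glob("*.fa")),
        sources={s: [str(tmp_path / f"{s}.fastq")] for s in dataset.reads},
        outgroup_id="outgroup",
        out_dir=str(tmp_path / "out"),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture()
def run_on_dataset(tmp_path):
    def _run(dataset, **overrides):
        cfg = write_and_configure(dataset, tmp_path, **overrides)
        return run_pipeline(cfg)

    return _run
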