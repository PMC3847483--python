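import numpy as np
import pytest

from orthopath.pipeline import RunConfig, run_reconstruct
from orthopath.simulate import ScenarioConfig, generate_scenario

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int, rec_id: str, species: str = ""):
    from orthopath.records import SequenceRecord

    idx = rng.integers(0, len(AA), size=length)
    return SequenceRecord(
        id=rec_id, residues="".join(AA[i] for i in idx), species=species, alphabet="protein"
    )


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """The default study conditions: 5 species, 30 families at 80-95%%
    identity, 30 decoys, 5 recent duplicates, 3 planted gaps."""
    root = tmp_path_factory.mktemp("scenario")
    bundle, manifest = generate_scenario(ScenarioConfig(seed=1), root)
    return bundle, manifest


@pytest.fixture(scope="session")
def pipeline_result(default_scenario, tmp_path_factory):
    """Full pipeline output on the default scenario (shared; ~20 s)."""
    bundle, manifest = default_scenario
    out = tmp_path_factory.mktemp("run")
    result = run_reconstruct(RunConfig.from_scenario_dir(bundle.root, out, make_plot=False))
    return result, manifest, out


SMALL = dict(
    n_families=4, n_decoys=4, n_paralogs=2, n_known_genes=3,
    n_gap_reactions=1, protein_length=(80, 120),
)


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    root = tmp_path_factory.mktemp("small_scenario")
    bundle, manifest = generate_scenario(ScenarioConfig(seed=7, **SMALL), root)
    return bundle, manifest
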