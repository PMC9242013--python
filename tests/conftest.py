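import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from barrierkit.fixtures import (
    SyntheticReactionSpec,
    build_reaction_records,
    generate_reactions,
)


@pytest.fixture(scope="session")
def small_reactions():
    """Six in-memory synthetic reactions with modest geometric noise."""
    spec = SyntheticReactionSpec(n_reactions=6, seed=11, geo_noise_sd=0.03)
    return build_reaction_records(spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk synthetic dataset: logs, XYZ, manifest, ground truth."""
    out = tmp_path_factory.mktemp("synthetic")
    spec = SyntheticReactionSpec(n_reactions=5, seed=7, geo_noise_sd=0.03)
    manifest, sidecar = generate_reactions(spec, out)
    return {"dir": out, "manifest": manifest, "sidecar": sidecar}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def water_xyz(tmp_path):
    """A 3-atom water XYZ file, oxygen first."""
    path = tmp_path / "water.xyz"
    path.write_text(
        "3\nwater fixture\n"
        "O    0.0000000000    0.0000000000    0.1173000000\n"
        "H    0.0000000000    0.7572000000   -0.4692000000\n"
        "H    0.0000000000   -0.7572000000   -0.4692000000\n"
    )
    return path
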