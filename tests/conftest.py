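import numpy as np
import pytest

from headdir import (
    CLUSTER_DEFAULTS,
    TUFT_DEFAULTS,
    SceneSpec,
    generate_cluster_scene,
    generate_tuft_scene,
    make_arc_trajectory,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def cluster_scene(tmp_path_factory):
    """A 40-frame blob-chain scene with its planted truth."""
    outdir = tmp_path_factory.mktemp("cluster_scene")
    traj = make_arc_trajectory(40, seed=3)
    spec = SceneSpec(archetype="cluster", trajectory=traj, seed=3)
    bg, frames, truth = generate_cluster_scene(spec, outdir)
    return {"dir": outdir, "truth": truth, "spec": spec, "params": CLUSTER_DEFAULTS}


@pytest.fixture(scope="session")
def tuft_scene(tmp_path_factory):
    """A 40-frame ear-tuft scene with its planted truth."""
    outdir = tmp_path_factory.mktemp("tuft_scene")
    traj = make_arc_trajectory(40, seed=7)
    spec = SceneSpec(archetype="tuft", trajectory=traj, seed=7)
    bg, frames, truth = generate_tuft_scene(spec, outdir)
    return {"dir": outdir, "truth": truth, "spec": spec, "params": TUFT_DEFAULTS}
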