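import numpy as np
import pytest

from bcrstruct.loopgeom import BackboneLoop
from bcrstruct.synthdata import (
    GroupDesign,
    StudyDesign,
    generate_germline_reference,
    generate_study,
    generate_template_library,
)


@pytest.fixture(scope="session")
def germlines():
    return generate_germline_reference(n_v_genes=4, seed=11)


@pytest.fixture(scope="session")
def small_library(germlines):
    """120 templates in 36 shape families (3 per CDR-H3 length)."""
    library, families = generate_template_library(
        n_templates=120, n_shape_families=36, seed=11, germlines=germlines
    )
    return library, families


@pytest.fixture(scope="session")
def small_study():
    """Two-group study small enough for per-test pipelines (~10 s)."""
    design = StudyDesign(
        groups=(
            GroupDesign("naive", "IGHM", 4, 3000, 5.0, True,
                        (0, 2, 4, 6, 8), 5.0, 0.005),
            GroupDesign("plasma", "IGHG", 4, 3000, 1.0, False, (), 1.0, 0.04),
        ),
        n_templates=120, n_shape_families=36, n_v_genes=4, rng_seed=7,
    )
    return generate_study(design)


@pytest.fixture(scope="session")
def small_study_result(small_study):
    from bcrstruct.pipeline import run_study
    from bcrstruct.profiles import AnalysisConfig

    cfg = AnalysisConfig(
        min_modelled=500, subsample_size=500, randomized_size=100_000, rng_seed=3
    )
    return run_study(small_study, cfg, reference_b_cell_type="naive")


def random_loop(rng: np.random.Generator, n_res: int) -> BackboneLoop:
    """A random but chain-like backbone: jittered CA walk with local offsets."""
    steps = rng.normal(size=(n_res, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    ca = np.cumsum(steps, axis=0)
    coords = np.empty((n_res, 3, 3))
    coords[:, 1] = ca
    coords[:, 0] = ca + rng.normal(0, 0.3, (n_res, 3)) + [-1.0, 0.4, 0.0]
    coords[:, 2] = ca + rng.normal(0, 0.3, (n_res, 3)) + [1.0, 0.4, 0.0]
    return BackboneLoop(coords)


def rigid_transform(loop: BackboneLoop, rng: np.random.Generator) -> BackboneLoop:
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng)
    t = rng.normal(0, 5.0, 3)
    return BackboneLoop(rot.apply(loop.atoms).reshape(-1, 3, 3) + t)
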