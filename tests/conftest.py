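import numpy as np
import pytest

from ringscape import EnsembleSpec, build_template
from ringscape.ensemble_sim import sample_ensemble
from ringscape.superpose import align_ensemble, core_mask


@pytest.fixture(scope="session")
def small_template():
    """Light template (6 atoms/domain) for geometry and I/O tests."""
    return build_template(atoms_per_domain=6)


@pytest.fixture(scope="session")
def default_template():
    """Full-size toy hexamer: 30 atoms/domain, 540 atoms."""
    return build_template()


@pytest.fixture(scope="session")
def pipeline_run(default_template):
    """A mid-size default-condition ensemble, aligned, with its truth.

    3,000 particles under the default study conditions (2% planted split,
    0.25 Å noise, random pose and register), shared by the landscape and
    recovery tests.
    """
    spec = EnsembleSpec(n_particles=3000, seed=11)
    ensemble, truth = sample_ensemble(spec, default_template)
    aligned = align_ensemble(
        ensemble, default_template.coords, core_mask(default_template)
    )
    return {
        "spec": spec,
        "template": default_template,
        "ensemble": ensemble,
        "aligned": aligned,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
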