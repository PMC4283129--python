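import numpy as np
import pytest

from ftirlip import (ArtifactModel, GroundTruthComposition, StudyDesign,
                     default_bands, default_grid, generate_study,
                     render_spectrum)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def default_study():
    """The full factorial study (450 spectra) under default conditions."""
    return generate_study(StudyDesign(seed=7))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast structural tests (2x5x2x1x2 = 40 spectra)."""
    design = StudyDesign(n_strains=2, n_media=5, n_runs=2,
                         n_wells_per_sample_per_run=1,
                         n_technical_replicates=2, seed=11)
    return generate_study(design)


@pytest.fixture
def clean_spectrum(grid):
    """One artifact-free spectrum of the default composition."""
    comp = GroundTruthComposition("ref", SAT=30, MUFA=40, PUFA=30,
                                  total_lipid=1.0)
    return render_spectrum(comp, default_bands(), ArtifactModel.none(), grid)
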