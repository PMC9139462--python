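import numpy as np
import pytest

import erbbsig as e


@pytest.fixture(scope="session")
def comp():
    return e.compile_default()


@pytest.fixture(scope="session")
def truth(comp):
    """Seeded ground truth for all four cell lines."""
    return e.sample_true_parameters(seed=0, comp=comp)


@pytest.fixture(scope="session")
def mcf7_params(truth):
    return truth.for_cell_line("MCF7")


@pytest.fixture(scope="session")
def mcf7_x0(comp, mcf7_params):
    x0, _ = e.steady_state_initialize(comp, mcf7_params)
    return x0


@pytest.fixture(scope="session")
def small_dataset(comp, truth):
    """Tiny merged panel (2 ligands, 1 drug + control) for fast objectives."""
    design = e.build_design(cell_lines=["MCF7"], ligands=["EGF", "NRG1"],
                            drugs=["cetuximab"])
    return e.generate_timecourse(design, truth, noise_sd=0.05, seed=7,
                                 comp=comp)


@pytest.fixture(scope="session")
def luminal_panel(comp, truth):
    """One full luminal panel (24 conditions), merged, noise sd 0.05."""
    design = e.build_design(cell_lines=["MCF7"])
    return e.generate_timecourse(design, truth, noise_sd=0.05, seed=11,
                                 comp=comp)


def species_index(comp):
    return {sp: i for i, sp in enumerate(comp.network.species)}
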