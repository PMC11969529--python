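import warnings

import pytest

from brainflux.pipeline import RunConfig, build_brain, extract_cells, single_cell_states

warnings.filterwarnings("ignore", message="empty evidence")


@pytest.fixture(scope="session")
def parent_models():
    """Parent (pre-extraction) toy models for all five cell types."""
    from brainflux.synth import CELL_TYPES, ToyBrainSpec, generate_toy_cell_model

    spec = ToyBrainSpec(cell_types=CELL_TYPES)
    return {c: generate_toy_cell_model(c, spec) for c in CELL_TYPES}


@pytest.fixture(scope="session")
def pipeline_ctx():
    """Extracted models, constrained models, single-cell states, and the
    simulation-ready brain for the default study conditions (seed 1)."""
    config = RunConfig(seed=1)
    parents, extracted, profiles, lengths = extract_cells(config)
    constrained, states = single_cell_states(extracted, config)
    brain = build_brain(constrained, states, config)
    return {
        "config": config,
        "parents": parents,
        "extracted": extracted,
        "profiles": profiles,
        "lengths": lengths,
        "constrained": constrained,
        "states": states,
        "brain": brain,
    }


@pytest.fixture(scope="session")
def protocol_results(pipeline_ctx):
    """All five protocol runs on the session brain."""
    from brainflux.simulate import run_protocol

    brain = pipeline_ctx["brain"]
    cfg = pipeline_ctx["config"].protocol
    return {
        p: run_protocol(brain, p, cfg)
        for p in ("resting", "glucose", "ketogenic", "hypoxia", "demyelination")
    }
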