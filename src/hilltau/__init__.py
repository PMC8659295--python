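"""hilltau: compact event-driven abstraction of biochemical signaling.

Each HillTau "reaction" lumps one or more chemical steps into a Hill-form
steady state relaxed exponentially with time constants tau (rising) and
tau2 (falling).  The package provides the model format and engine, a
mass-action ODE oracle, the MASH model-reduction optimizer, and SBML/DOT
export.
"""

from importlib import resources

from .engine import (Event, SimState, StimulusProgram, Trace, advance,
                     default_dt, dose_response, initialize, relax,
                     run_program, solve_steady_state, steady_state_output)
from .massaction import (BindingReaction, EnzymeStep, HillFit,
                         MassActionNetwork, fit_hill_to_cascade,
                         load_network, simulate)
from .mash import (FitParam, FitResult, FitSpec, default_bounds, fit,
                   make_protocol, nrms_score, staged_fit)
from .model import (EquationSpec, ModelError, ModelSpec, ReactionSpec,
                    SpeciesSpec, canonicalize_units, convert_units,
                    load_model, load_model_file, write_model,
                    write_model_file)
from .scheduler import LayerAssignment, build_dependency_layers
from .export import RateRule, to_dot, to_ode_rates, to_sbml

__version__ = "0.1.0"


def example_model(name: str) -> ModelSpec:
    """Load one of the packaged example models by name.

    Available: binding, conversion, inhibition, baseline_tau2, modifier,
    gain, feedback_inhibition, bistable, oscillator, bcm.
    """
    ref = resources.files("hilltau") / "models" / f"{name}.json"
    return load_model(ref.read_text(encoding="utf-8"))


def example_model_path(name: str) -> str:
    ref = resources.files("hilltau") / "models" / f"{name}.json"
    return str(ref)
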