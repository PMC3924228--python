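"""ccrsim: crowding-constrained flux balance modeling of carbon catabolite repression.

Flux balance analysis with a macromolecular-crowding budget (FBAwMC), plus
dynamic batch and chemostat culture simulators built on it, a reduced
five-substrate fixture network, uptake-kinetics/density-gradient analysis,
and seeded synthetic-data generators.
"""

from importlib import resources as _resources

from .network import (
    FixtureCalibrationError,
    FixtureParams,
    Metabolite,
    MetabolicNetwork,
    NetworkValidationError,
    Reaction,
    SUBSTRATES,
    build_fixture_network,
    calibration_report,
    load_network,
    loads_network,
    merge_split_fluxes,
    split_reversible,
    write_network,
)
from .fba import FluxProblem, FluxState, crowding_lhs, solve_fbawmc
from .oracle import OracleSizeError, brute_force_oracle
from .batch import (
    BatchConfig,
    BatchSimulationError,
    BatchTrajectory,
    carbon_balance_error,
    exhaustion_order,
    simulate_batch,
)
from .chemostat import (
    ChemostatPoint,
    WashoutError,
    ccr_onset,
    consumption_ratio,
    dilution_scan,
    scan_frame,
    simulate_chemostat_point,
)
from .kinetics import (
    DecayFit,
    DensityProfile,
    GrowthCurve,
    GrowthRateSeries,
    cell_density_distribution,
    fit_one_phase_decay,
    fold_ratio,
    growth_rate,
    normalize_to_biomass,
    promoter_activity,
    two_sample_ttest,
)
from .synth import (
    BatchTruth,
    DecayTruth,
    GeneratorSpec,
    generate_batch_observations,
    generate_decay_series,
    generate_gradient_profile,
    generate_induction_timecourse,
)

__version__ = "0.1.0"


def fixture_network_path() -> str:
    """Path of the packaged reduced-network JSON fixture."""
    return str(_resources.files("ccrsim").joinpath("data/ccr_reduced_network.json"))


def load_fixture_network() -> MetabolicNetwork:
    """Load the packaged calibrated five-substrate reduced network."""
    return load_network(fixture_network_path())
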