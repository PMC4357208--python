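"""Flux scenarios behind macroscopically indistinguishable phenotypes.

A small constraint-based model of E. coli central metabolism whose feasible
flux space is pinned down only by measured phenotype (growth rate, yields,
byproducts) within experimental resolution; extreme-scenario enumeration,
2-D feasible-region projection, demand-vector calibration against published
scenario tables, and a simple proteome differential screen with synthetic
data generators.
"""

from .constraints import (
    BoundSet,
    PhenotypeConstraints,
    atp_bounds,
    build_bounds,
    glucose_bounds,
    load_config,
)
from .loads import (
    Composition,
    LoadVector,
    PolymerizationCosts,
    compute_load_vector,
    dna_precursor_load,
    genome_equivalents,
    parse_composition,
    scale_dna_load,
)
from .network import (
    REGISTRY_FLUXES,
    FluxVector,
    Metabolite,
    Reaction,
    StoichiometricSystem,
    assemble_system,
    degrees_of_freedom,
    derived_fluxes,
    load_default_system,
    parse_metabolites,
    parse_network,
)
from .projection import (
    FeasibleRegion2D,
    contains_point,
    pairwise_trend,
    project_pair,
)
from .scenarios import (
    CalibrationResult,
    ObjectiveSpec,
    PrintedScenario,
    ScenarioRecord,
    ScenarioTable,
    biomass_max_equivalence,
    calibrate_loads,
    classify_co_optimal,
    enumerate_scenarios,
    load_printed_scenarios,
    nadph_breakdown,
    solve_lp,
)
from .screen import replicate_correlation, screen, screen_metrics
from .synthetic import (
    SyntheticPhenotype,
    SyntheticProteome,
    generate_phenotype,
    generate_proteome,
    summarize_phenotype,
)

__version__ = "0.1.0"


def calibrated_study(config=None):
    """Convenience: assemble the default study (system, load, bounds).

    Parses the bundled network, builds bounds from the default phenotype
    window, computes the composition-derived load as prior, and calibrates
    the demand vector against published scenarios 1, 2 and 5.  Returns
    ``(system, calibration_result, bounds, constraints)``.
    """
    system = load_default_system()
    constraints = config or load_config()
    bounds = build_bounds(constraints)
    prior = compute_load_vector(parse_composition(), mu=constraints.mu)
    printed = [
        s for s in load_printed_scenarios(constraints=constraints)
        if s.name in ("1", "2", "5")
    ]
    cal = calibrate_loads(
        system, bounds, printed, prior,
        po_nadh=constraints.po_nadh, po_fadh=constraints.po_fadh,
        mu=constraints.mu,
    )
    return system, cal, bounds, constraints
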