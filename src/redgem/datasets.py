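"""Published comparison tables for *S. clavuligerus* clavulanic-acid
cultivations.

Three small tables accompany the reduced-model study and are shipped here
as in-memory DataFrames:

* :func:`chemostat_validation_table` — model-predicted vs experimental
  exchange rates in continuous cultures at three dilution rates
  (D = 0.045, 0.035, 0.050 h⁻¹), with printed squared errors and the MSE
  row computed over the five quantified fluxes per column;
* :func:`fedbatch_comparison_table` — predicted vs measured rates for the
  batch (36 h) and fed-batch (48 h) states of the 2D-rocking-bioreactor
  cultivation, including the soft-constraint roles of each flux;
* :func:`central_shadow_price_table` — shadow prices of selected central
  carbon metabolism metabolites under both states.

Fluxes are mmol·gDCW⁻¹·h⁻¹ (growth in h⁻¹); uptakes are negative.  The
printed aggregate of the fed-batch table matches the *sum* of its SE
column, not the mean — both are recomputable from these data and the
discrepancy is deliberately left as published.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "chemostat_validation_table",
    "fedbatch_comparison_table",
    "fedbatch_scenario_roles",
    "central_shadow_price_table",
]

# columns: quantity, dilution (h⁻¹), fba, exp, se (printed), available
_CHEMOSTAT = [
    # D = 0.045
    ("growth", 0.045, 0.039, 0.045, 0.0, 1),
    ("o2", 0.045, -0.375, -1.665, 1.662, 1),
    ("glycerol", 0.045, -0.695, -1.110, 0.172, 1),
    ("co2", 0.045, 0.067, 0.067, 0.0, 1),
    ("clavulanate", 0.045, 0.017, 0.398, 0.145, 1),
    ("phosphate", 0.045, 0.000, None, None, 0),
    ("glutamate", 0.045, -0.350, None, None, 0),
    # D = 0.035
    ("growth", 0.035, 0.034, 0.035, 0.0, 1),
    ("o2", 0.035, -0.322, -1.621, 1.686, 1),
    ("glycerol", 0.035, -0.639, -0.968, 0.108, 1),
    ("co2", 0.035, 0.023, 0.023, 0.0, 1),
    ("clavulanate", 0.035, 0.015, 0.357, 0.117, 1),
    ("phosphate", 0.035, 0.000, None, None, 0),
    ("glutamate", 0.035, -0.310, None, None, 0),
    # D = 0.050
    ("growth", 0.050, 0.044, 0.050, 0.0, 1),
    ("o2", 0.050, -0.511, -1.848, 1.787, 1),
    ("glycerol", 0.050, -0.728, -0.728, 0.0, 1),
    ("co2", 0.050, 0.253, 0.253, 0.0, 1),
    ("clavulanate", 0.050, 0.020, 0.435, 0.172, 1),
    ("phosphate", 0.050, 0.000, None, None, 0),
    ("glutamate", 0.050, -0.400, None, None, 0),
]

#: Printed MSE row of the chemostat table, keyed by dilution rate.
CHEMOSTAT_PRINTED_MSE = {0.045: 0.396, 0.035: 0.382, 0.050: 0.392}

# columns: quantity, condition, fba, exp, exp_sd, se (printed)
_FEDBATCH = [
    ("growth", "batch", 0.042, 0.042, 0.004, 0.0),
    ("o2", "batch", -0.512, -1.350, None, 0.702),
    ("glycerol", "batch", -0.182, -0.182, None, 0.0),
    ("co2", "batch", 0.639, 1.640, None, 1.002),
    ("clavulanate", "batch", 0.002, 0.002, None, 0.0),
    ("succinate", "batch", 0.014, 0.014, None, 0.0),
    ("oxaloacetate", "batch", 0.004, 0.004, None, 0.0),
    ("malate", "batch", 0.0, 0.001, None, 0.0),
    ("pyruvate", "batch", 0.0, 0.0, None, 0.0),
    ("acetate", "batch", 0.0, 0.0, None, 0.0),
    ("growth", "fed-batch", 0.031, 0.031, 0.003, 0.0),
    ("o2", "fed-batch", -0.776, -1.2, None, 0.180),
    ("glycerol", "fed-batch", -0.457, -0.47, None, 0.0),
    ("co2", "fed-batch", 0.610, 1.4, None, 0.623),
    ("clavulanate", "fed-batch", 0.004, 0.004, None, 0.0),
    ("succinate", "fed-batch", 0.257, 0.007, None, 0.063),
    ("oxaloacetate", "fed-batch", 0.0, 0.003, None, 0.0),
    ("malate", "fed-batch", 0.0, 0.0, None, 0.0),
    ("pyruvate", "fed-batch", 0.038, 0.005, None, 0.001),
    ("acetate", "fed-batch", 0.0, 0.0, None, 0.0),
]

#: Printed aggregate row of the fed-batch table (sum of the SE column).
FEDBATCH_PRINTED_AGGREGATE = {"batch": 1.700, "fed-batch": 0.860}

#: Constraint role of each measured flux when building a scenario: the
#: growth rate is hard, uptakes are lower bounds, secretions upper bounds.
_ROLES = {
    "growth": "hard_growth",
    "o2": "lower",
    "glycerol": "lower",
    "succinate": "lower",
    "oxaloacetate": "lower",
    "malate": "lower",
    "co2": "upper",
    "pyruvate": "upper",
    "acetate": "upper",
    "clavulanate": "upper",
}

# columns: metabolite, batch, fed_batch, pathway
_SHADOW = [
    ("akg", 0.0, 0.05, "glycolysis_tca"),
    ("pyruvate", 0.0, 0.02, "glycolysis_tca"),
    ("citrate", 0.0, 0.05, "glycolysis_tca"),
    ("isocitrate", 0.0, 0.05, "glycolysis_tca"),
    ("fumarate", 0.0, 0.02, "glycolysis_tca"),
    ("acetate", 0.0, 0.02, "glycolysis_tca"),
    ("succinate", 0.0, 0.02, "glycolysis_tca"),
    ("oxaloacetate", 0.0, 0.02, "glycolysis_tca"),
    ("malate", 0.0, 0.02, "glycolysis_tca"),
    ("e4p", 0.0, -0.40, "pentose_phosphate"),
    ("f6p", 0.0, -0.38, "pentose_phosphate"),
    ("x5p", 0.0, -0.39, "pentose_phosphate"),
    ("s7p", 0.0, -0.37, "pentose_phosphate"),
    ("glutamate", 0.5, 0.05, "amino_acids"),
    ("glutamine", 0.5, 0.05, "amino_acids"),
    ("arginine", 1.5, 0.05, "amino_acids"),
    ("asparagine", 0.5, 0.02, "amino_acids"),
    ("aspartate", 0.5, 0.02, "amino_acids"),
]


def chemostat_validation_table() -> pd.DataFrame:
    """Continuous-culture validation data (three dilution rates)."""
    return pd.DataFrame(
        _CHEMOSTAT,
        columns=["quantity", "dilution", "fba", "exp", "se_printed",
                 "available"],
    )


def fedbatch_comparison_table() -> pd.DataFrame:
    """Batch (36 h) vs fed-batch (48 h) measured and simulated rates."""
    df = pd.DataFrame(
        _FEDBATCH,
        columns=["quantity", "condition", "fba", "exp", "exp_sd",
                 "se_printed"],
    )
    df["role"] = df["quantity"].map(_ROLES)
    return df


def fedbatch_scenario_roles() -> dict[str, str]:
    """Constraint role of each measured quantity (hard/lower/upper)."""
    return dict(_ROLES)


def central_shadow_price_table() -> pd.DataFrame:
    """Shadow prices of central-carbon metabolites under both states."""
    return pd.DataFrame(
        _SHADOW, columns=["metabolite", "batch", "fed_batch", "pathway"]
    )
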