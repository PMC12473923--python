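"""Published population-PK parameter sets for denosumab.

Two estimate sets are provided: one characterizing the rich single-dose
35 mg phase-I-style population (healthy adult men), and the final pooled
set additionally informed by the sparse 60 mg every-6-months
phase-III-style population (postmenopausal women), which carries a study
shift on the apparent volume.

Units: typical values are stored as natural logs of CL/F (L/day at 70 kg),
V/F (L), KA (1/day), Km (mg/L) and Vmax (mg/day).  The Michaelis constant
and maximum saturable rate are interpreted on the mg/L / mg/day scale,
the only reading consistent with 35-120 mg doses and L/day clearances
(the printed ng-scale labels would render the saturable pathway
numerically inert).  IIV is stored as omega^2 with CV% = 100*omega, the
usual reporting convention for exponential random effects.
"""

import math

from .estimation import PopulationModel
from .model_core import FixedEffects, RandomEffectsSpec, ResidualSpec

#: body-weight distributions (mean, SD, lower bound, upper bound), kg
PHASE1_WEIGHT_KG = (82.97, 8.492, 50.0, 130.0)
PHASE3_WEIGHT_KG = (63.196, 8.787, 40.0, 110.0)

#: study sizes of the two source designs
PHASE1_N = 255
PHASE3_N = 555


def phase1_reference_model() -> PopulationModel:
    """Estimates from the rich phase-I-style population (35 mg single dose):
    CL/F 0.123 L/day, V/F 9.33 L, KA 0.406 1/day, BW power on CL 1.32,
    Km 0.124 mg/L, Vmax 0.139 mg/day; IIV CV 37/13/61% on CL/V/KA;
    proportional residual SD 17%."""
    return PopulationModel(
        fixed=FixedEffects(
            mu_cl=math.log(0.123),
            mu_v=math.log(9.33),
            mu_ka=math.log(0.406),
            mu_km=math.log(0.124),
            mu_vm=math.log(0.139),
            beta_bw_cl=1.32,
        ),
        iiv=RandomEffectsSpec(omega2_cl=0.37**2, omega2_v=0.13**2, omega2_ka=0.61**2),
        residual=ResidualSpec(sigma_prop=0.17),
        bw_on_cl=True,
        study_on_v=False,
    )


def pooled_reference_model() -> PopulationModel:
    """Final pooled estimates (phase-I + phase-III populations):
    CL/F 0.143 L/day, V/F 9.00 L (phase-I-like reference study), KA 0.349
    1/day, BW power on CL 1.07, study shift on log V -0.534, Km 0.162 mg/L,
    Vmax 0.128 mg/day; IIV CV 34.6/15.7/60% on CL/V/KA; residual SD 19.5%."""
    return PopulationModel(
        fixed=FixedEffects(
            mu_cl=math.log(0.143),
            mu_v=math.log(9.00),
            mu_ka=math.log(0.349),
            mu_km=math.log(0.162),
            mu_vm=math.log(0.128),
            beta_bw_cl=1.07,
            beta_study_v=-0.534,
        ),
        iiv=RandomEffectsSpec(
            omega2_cl=0.346**2, omega2_v=0.157**2, omega2_ka=0.60**2
        ),
        residual=ResidualSpec(sigma_prop=0.195),
        bw_on_cl=True,
        study_on_v=True,
    )


def generic_init_model(study_on_v: bool = False) -> PopulationModel:
    """A deliberately off-target starting point for fitting (typical
    mAb-scale values), so recovery fits exercise real optimization."""
    return PopulationModel(
        fixed=FixedEffects(
            mu_cl=math.log(0.2),
            mu_v=math.log(12.0),
            mu_ka=math.log(0.3),
            mu_km=math.log(0.3),
            mu_vm=math.log(0.3),
            beta_bw_cl=0.75,
            beta_study_v=0.0 if study_on_v else 0.0,
        ),
        iiv=RandomEffectsSpec(omega2_cl=0.1, omega2_v=0.1, omega2_ka=0.25),
        residual=ResidualSpec(sigma_prop=0.25),
        bw_on_cl=True,
        study_on_v=study_on_v,
    )
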