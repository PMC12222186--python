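"""Normalize salinity units to EC and derive the effect-size quantities.

Salinity is reported in the literature as electrical conductivity (dS/m),
molar NaCl, or ppm NaCl; everything downstream of ingestion works on EC.
"""

from saltmeta import (
    ObservationRecord,
    SalinityMeasure,
    SalinityUnit,
    Setting,
    Stage,
    Variable,
    VariableKey,
    derive_relative,
    ec_from_unit,
    parse_salinity,
)

print("1 M NaCl     ->", ec_from_unit(1.0, SalinityUnit.MOL_PER_L_NACL), "dS/m")
print("1000 ppm NaCl->", ec_from_unit(1000.0, SalinityUnit.PPM_NACL), "dS/m")
print("'150 mM'     ->", parse_salinity("150 mM").to_ec(), "dS/m")

# A study grew wheat at control EC 2 dS/m and stress EC 12 dS/m for 20 days
# (vegetative stage) and saw shoot dry weight drop from 100 to 50 g.
record = ObservationRecord(
    study_id="demo",
    experiment_id="E1",
    setting=Setting.GREENHOUSE,
    variable=VariableKey(Variable.SHOOT_DW, Stage.VEGETATIVE),
    control_salinity=SalinityMeasure(2.0, SalinityUnit.DS_PER_M),
    stress_salinity=SalinityMeasure(12.0, SalinityUnit.DS_PER_M),
    control_value=100.0,
    stress_value=50.0,
    stress_duration_days=20.0,
)
rel = derive_relative(record)
print("relative EC      :", rel.relative_ec, "dS/m   (stress EC - control EC)")
print("relative response:", rel.relative_response, "      (stress/control; <1 = decrease)")
print("stress integral  :", rel.stress_integral, "dS*day/m (EC x duration)")
print("stress axis      :", rel.stress_axis.value, "(vegetative growth uses the integral)")
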