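# Limb-circumference predictive-equation registry.
#
# Each entry declares the predictor form, the log10-linear coefficients,
# input units (always millimetres), the declared output unit (g or kg;
# converted to kg at the boundary) and a prediction-interval method:
#   log_se        -> param is a log10-space half-width (optionally with a
#                    t-distribution df)
#   percent_error -> param is a symmetric percent prediction error
#
# Published equations ship as STUBS (coefficients: null) carrying only
# provenance: their coefficients are facts of the cited literature and must
# be copied in by the user from the original sources before use.  The
# synthetic_example entry is fully configured and exists for demonstrations
# and tests.
equations:
  - id: synthetic_example
    predictor: summed_circumference
    coefficients:
      slopes: [2.0]
      intercept: 0.0
    output_unit: g
    pi:
      method: percent_error
      param: 25.0
    citation: "synthetic demonstration equation (not from the literature)"

  - id: CE2012_b
    predictor: summed_circumference
    coefficients: null
    output_unit: g
    citation: "Campione & Evans 2012, bivariate stylopodial-circumference equation"

  - id: CE2012_m
    predictor: separate_circumferences
    coefficients: null
    output_unit: g
    citation: "Campione & Evans 2012, multivariate equation"

  - id: An1985
    predictor: summed_circumference
    coefficients: null
    output_unit: kg
    citation: "Anderson et al. 1985 (as modified for quadrupeds)"

  - id: M2004
    predictor: femur_circumference
    coefficients: null
    output_unit: kg
    citation: "Mazzetta et al. 2004 (modified)"
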