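# Worked simulation config: 300 simulated patients spread over the
# severity continuum, each judging a fixed set of 12 states against
# their own first-stage classification.
system: eq5d3l
seed: 2026
n_respondents: 300
theta_dist: {family: normal, loc: -2.0, scale: 1.5}
theta_mode: free
gamma:
  "mobility:2": -0.25
  "mobility:3": -0.90
  "self_care:2": -0.20
  "self_care:3": -0.75
  "usual_activities:2": -0.15
  "usual_activities:3": -0.60
  "pain_discomfort:2": -0.30
  "pain_discomfort:3": -1.00
  "anxiety_depression:2": -0.20
  "anxiety_depression:3": -0.80
# the single-deviation states at both severity levels span the full
# design space, so gamma is identified even in free-theta mode
design:
  kind: fixed_set
  states: ["21111", "31111", "12111", "13111", "11211", "11311",
           "11121", "11131", "11112", "11113", "22222", "33333"]
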