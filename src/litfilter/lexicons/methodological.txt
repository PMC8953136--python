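# Study-design and methods vocabulary: would bias the filter toward a design.
study
studies
trial
trials
randomized
randomised
randomization
controlled
control
cohort
cross
sectional
observational
retrospective
prospective
survey
surveys
questionnaire
interview
interviews
qualitative
quantitative
systematic
review article
meta
analysis
analyses
method
methods
design
protocol
baseline
follow
followup
outcome measure
sample
participants
recruitment
blinded
placebo
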