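# Generic terms: single words too broad to carry the topical concept
# when used outside a phrase.
use
using
used
effect
effects
outcome
outcomes
result
results
associated
association
impact
improve
improvement
increase
decrease
change
changes
management
intervention
interventions
treatment
treatments
therapy
health
healthcare
clinical
medical
quality
risk
risks
time
year
years
common
potential
potentially
related
based
approach
process
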