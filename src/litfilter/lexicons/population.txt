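# Population descriptors: would focus the filter on one patient group.
older
elderly
aged
age
geriatric
seniors
adults
adult
patient
patients
people
women
men
children
frail
frailty
veterans
residents
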