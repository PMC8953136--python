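# Care-setting descriptors: would focus the filter on one setting.
hospital
hospitals
hospitalized
hospitalised
nursing
home
homes
community
primary
care
ward
wards
clinic
clinics
ambulatory
outpatient
inpatient
facility
facilities
pharmacy
pharmacies
general practice
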