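dr	doctor
appt	appointment
hr	hour
min	minute
meds	medication
er	emergency
op	operation
temp	temperature
info	information
dept	department
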