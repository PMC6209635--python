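# ASTM E1840-96 Raman shift standard positions (cm-1) for the two chemical
# standards used for standard-scattering-shift axis calibration.
compound,shift_cm1,sd_cm1
acetaminophen,329.2,0.5
acetaminophen,390.9,0.8
acetaminophen,465.1,0.3
acetaminophen,504.0,0.6
acetaminophen,651.6,0.5
acetaminophen,710.8,0.7
acetaminophen,797.2,0.5
acetaminophen,834.5,0.5
acetaminophen,857.9,0.5
acetaminophen,968.7,0.6
acetaminophen,1105.5,0.3
acetaminophen,1168.5,0.6
acetaminophen,1236.8,0.5
acetaminophen,1278.5,0.5
acetaminophen,1323.9,0.5
acetaminophen,1371.5,0.1
acetaminophen,1515.1,0.7
acetaminophen,1561.5,0.5
acetaminophen,1648.4,0.5
cyclohexane,384.1,0.8
cyclohexane,426.3,0.4
cyclohexane,801.3,0.96
cyclohexane,1028.3,0.5
cyclohexane,1157.6,0.9
cyclohexane,1266.4,0.6
cyclohexane,1444.4,0.3
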