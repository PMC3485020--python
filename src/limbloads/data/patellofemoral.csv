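# Frictionless-pulley patella tables vs knee flexion. tendon_ratio is the
# patellar-tendon : quadriceps-tendon force ratio rho(flexion); included_deg
# is the angle between the quadriceps-tendon and patellar-tendon pulls on the
# patella (180 deg = collinear opposing pulls, so contact -> 0 at full
# extension). Values are a monotone, editable placeholder representative of
# published patellar-mechanism data; linear interpolation between rows.
flexion_rad,tendon_ratio,included_deg
0.00,1.00,178.0
0.35,0.97,160.0
0.70,0.92,143.0
1.05,0.85,127.0
1.40,0.78,113.0
1.75,0.72,102.0
2.10,0.68,95.0
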