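# Segment inertial scaling coefficients (adult male), after the adjusted
# Zatsiorsky-Seluyanov tables. mass_frac: fraction of body mass. length_frac:
# segment length as fraction of stature. com_*: centre-of-mass offset from the
# segment origin as fractions of segment length (segment frames: x anterior,
# y up/longitudinal, z right-lateral; origins at the proximal joint centre,
# foot origin at the ankle). r_*: radii of gyration about the local axes as
# fractions of segment length. The shank r_x and r_z are symmetrized to a
# single value so its tensor is exactly axisymmetric about the long axis.
# "pelvis" is the lower-trunk entry; its origin is the right hip centre.
segment,mass_frac,length_frac,com_x,com_y,com_z,r_x,r_y,r_z
foot,0.0137,0.152,0.140,-0.128,0.0,0.124,0.257,0.245
shank,0.0433,0.246,0.0,-0.4459,0.0,0.2485,0.102,0.2485
thigh,0.1416,0.245,0.0,-0.4095,0.0,0.329,0.149,0.329
pelvis,0.1117,0.105,-0.25,0.45,-0.85,0.615,0.587,0.551
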