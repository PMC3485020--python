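# Reference marker clouds: fixed marker positions in segment-local
# coordinates (m) for the 1.79 m reference skeleton. Four non-collinear
# markers per segment; the synthetic generator places these and the pose
# reconstruction uses them as Horn reference clouds.
segment,label,x,y,z
foot,heel,-0.050,-0.060,0.010
foot,toe,0.180,-0.065,-0.020
foot,meta5,0.120,-0.060,0.040
foot,navic,0.020,0.000,0.030
shank,tib_tub,0.040,-0.080,0.000
shank,shank_lat,0.000,-0.200,0.050
shank,med_mal,0.000,-0.420,-0.035
shank,fib_head,-0.020,-0.040,0.040
thigh,thigh_ant,0.030,-0.150,0.040
thigh,thigh_lat,0.000,-0.300,0.060
thigh,knee_lat,0.040,-0.420,0.000
thigh,thigh_post,-0.030,-0.250,0.030
pelvis,rasi,0.060,0.050,0.020
pelvis,lasi,0.060,0.050,-0.200
pelvis,sacr,-0.090,0.040,-0.090
pelvis,rpsi,-0.080,0.050,0.000
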