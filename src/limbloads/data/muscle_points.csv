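# Muscle path points in segment-local coordinates (m) for the 1.79 m
# reference skeleton. idx orders the path from origin (0) to insertion (last);
# intermediate rows are fixed via points. Segment frames: origin at the
# proximal joint centre (foot: at the ankle), x anterior, y up, z lateral
# (right side). Shank origin is the knee centre, thigh origin the hip centre,
# pelvis origin the right hip centre. The quadriceps/patellar via point is a
# fixed thigh-frame stand-in for the patellar mechanism, placed so the
# extensor moment arm stays positive over the whole flexion range.
name,idx,segment,x,y,z
soleus,0,shank,-0.020,-0.100,0.005
soleus,1,foot,-0.060,-0.040,0.000
gastroc_med,0,thigh,-0.025,-0.410,-0.020
gastroc_med,1,foot,-0.060,-0.040,-0.005
gastroc_lat,0,thigh,-0.025,-0.410,0.020
gastroc_lat,1,foot,-0.060,-0.040,0.005
tib_ant,0,shank,0.010,-0.130,0.010
tib_ant,1,foot,0.055,-0.030,-0.025
tib_post,0,shank,-0.015,-0.150,0.000
tib_post,1,shank,-0.010,-0.420,-0.030
tib_post,2,foot,0.070,-0.040,-0.040
per_long,0,shank,-0.005,-0.100,0.025
per_long,1,shank,-0.010,-0.420,0.035
per_long,2,foot,0.045,-0.050,0.000
plantaris,0,thigh,-0.020,-0.400,0.022
plantaris,1,foot,-0.055,-0.035,0.000
vas_lat,0,thigh,0.015,-0.250,0.030
vas_lat,1,thigh,0.050,-0.500,0.005
vas_lat,2,shank,0.040,-0.060,0.000
vas_med,0,thigh,0.015,-0.300,-0.025
vas_med,1,thigh,0.050,-0.500,-0.005
vas_med,2,shank,0.040,-0.060,0.000
vas_int,0,thigh,0.020,-0.220,0.000
vas_int,1,thigh,0.050,-0.500,0.000
vas_int,2,shank,0.040,-0.060,0.000
rect_fem,0,pelvis,0.030,0.020,0.005
rect_fem,1,thigh,0.050,-0.500,0.000
rect_fem,2,shank,0.040,-0.060,0.000
bf_long,0,pelvis,-0.050,-0.040,-0.020
bf_long,1,shank,-0.025,-0.035,0.035
bf_short,0,thigh,-0.015,-0.250,0.010
bf_short,1,shank,-0.025,-0.035,0.033
semiten,0,pelvis,-0.050,-0.040,-0.025
semiten,1,shank,0.015,-0.080,-0.028
semimem,0,pelvis,-0.055,-0.035,-0.020
semimem,1,shank,-0.025,-0.025,-0.025
popliteus,0,thigh,-0.020,-0.430,0.026
popliteus,1,shank,-0.030,-0.060,0.000
gracilis,0,pelvis,0.010,-0.050,-0.060
gracilis,1,shank,0.010,-0.085,-0.028
sartorius,0,pelvis,0.035,0.030,0.020
sartorius,1,thigh,-0.010,-0.380,-0.045
sartorius,2,shank,0.015,-0.075,-0.030
tfl,0,pelvis,0.025,0.045,0.045
tfl,1,thigh,0.000,-0.300,0.045
tfl,2,shank,0.025,-0.045,0.030
glut_max,0,pelvis,-0.075,0.030,-0.020
glut_max,1,thigh,-0.025,-0.120,0.030
glut_med_ant,0,pelvis,0.030,0.050,0.035
glut_med_ant,1,thigh,0.005,-0.020,0.045
glut_med_post,0,pelvis,-0.040,0.050,0.030
glut_med_post,1,thigh,-0.005,-0.020,0.045
iliopsoas,0,pelvis,0.020,0.040,-0.020
iliopsoas,1,pelvis,0.035,0.000,0.000
iliopsoas,2,thigh,-0.010,-0.050,-0.010
add_long,0,pelvis,0.015,-0.045,-0.050
add_long,1,thigh,-0.010,-0.200,-0.005
add_mag,0,pelvis,-0.045,-0.050,-0.030
add_mag,1,thigh,-0.012,-0.240,-0.010
piriformis,0,pelvis,-0.060,0.020,-0.060
piriformis,1,thigh,0.000,-0.010,0.040
quad_fem,0,pelvis,-0.050,-0.040,-0.035
quad_fem,1,thigh,-0.015,-0.030,0.030
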