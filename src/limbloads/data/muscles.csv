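# Reduced 27-element right lower-limb muscle set. PCSA (cm^2) values are
# representative of published cadaveric tables for the major actuators;
# coordinates live in muscle_points.csv. "crosses" declares the joints a
# muscle spans (used to build the moment-arm matrix; never inferred).
# Reference stature for the geometry: 1.79 m.
name,pcsa_cm2,crosses
soleus,60.0,ankle
gastroc_med,26.0,knee;ankle
gastroc_lat,16.0,knee;ankle
tib_ant,14.0,ankle
tib_post,20.0,ankle
per_long,13.0,ankle
plantaris,1.5,knee;ankle
vas_lat,70.0,knee
vas_med,55.0,knee
vas_int,45.0,knee
rect_fem,40.0,hip;knee
bf_long,27.0,hip;knee
bf_short,7.0,knee
semiten,14.0,hip;knee
semimem,19.0,hip;knee
popliteus,2.5,knee
gracilis,2.3,hip;knee
sartorius,1.9,hip;knee
tfl,2.5,hip;knee
glut_max,45.0,hip
glut_med_ant,20.0,hip
glut_med_post,20.0,hip
iliopsoas,25.0,hip
add_long,6.5,hip
add_mag,25.0,hip
piriformis,16.0,hip
quad_fem,16.0,hip
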