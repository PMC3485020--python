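# Flexion-dependent effectiveness of the cruciate ligaments in resisting
# anterior (ACL) and posterior (PCL) tibial shear. The resisted magnitude
# reported for the recruited ligament is |shear_ap| x factor; ligaments carry
# no load inside the equilibrium. Placeholder table, linear interpolation.
flexion_rad,acl_factor,pcl_factor
0.00,1.00,0.80
0.35,0.95,0.85
0.70,0.85,0.92
1.05,0.75,0.97
1.40,0.68,1.00
1.75,0.62,1.00
2.10,0.58,1.00
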