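# Synthetic stand-in hydraulic table for a Hagerstown-like silt loam
# (9.4/67.1/23.5 sand/silt/clay), indexed by bulk density. Values approximate
# ROSETTA-style pedotransfer behaviour: saturated water content tracks porosity
# minus entrapped air, n and Ks decline with compaction. alpha_vg is per kPa.
bulk_density,theta_r,theta_s,alpha_vg,n_vg,ks_cm_d
1.0,0.065,0.603,0.052,1.450,25.00
1.1,0.065,0.565,0.051,1.435,18.40
1.2,0.065,0.527,0.050,1.420,13.60
1.3,0.065,0.489,0.049,1.405,10.00
1.4,0.065,0.452,0.048,1.390,7.40
1.5,0.065,0.414,0.047,1.375,5.40
1.6,0.065,0.376,0.046,1.360,4.00
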