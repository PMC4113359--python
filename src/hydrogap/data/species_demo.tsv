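# Illustrative (synthetic) three-species parameterization for an evergreen
# broad-leaved temperate rainforest: a shade-tolerant conifer-like canopy
# species, a mid-tolerant broadleaf, and a light-demanding pioneer.
# These values are demo magnitudes, NOT a published calibration; replace
# this file with a site calibration for quantitative work.
species_id	pmax	alpha_light	light_extinction_k	leaf_transmittance_m	resp_maintenance	resp_growth	h_max	h_half	cd_per_dbh	crown_length_frac	crown_lai	form_factor	wood_density	max_dbh	mort_background	mort_slow	slow_growth_dbh	max_recruits	light_threshold
shadetol_conifer	2.0	0.06	0.6	0.1	0.018	0.25	32	60	0.126	0.5	5.0	0.5	0.55	120	0.012	0.025	0.03	2	0.03
midtol_broadleaf	3.0	0.05	0.55	0.1	0.025	0.25	28	45	0.112	0.45	4.5	0.48	0.5	90	0.015	0.04	0.05	3	0.1
pioneer_broadleaf	4.5	0.045	0.5	0.1	0.035	0.25	35	40	0.098	0.4	4.0	0.45	0.45	100	0.02	0.06	0.08	1.5	0.35
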