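# Placeholder per-class management costs and topsoil carbon densities for the
# synthetic generator. Ordering is calibrated qualitatively (forest and
# successional management cheap, intensive agriculture expensive); absolute
# values are synthetic stand-ins, not published figures.
lulc_class,cost_eur_ha_yr,soil_carbon_mg_c_km2
forests,110,9500
pastureland,450,7000
old_field_succession,60,8200
other_agricultural,520,5500
urban_artificial,0,2000
other_non_agricultural,80,4000
permanent_cultures,2400,5200
fields_gardens,1600,4800
water_bodies,40,600
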