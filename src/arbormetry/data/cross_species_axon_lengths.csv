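label,species,system,route,n_neurons,axon_density_um_per_um3,target_volume_mm3,total_axon_length_m,total_varicosities,varicosity_rate_low_per_um,varicosity_rate_high_per_um,printed_value,printed_unit,printed_value_high
mouse_chol_total_n6632,mouse,cholinergic,total,6632,,,1300,,,,20,cm,
mouse_chol_total_n4500,mouse,cholinergic,total,4500,,,1300,,,,29,cm,
mouse_chol_density_low_n6632,mouse,cholinergic,density,6632,0.020,109,,,,,33,cm,
mouse_chol_density_high_n6632,mouse,cholinergic,density,6632,0.044,109,,,,,72,cm,
mouse_chol_density_low_n4500,mouse,cholinergic,density,4500,0.020,109,,,,,48,cm,
mouse_chol_density_high_n4500,mouse,cholinergic,density,4500,0.044,109,,,,,107,cm,
rat_chol_density,rat,cholinergic,density,7312,0.0113,400,,,,,62,cm,
chimp_chol_density,chimpanzee,cholinergic,density,315000,0.066,147000,,,,,31,m,
human_chol_density,human,cholinergic,density,435000,0.080,583000,,,,,107,m,
rat_dopa_total,rat,dopaminergic,total,14000,,,7900,,,,56,cm,
rat_dopa_varicosity,rat,dopaminergic,varicosity,7000,,,,3.4e9,0.7142857142857143,1.0,55,cm,77
rat_sero_density_n11500,rat,serotonergic,density,11500,0.023,400,,,,,80,cm,
rat_sero_density_n15191,rat,serotonergic,density,15191,0.023,400,,,,,61,cm,
human_sero_density_n80386,human,serotonergic,density,80386,0.048,583000,,,,,348,m,
human_sero_density_n86565,human,serotonergic,density,86565,0.048,583000,,,,,323,m,
human_sero_density_n165000,human,serotonergic,density,165000,0.048,583000,,,,,170,m,
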