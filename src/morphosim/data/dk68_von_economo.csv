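region,von_economo_class
lh_bankssts,association
lh_caudalanteriorcingulate,limbic
lh_caudalmiddlefrontal,association
lh_cuneus,secondary_sensory
lh_entorhinal,limbic
lh_fusiform,association
lh_inferiorparietal,association
lh_inferiortemporal,association
lh_isthmuscingulate,limbic
lh_lateraloccipital,secondary_sensory
lh_lateralorbitofrontal,association
lh_lingual,secondary_sensory
lh_medialorbitofrontal,limbic
lh_middletemporal,association
lh_parahippocampal,limbic
lh_paracentral,primary_motor
lh_parsopercularis,association
lh_parsorbitalis,association
lh_parstriangularis,association
lh_pericalcarine,primary_sensory
lh_postcentral,primary_sensory
lh_posteriorcingulate,limbic
lh_precentral,primary_motor
lh_precuneus,association
lh_rostralanteriorcingulate,limbic
lh_rostralmiddlefrontal,association
lh_superiorfrontal,association
lh_superiorparietal,association
lh_superiortemporal,association
lh_supramarginal,association
lh_frontalpole,association
lh_temporalpole,limbic
lh_transversetemporal,primary_sensory
lh_insula,insular
rh_bankssts,association
rh_caudalanteriorcingulate,limbic
rh_caudalmiddlefrontal,association
rh_cuneus,secondary_sensory
rh_entorhinal,limbic
rh_fusiform,association
rh_inferiorparietal,association
rh_inferiortemporal,association
rh_isthmuscingulate,limbic
rh_lateraloccipital,secondary_sensory
rh_lateralorbitofrontal,association
rh_lingual,secondary_sensory
rh_medialorbitofrontal,limbic
rh_middletemporal,association
rh_parahippocampal,limbic
rh_paracentral,primary_motor
rh_parsopercularis,association
rh_parsorbitalis,association
rh_parstriangularis,association
rh_pericalcarine,primary_sensory
rh_postcentral,primary_sensory
rh_posteriorcingulate,limbic
rh_precentral,primary_motor
rh_precuneus,association
rh_rostralanteriorcingulate,limbic
rh_rostralmiddlefrontal,association
rh_superiorfrontal,association
rh_superiorparietal,association
rh_superiortemporal,association
rh_supramarginal,association
rh_frontalpole,association
rh_temporalpole,limbic
rh_transversetemporal,primary_sensory
rh_insula,insular
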