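name	hemisphere	kind	dim
lh_bankssts	left	cortical	3
lh_caudalanteriorcingulate	left	cortical	3
lh_caudalmiddlefrontal	left	cortical	3
lh_cuneus	left	cortical	3
lh_entorhinal	left	cortical	3
lh_fusiform	left	cortical	3
lh_inferiorparietal	left	cortical	3
lh_inferiortemporal	left	cortical	3
lh_isthmuscingulate	left	cortical	3
lh_lateraloccipital	left	cortical	3
lh_lateralorbitofrontal	left	cortical	3
lh_lingual	left	cortical	3
lh_medialorbitofrontal	left	cortical	3
lh_middletemporal	left	cortical	3
lh_parahippocampal	left	cortical	3
lh_paracentral	left	cortical	3
lh_parsopercularis	left	cortical	3
lh_parsorbitalis	left	cortical	3
lh_parstriangularis	left	cortical	3
lh_pericalcarine	left	cortical	3
lh_postcentral	left	cortical	3
lh_posteriorcingulate	left	cortical	3
lh_precentral	left	cortical	3
lh_precuneus	left	cortical	3
lh_rostralanteriorcingulate	left	cortical	3
lh_rostralmiddlefrontal	left	cortical	3
lh_superiorfrontal	left	cortical	3
lh_superiorparietal	left	cortical	3
lh_superiortemporal	left	cortical	3
lh_supramarginal	left	cortical	3
lh_frontalpole	left	cortical	3
lh_temporalpole	left	cortical	3
lh_transversetemporal	left	cortical	3
lh_insula	left	cortical	3
rh_bankssts	right	cortical	3
rh_caudalanteriorcingulate	right	cortical	3
rh_caudalmiddlefrontal	right	cortical	3
rh_cuneus	right	cortical	3
rh_entorhinal	right	cortical	3
rh_fusiform	right	cortical	3
rh_inferiorparietal	right	cortical	3
rh_inferiortemporal	right	cortical	3
rh_isthmuscingulate	right	cortical	3
rh_lateraloccipital	right	cortical	3
rh_lateralorbitofrontal	right	cortical	3
rh_lingual	right	cortical	3
rh_medialorbitofrontal	right	cortical	3
rh_middletemporal	right	cortical	3
rh_parahippocampal	right	cortical	3
rh_paracentral	right	cortical	3
rh_parsopercularis	right	cortical	3
rh_parsorbitalis	right	cortical	3
rh_parstriangularis	right	cortical	3
rh_pericalcarine	right	cortical	3
rh_postcentral	right	cortical	3
rh_posteriorcingulate	right	cortical	3
rh_precentral	right	cortical	3
rh_precuneus	right	cortical	3
rh_rostralanteriorcingulate	right	cortical	3
rh_rostralmiddlefrontal	right	cortical	3
rh_superiorfrontal	right	cortical	3
rh_superiorparietal	right	cortical	3
rh_superiortemporal	right	cortical	3
rh_supramarginal	right	cortical	3
rh_frontalpole	right	cortical	3
rh_temporalpole	right	cortical	3
rh_transversetemporal	right	cortical	3
rh_insula	right	cortical	3
Left-Cerebellum-White-Matter	left	noncortical	1
Left-Cerebellum-Cortex	left	noncortical	1
Left-Thalamus	left	noncortical	1
Left-Caudate	left	noncortical	1
Left-Putamen	left	noncortical	1
Left-Pallidum	left	noncortical	1
Left-Hippocampus	left	noncortical	1
Left-Amygdala	left	noncortical	1
Left-Accumbens-area	left	noncortical	1
Right-Cerebellum-White-Matter	right	noncortical	1
Right-Cerebellum-Cortex	right	noncortical	1
Right-Thalamus	right	noncortical	1
Right-Caudate	right	noncortical	1
Right-Putamen	right	noncortical	1
Right-Pallidum	right	noncortical	1
Right-Hippocampus	right	noncortical	1
Right-Amygdala	right	noncortical	1
Right-Accumbens-area	right	noncortical	1
Brain-Stem	bilateral-midline	noncortical	1
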