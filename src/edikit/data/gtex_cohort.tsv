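tissue	body_site	n_samples
Artery	Aorta	14
Artery	Tibial	14
Brain	Amygdala	13
Brain	Cerebellum	12
Brain	Frontal cortex	13
Brain	Hippocampus	11
Brain	Hypothalamus	14
Brain	Spinal cord	10
Lung	Lung	9
Muscle	Skeletal	13
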