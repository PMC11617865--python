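Left-Thalamus-Proper
Right-Thalamus-Proper
Left-Caudate
Right-Caudate
Left-Putamen
Right-Putamen
Left-Pallidum
Right-Pallidum
Left-Hippocampus
Right-Hippocampus
Left-Amygdala
Right-Amygdala
Cingulate-Posterior
Cingulate-Mid-Posterior
Cingulate-Central
Cingulate-Mid-Anterior
Cingulate-Anterior
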