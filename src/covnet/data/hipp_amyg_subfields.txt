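Left-Hippocampal_tail
Left-subiculum-body
Left-subiculum-head
Left-CA1-body
Left-CA1-head
Left-CA3-body
Left-CA3-head
Left-CA4-body
Left-CA4-head
Left-GC-ML-DG-body
Left-GC-ML-DG-head
Left-molecular_layer_HP-body
Left-molecular_layer_HP-head
Left-presubiculum-body
Left-presubiculum-head
Left-parasubiculum
Left-HATA
Left-fimbria
Left-hippocampal-fissure
Left-Lateral-nucleus
Left-Basal-nucleus
Left-Accessory-Basal-nucleus
Left-Anterior-amygdaloid-area-AAA
Left-Central-nucleus
Left-Medial-nucleus
Left-Cortical-nucleus
Left-Corticoamygdaloid-transitio
Left-Paralaminar-nucleus
Right-Hippocampal_tail
Right-subiculum-body
Right-subiculum-head
Right-CA1-body
Right-CA1-head
Right-CA3-body
Right-CA3-head
Right-CA4-body
Right-CA4-head
Right-GC-ML-DG-body
Right-GC-ML-DG-head
Right-molecular_layer_HP-body
Right-molecular_layer_HP-head
Right-presubiculum-body
Right-presubiculum-head
Right-parasubiculum
Right-HATA
Right-fimbria
Right-hippocampal-fissure
Right-Lateral-nucleus
Right-Basal-nucleus
Right-Accessory-Basal-nucleus
Right-Anterior-amygdaloid-area-AAA
Right-Central-nucleus
Right-Medial-nucleus
Right-Cortical-nucleus
Right-Corticoamygdaloid-transitio
Right-Paralaminar-nucleus
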