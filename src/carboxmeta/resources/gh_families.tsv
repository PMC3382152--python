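family	function_group
GH5	cellulases
GH6	cellulases
GH7	cellulases
GH9	cellulases
GH44	cellulases
GH45	cellulases
GH48	cellulases
GH8	endohemicellulases
GH10	endohemicellulases
GH11	endohemicellulases
GH12	endohemicellulases
GH26	endohemicellulases
GH28	endohemicellulases
GH53	endohemicellulases
GH51	debranching_enzymes
GH54	debranching_enzymes
GH62	debranching_enzymes
GH67	debranching_enzymes
GH78	debranching_enzymes
GH1	oligosaccharide_degradation
GH2	oligosaccharide_degradation
GH3	oligosaccharide_degradation
GH29	oligosaccharide_degradation
GH35	oligosaccharide_degradation
GH38	oligosaccharide_degradation
GH39	oligosaccharide_degradation
GH42	oligosaccharide_degradation
GH43	oligosaccharide_degradation
GH52	oligosaccharide_degradation
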