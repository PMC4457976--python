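stratum,category,measured_ev
urban,basic_medical,1957673
urban,nursing,311082
urban,pharmacy,663543
urban,auxiliary_exam,245811
urban,nephsp,3520967
suburban,basic_medical,2553832
suburban,nursing,226897
suburban,pharmacy,621532
suburban,auxiliary_exam,555615
suburban,nephsp,1993810
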