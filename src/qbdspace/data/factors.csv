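name,unit,center,half_range,discrete
extraction_time,h,1.25,0.75,False
wm_ratio,g/g,8,2,False
extraction_number,-,2,1,True
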