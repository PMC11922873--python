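endpoint,pattern,match_mode
dyskinesia,dyskinesia,keyword
dyskinesia,dystonia,keyword
dyskinesia,hyperkinesia,keyword
dyskinesia,ballismus,keyword
dyskinesia,alien limb syndrome,keyword
wearing_off,therapeutic response shortened,keyword
wearing_off,therapeutic response incomplete,keyword
on_off_phenomenon,On and off phenomenon,exact_pt
freezing_phenomenon,Freezing phenomenon,exact_pt
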