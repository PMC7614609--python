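analysis_index,successes_control,total_control,successes_treatment,total_treatment
1,12,97,27,101
2,21,134,42,143
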