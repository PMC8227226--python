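t_count,m_count,score
1,1,-0.0121
1,2,-0.0185
1,3,-0.0228
1,4,-0.0251
1,5,-0.0243
1,6,-0.0230
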