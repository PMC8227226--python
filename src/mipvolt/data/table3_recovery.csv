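matrix,spiked_uM,mean_uM,printed_recovery_pct,printed_rsd_pct
plasma,25,22.9,91.61,6.58
plasma,40,38.98,97.45,3.84
urine,25,23.71,94.84,8.88
urine,40,39.27,98.19,7.81
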