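# Affymetrix probe set -> canonical Agilent probe (best sequence match)
230356_at	A_32_P104334
209602_s_at	A_23_P75056
203963_at	A_23_P372234
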