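# Consensus terminal motifs for the default antibody-chain terminus classifier.
# class<TAB>motif  (I/L comparison is done in Leu-space)
LC-START	DIQMTQSP
LC-START	EIVLTQSP
LC-START	QSVLTQPP
LC-END	WVFNRGEC
Fd-START	EVQLVESG
Fd-START	QVQLVQSG
Fd-START	QVTLKESG
Fd-END	SCPAPELLG
Fc/2-START	GPSVFLFP
Fc/2-END	SLSLSPGK
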