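# position_bp	name	role	occupied
50	full_complex	repressor	1
100	dStat	activator	1
160	full_complex	repressor	1
230	Zld	activator	1
290	full_complex	repressor	1
360	dStat	activator	1
410	full_complex	repressor	1
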