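>cebp
A	0.8500	0.0500	0.0500	0.0500	0.0500	0.0500	0.0500	0.8500	0.8500	0.0500
C	0.0500	0.0500	0.0500	0.0500	0.8500	0.0500	0.8500	0.0500	0.0500	0.0500
G	0.0500	0.0500	0.0500	0.8500	0.0500	0.8500	0.0500	0.0500	0.0500	0.0500
T	0.0500	0.8500	0.8500	0.0500	0.0500	0.0500	0.0500	0.0500	0.0500	0.8500
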