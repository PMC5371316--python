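>axin1_380_490_synthetic | synthetic stand-in for human Axin-1 residues 380-490; helix-prone blocks at 390-420 and 460-480, coil-prone linker at 420-460, Arg/Glu pairs at 401-404, 403-410, 412-420
SSDNEQHSTGAEQLAEKLRAARLREALKAQEARALEQKLAEGSPGNSTDGPSNGSDQTSG
GSDALKSNTGPDSGNSTSGHSAQELLRKAEELKAQALEKRAEKLSAQGNSD
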