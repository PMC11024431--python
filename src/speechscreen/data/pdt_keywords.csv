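word
niño
niña
madre
galleta
tarro
taburete
fregadero
agua
plato
ventana
cortina
jardín
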