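word
manzana
pera
plátano
naranja
limón
fresa
uva
melón
sandía
melocotón
albaricoque
cereza
ciruela
kiwi
piña
mango
papaya
granada
higo
níspero
mandarina
pomelo
frambuesa
mora
arándano
coco
aguacate
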