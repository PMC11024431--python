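word
fútbol
baloncesto
tenis
natación
ciclismo
atletismo
balonmano
voleibol
golf
boxeo
judo
kárate
esquí
senderismo
pádel
rugby
béisbol
hockey
gimnasia
remo
vela
surf
escalada
esgrima
petanca
patinaje
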