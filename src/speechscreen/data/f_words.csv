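word
foca
flor
fuego
familia
fiesta
feliz
faro
farol
fácil
falda
fama
farmacia
favor
febrero
fecha
feo
feria
ferrocarril
ficha
fideo
fiebre
figura
fila
filete
final
fino
firma
física
flaco
flauta
flecha
foto
frase
fresa
frío
fruta
fuente
fuerte
fuerza
función
fútbol
futuro
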