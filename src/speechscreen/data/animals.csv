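word,subcategory
perro,mascotas
gato,mascotas
hámster,mascotas
conejo,mascotas
conejo,granja
cobaya,mascotas
tortuga,mascotas
loro,mascotas
loro,aves
canario,mascotas
canario,aves
periquito,mascotas
periquito,aves
vaca,granja
toro,granja
caballo,granja
burro,granja
mula,granja
oveja,granja
cabra,granja
cerdo,granja
gallina,granja
gallina,aves
gallo,granja
gallo,aves
pato,granja
pato,aves
león,salvajes
tigre,salvajes
elefante,salvajes
jirafa,salvajes
cebra,salvajes
mono,salvajes
gorila,salvajes
oso,salvajes
lobo,salvajes
zorro,salvajes
ciervo,salvajes
jabalí,salvajes
rinoceronte,salvajes
hipopótamo,salvajes
leopardo,salvajes
pantera,salvajes
camello,salvajes
canguro,salvajes
serpiente,salvajes
cocodrilo,salvajes
águila,aves
búho,aves
paloma,aves
gorrión,aves
cigüeña,aves
golondrina,aves
cuervo,aves
gaviota,aves
gaviota,peces_y_mar
avestruz,aves
flamenco,aves
pingüino,aves
pingüino,peces_y_mar
atún,peces_y_mar
sardina,peces_y_mar
salmón,peces_y_mar
trucha,peces_y_mar
merluza,peces_y_mar
tiburón,peces_y_mar
ballena,peces_y_mar
delfín,peces_y_mar
pulpo,peces_y_mar
calamar,peces_y_mar
cangrejo,peces_y_mar
gamba,peces_y_mar
medusa,peces_y_mar
foca,peces_y_mar
mosca,insectos
mosquito,insectos
abeja,insectos
avispa,insectos
hormiga,insectos
mariposa,insectos
araña,insectos
escarabajo,insectos
grillo,insectos
saltamontes,insectos
libélula,insectos
gusano,insectos
caracol,insectos
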