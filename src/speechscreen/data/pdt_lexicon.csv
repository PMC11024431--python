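word,lemma,pos
el,el,DET
la,la,DET
los,el,DET
las,la,DET
un,un,DET
una,una,DET
unos,un,DET
unas,una,DET
su,su,DET
sus,su,DET
este,este,DET
esta,esta,DET
niño,niño,NOUN
niña,niña,NOUN
niños,niño,NOUN
madre,madre,NOUN
mujer,mujer,NOUN
señora,señora,NOUN
cocina,cocina,NOUN
galleta,galleta,NOUN
galletas,galleta,NOUN
tarro,tarro,NOUN
bote,bote,NOUN
taburete,taburete,NOUN
banqueta,banqueta,NOUN
silla,silla,NOUN
agua,agua,NOUN
grifo,grifo,NOUN
fregadero,fregadero,NOUN
plato,plato,NOUN
platos,plato,NOUN
taza,taza,NOUN
ventana,ventana,NOUN
cortina,cortina,NOUN
cortinas,cortina,NOUN
jardín,jardín,NOUN
hierba,hierba,NOUN
árbol,árbol,NOUN
armario,armario,NOUN
estante,estante,NOUN
suelo,suelo,NOUN
mano,mano,NOUN
manos,mano,NOUN
pie,pie,NOUN
vestido,vestido,NOUN
delantal,delantal,NOUN
hermano,hermano,NOUN
hermana,hermana,NOUN
roba,robar,VERB
robando,robar,VERB
coge,coger,VERB
cogiendo,coger,VERB
cae,caer,VERB
caerse,caer,VERB
cayendo,caer,VERB
seca,secar,VERB
secando,secar,VERB
lava,lavar,VERB
lavando,lavar,VERB
rebosa,rebosar,VERB
desborda,desbordar,VERB
mira,mirar,VERB
pide,pedir,VERB
da,dar,VERB
sube,subir,VERB
está,estar,VERB
están,estar,VERB
es,ser,VERB
hay,haber,VERB
tiene,tener,VERB
quiere,querer,VERB
juega,jugar,VERB
ríe,reír,VERB
lleva,llevar,VERB
él,él,PRON
ella,ella,PRON
ellos,ellos,PRON
se,se,PRON
le,le,PRON
lo,lo,PRON
que,que,PRON
pequeño,pequeño,ADJ
pequeña,pequeño,ADJ
grande,grande,ADJ
mojado,mojado,ADJ
mojada,mojado,ADJ
abierto,abierto,ADJ
abierta,abierto,ADJ
lleno,lleno,ADJ
llena,lleno,ADJ
sucio,sucio,ADJ
alto,alto,ADJ
alta,alto,ADJ
distraída,distraído,ADJ
distraído,distraído,ADJ
y,y,CONJ
mientras,mientras,CONJ
en,en,PREP
de,de,PREP
con,con,PREP
no,no,ADV
muy,muy,ADV
también,también,ADV
arriba,arriba,ADV
fuera,fuera,ADV
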