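symbol,klass,place,manner,voicing,height,frontness
AA,vowel,none,none,voiced,low,back
AE,vowel,none,none,voiced,low,front
AH,vowel,none,none,voiced,mid,central
AO,vowel,none,none,voiced,low,back
AW,vowel,none,none,voiced,low,back
AY,vowel,none,none,voiced,low,central
EH,vowel,none,none,voiced,mid,front
ER,vowel,none,none,voiced,mid,central
EY,vowel,none,none,voiced,mid,front
IH,vowel,none,none,voiced,high,front
IY,vowel,none,none,voiced,high,front
OW,vowel,none,none,voiced,mid,back
OY,vowel,none,none,voiced,mid,back
UH,vowel,none,none,voiced,high,back
UW,vowel,none,none,voiced,high,back
B,consonant,bilabial,stop,voiced,none,none
CH,consonant,palatal,affricate,voiceless,none,none
D,consonant,alveolar,stop,voiced,none,none
DH,consonant,linguodental,fricative,voiced,none,none
F,consonant,labiodental,fricative,voiceless,none,none
G,consonant,velar,stop,voiced,none,none
HH,consonant,glottal,fricative,voiceless,none,none
JH,consonant,palatal,affricate,voiced,none,none
K,consonant,velar,stop,voiceless,none,none
L,consonant,alveolar,liquid,voiced,none,none
M,consonant,bilabial,nasal,voiced,none,none
N,consonant,alveolar,nasal,voiced,none,none
NG,consonant,velar,nasal,voiced,none,none
P,consonant,bilabial,stop,voiceless,none,none
R,consonant,alveolar,liquid,voiced,none,none
S,consonant,alveolar,fricative,voiceless,none,none
SH,consonant,palatal,fricative,voiceless,none,none
T,consonant,alveolar,stop,voiceless,none,none
TH,consonant,linguodental,fricative,voiceless,none,none
V,consonant,labiodental,fricative,voiced,none,none
W,consonant,bilabial,glide,voiced,none,none
Y,consonant,palatal,glide,voiced,none,none
Z,consonant,alveolar,fricative,voiced,none,none
ZH,consonant,palatal,fricative,voiced,none,none
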