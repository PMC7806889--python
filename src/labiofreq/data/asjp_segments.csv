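symbol,class,subclass
p,consonant,
b,consonant,
f,consonant,labiodental
v,consonant,labiodental
m,consonant,
w,consonant,
8,consonant,
t,consonant,
d,consonant,
s,consonant,
z,consonant,
c,consonant,
n,consonant,
r,consonant,
l,consonant,
S,consonant,
Z,consonant,
C,consonant,
j,consonant,
T,consonant,
5,consonant,
y,consonant,
k,consonant,
g,consonant,
x,consonant,
N,consonant,
q,consonant,
X,consonant,
h,consonant,
7,consonant,
L,consonant,
4,consonant,
G,consonant,
!,consonant,
i,vowel,
e,vowel,
E,vowel,
3,vowel,
a,vowel,
u,vowel,
o,vowel,
~,modifier,binds2
$,modifier,binds3
" ",ignorable,space
%,ignorable,loan_marker
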