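symbol,class,subclass
p,consonant,
b,consonant,
t,consonant,
d,consonant,
ʈ,consonant,
ɖ,consonant,
c,consonant,
ɟ,consonant,
k,consonant,
g,consonant,
ɡ,consonant,
q,consonant,
ɢ,consonant,
ʔ,consonant,
m,consonant,
ɱ,consonant,labiodental
n,consonant,
ɳ,consonant,
ɲ,consonant,
ŋ,consonant,
ɴ,consonant,
ʙ,consonant,
r,consonant,
ʀ,consonant,
ⱱ,consonant,labiodental
ɾ,consonant,
ɽ,consonant,
ɸ,consonant,
β,consonant,
f,consonant,labiodental
v,consonant,labiodental
ʋ,consonant,labiodental
θ,consonant,
ð,consonant,
s,consonant,
z,consonant,
ʃ,consonant,
ʒ,consonant,
ʂ,consonant,
ʐ,consonant,
ç,consonant,
ʝ,consonant,
x,consonant,
ɣ,consonant,
χ,consonant,
ʁ,consonant,
ħ,consonant,
ʕ,consonant,
h,consonant,
ɦ,consonant,
ɬ,consonant,
ɮ,consonant,
l,consonant,
ɭ,consonant,
ʎ,consonant,
ʟ,consonant,
j,consonant,
ɥ,consonant,
w,consonant,
ɰ,consonant,
ʍ,consonant,
ɕ,consonant,
ʑ,consonant,
ɺ,consonant,
ɫ,consonant,
ʦ,consonant,
ʣ,consonant,
ʧ,consonant,
ʤ,consonant,
i,vowel,
y,vowel,
ɨ,vowel,
ʉ,vowel,
ɯ,vowel,
u,vowel,
ɪ,vowel,
ʏ,vowel,
ʊ,vowel,
e,vowel,
ø,vowel,
ɘ,vowel,
ɵ,vowel,
ɤ,vowel,
o,vowel,
ə,vowel,
ɛ,vowel,
œ,vowel,
ɜ,vowel,
ɞ,vowel,
ʌ,vowel,
ɔ,vowel,
æ,vowel,
ɐ,vowel,
a,vowel,
ɶ,vowel,
ɑ,vowel,
ɒ,vowel,
ʰ,modifier,diacritic
ʷ,modifier,diacritic
ʲ,modifier,diacritic
ˠ,modifier,diacritic
ˤ,modifier,diacritic
ʼ,modifier,diacritic
ⁿ,modifier,diacritic
ˡ,modifier,diacritic
ː,modifier,length
ˑ,modifier,length
̃,modifier,diacritic
̥,modifier,diacritic
̬,modifier,diacritic
̪,modifier,diacritic
̺,modifier,diacritic
̻,modifier,diacritic
̤,modifier,diacritic
̰,modifier,diacritic
̩,modifier,diacritic
̯,modifier,diacritic
̝,modifier,diacritic
̞,modifier,diacritic
̟,modifier,diacritic
̠,modifier,diacritic
͡,modifier,tie
͜,modifier,tie
" ",ignorable,space
ˈ,ignorable,stress
ˌ,ignorable,stress
.,ignorable,syllable_break
|,ignorable,prosodic_break
‖,ignorable,prosodic_break
‿,ignorable,linking
̧,modifier,diacritic
̈,modifier,diacritic
̆,modifier,diacritic
́,modifier,diacritic
̀,modifier,diacritic
̂,modifier,diacritic
̌,modifier,diacritic
̄,modifier,diacritic
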