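surface,category,voicing,nasal,voicing_pair,nasal_pair,rule_id
a,vowel,not-applicable,0,,,
e,vowel,not-applicable,0,,,
i,vowel,not-applicable,0,,,
o,vowel,not-applicable,0,,,
u,vowel,not-applicable,0,,,
à,vowel,not-applicable,0,,,
è,vowel,not-applicable,0,,,
é,vowel,not-applicable,0,,,
ì,vowel,not-applicable,0,,,
ò,vowel,not-applicable,0,,,
ù,vowel,not-applicable,0,,,
b,consonant,voiced,0,p,m,
c,consonant,voiceless,0,g,,
d,consonant,voiced,0,t,n,
f,consonant,voiceless,0,v,,
g,consonant,voiced,0,c,,
h,consonant,not-applicable,0,,,
k,consonant,voiceless,0,g,,
l,consonant,not-applicable,0,,,
m,consonant,not-applicable,1,,b,
n,consonant,not-applicable,1,,d,
p,consonant,voiceless,0,b,,
q,consonant,voiceless,0,,,
r,consonant,not-applicable,0,,,
s,consonant,voiceless,0,z,,
t,consonant,voiceless,0,d,,
v,consonant,voiced,0,f,,
z,consonant,voiced,0,s,,
ch,consonant,voiceless,0,gh,,digraph_ch
gh,consonant,voiced,0,ch,,digraph_gh
gn,consonant,not-applicable,1,,,digraph_gn
gl,consonant,not-applicable,0,,,rule_gl_i
sc,consonant,voiceless,0,,,rule_sc_ei
ci,consonant,voiceless,0,gi,,rule_ci_v
gi,consonant,voiced,0,ci,,rule_gi_v
qu,consonant,voiceless,0,,,digraph_qu
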