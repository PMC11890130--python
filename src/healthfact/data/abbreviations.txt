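# Tokens ending in "." that do not terminate a sentence.
e.g.
i.e.
etc.
cf.
vs.
v.
dr.
mr.
mrs.
ms.
prof.
st.
jr.
sr.
fig.
figs.
eq.
ref.
refs.
al.
et al.
no.
vol.
pp.
approx.
ca.
resp.
inc.
ltd.
co.
dept.
univ.
jan.
feb.
mar.
apr.
jun.
jul.
aug.
sep.
sept.
oct.
nov.
dec.
mon.
tue.
wed.
thu.
fri.
sat.
sun.
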