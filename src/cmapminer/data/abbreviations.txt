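# Tokens (ending in a period) that never terminate a sentence.
# One entry per line; '#' starts a comment. Users may extend this file
# or pass extra entries to segment_sentences().
e.g.
i.e.
etc.
cf.
ca.
vs.
al.
no.
approx.
fig.
figs.
ref.
refs.
dr.
prof.
st.
mr.
mrs.
ms.
inc.
ltd.
resp.
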