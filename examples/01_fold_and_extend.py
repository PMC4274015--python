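"""Fold the ancestral hairpin, score its stability, and extend it.

Finds the self-priming stem of the shipped 107-nt ancestor, prints its
temperature-dependent stability and fold probability, and shows the
self-primed extension product with its restriction-mediated return to the
original length.
"""

from olisim import (
    BSAI,
    ancestor_sequence,
    celsius_to_kelvin,
    digest_trim,
    extend_by_self_priming,
    find_self_priming_stem,
    p_self_prime,
    stem_free_energy,
)

anc = ancestor_sequence()
stem = find_self_priming_stem(anc)
print(f"ancestor: {len(anc)} nt")
print(f"stem: {stem.length} bp, 3' span {stem.three_prime_span}, partner {stem.partner_span}")

print("\n T (degC)   dG (kcal/mol)   P(fold)")
for t_c in (45, 55, 60, 65, 70):
    dg = stem_free_energy(stem, celsius_to_kelvin(t_c))
    p = p_self_prime(anc, celsius_to_kelvin(t_c))
    print(f"   {t_c:5.1f}       {dg:+7.3f}       {p:6.3f}")

ext = extend_by_self_priming(anc)
print(f"\nextension product: {len(ext)} nt, new 3' end ...{ext[-8:]}")
back = digest_trim(ext, enzymes=[BSAI])
print(f"BsaI digestion restores the ancestor: {back == anc} ({len(back)} nt)")
# The stem is stable below ~60 degC (dG < 0, P(fold) > 1/2) and melts above,
# which is what the rising-temperature selection regimes act on.
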