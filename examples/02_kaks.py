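"""Nei-Gojobori Ka/Ks on a coding pair with known divergence.

Evolves a 200-codon pair carrying exactly 12 synonymous and 4
nonsynonymous substitutions, then recovers those counts and the corrected
rates with the NG86 estimator.
"""

from asterfam import evolve_codon_pair, ng86

cds_a, cds_b = evolve_codon_pair(200, syn_subs=12, nonsyn_subs=4, seed=1)
pair = ng86((cds_a, cds_b), "geneA", "geneB")

print(f"synonymous sites      S  = {pair.S:.2f}")
print(f"nonsynonymous sites   N  = {pair.N:.2f}")
print(f"synonymous diffs      Sd = {pair.Sd:.1f}  (planted 12)")
print(f"nonsynonymous diffs   Nd = {pair.Nd:.1f}  (planted 4)")
print(f"Ks = {pair.Ks:.4f}  Ka = {pair.Ka:.4f}  Ka/Ks = {pair.omega:.4f}")
# Ka/Ks < 1 indicates purifying selection: nonsynonymous changes are
# rarer per available site than synonymous ones.
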