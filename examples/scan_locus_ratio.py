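"""How many more loci can a near-PAM-less dimer target than a dual-NGG one?

Builds a seeded 1-Mb i.i.d. random genome, counts paired (PAM-out, dimer
spacer 13-18 bp) protospacer sites under an NNN x NNN rule and an NGG x NGG
rule, and prints their ratio. On uniform sequence the expected ratio is the
squared PAM-density ratio, (16/1)^2 = 256; on a real genome the analogous
comparison measures how much a near-PAM-less variant widens the editable
target space relative to a dual-NGG requirement.
"""

from dimerscan import ScanRule, count_paired_sites, count_single_sites, random_genome

genome = random_genome(1_000_000, gc_fraction=0.5, seed=0)

rule_pamless = ScanRule("NNN", "NNN", guide_len=20, spacer_range=(13, 18))
rule_ngg = ScanRule("NGG", "NGG", guide_len=20, spacer_range=(13, 18))

n_pamless = count_paired_sites(genome, rule_pamless)
n_ngg = count_paired_sites(genome, rule_ngg)
n_single = count_single_sites(genome, "NGG", guide_len=20)

print(f"paired loci, NNN x NNN : {n_pamless}")
print(f"paired loci, NGG x NGG : {n_ngg}")
print(f"single NGG half-sites  : {n_single}")
print(f"paired ratio NNN/NGG   : {n_pamless / n_ngg:.1f}  (analytic expectation 256)")
print(f"single/paired NGG ratio: {n_single / n_ngg:.1f}")
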