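"""Per-individual heterozygosity, runs of homozygosity and F_ROH on a panel
with one planted identity-by-descent tract.

A 150-kb stretch of one genome is forced homozygous; the PLINK-style
window caller (20-SNP windows, 100-kb minimum) should report exactly that
tract, and F_ROH is its length over the SNP-covered genome.
"""

from evopot import (
    SynthSpec,
    call_roh,
    froh,
    individual_heterozygosity,
    inject_roh,
    simulate_structured_genotypes,
)

spec = SynthSpec(n_lineages=1, samples_per_lineage=(6,), target_fst=0.0,
                 n_sites=2_000, seed=7, outgroup=False)
table, lineages, _ = simulate_structured_genotypes(spec)

he = individual_heterozygosity(table, "L0_0", callable_sites=table.n_sites)
print(f"heterozygosity of L0_0 over the SNP panel: {he:.3f}")

lo = int(table.sites["pos"].iloc[600])
table, truth = inject_roh(table, "L0_0", ("1", lo, lo + 150_000), seed=2)
segments = call_roh(table, "L0_0")
l_auto = float(table.sites["pos"].iloc[-1] - table.sites["pos"].iloc[0] + 1)
print(f"planted tract 1:{lo}-{lo + 150_000}")
for s in segments:
    print(f"called ROH {s.chrom}:{s.start}-{s.end} ({s.n_snps} SNPs)")
print(f"F_ROH = {froh(segments, l_auto):.5f}")
# One called segment covering the planted interval; F_ROH is the genomic
# inbreeding coefficient: the fraction of the genome inside ROH.
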