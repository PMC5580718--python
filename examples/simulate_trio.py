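"""Simulate a trio of diploid bubbled assemblies with full ground truth.

Builds a 100-kb founder panel with balancing-selection structure, draws a
father-mother-child trio, emulates diploid assembly output (heterozygous
sites kept as bubbles, scaffolds fragmented and strand-flipped) and
writes everything to ./example_sim/.
"""

from pathlib import Path

from triophaser import default_classical_loci, emulate_assembly, generate_founders, sample_trio
from triophaser.simdata import write_simulation

length = 100_000
loci = default_classical_loci(length)
panel = generate_founders(
    ancestral_length=length,
    n_haplotypes=20,
    snv_rate=1 / 150,
    indel_rate=1 / 1500,
    balanced_loci=loci,
    seed=11,
)
truth = sample_trio(panel, seed=12)
emu = emulate_assembly(truth, fragments_per_ind=(1, 4), seed=13)

out = Path("example_sim")
write_simulation(emu, out)

n_snv = sum(v.vclass == "snv" for v in panel.variants)
n_indel = len(panel.variants) - n_snv
print(f"panel: {panel.n_haplotypes} founders, {n_snv} SNVs + {n_indel} indels over {length/1000:.0f} kb")
print(f"father carries {truth.father_haps}, transmitted {truth.father_transmitted}")
for member, ind in emu.individuals.items():
    n_bub = sum(sc.n_bubbles for sc in ind.scaffolds)
    print(f"{member}: {len(ind.scaffolds)} scaffolds, {n_bub} bubbles (het sites retained by the assembler)")
print(f"wrote scaffolds, alignments, registry VCF and truth maps to {out}/")
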