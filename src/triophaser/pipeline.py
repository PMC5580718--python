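"""End-to-end helpers: simulate a trio, prep scaffolds, phase, evaluate.

These functions wire the modules together under the study's default
conditions (a 500-kb polymorphic region, SNV rate 1/150 bp, indel rate
1/1500 bp, scaffold fragmentation into 1-8 pieces, 5% bubble loss) and
are what the command-line interface, the examples and the acceptance
measurements call.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_core import BubbledScaffold, Interval
from .scaffoldprep import prep_individual, read_alignments
from .simdata import (
    AssemblyEmulation,
    DEFAULT_MAF_GRADIENT,
    FounderPanel,
    TrioTruth,
    emulate_assembly,
    generate_founders,
    sample_trio,
)
from .triophase import MEMBERS, PhaseOutcome, run_phasing

#: study-condition defaults for the simulated trios
DEFAULTS = dict(
    length=500_000,
    n_founders=50,
    snv_rate=1 / 150,
    indel_rate=1 / 1500,
    bubble_loss=0.05,
    fragments=(1, 8),
    flip_prob=0.5,
    gap_rate=2e-5,
    recomb_per_meiosis=0.0,
    maf_gradient=DEFAULT_MAF_GRADIENT,
)


def default_classical_loci(length: int) -> list[Interval]:
    """Five balanced 'classical' loci spread across the region.

    Emulates the multi-locus layout of the MHC at reduced scale: each
    locus carries an independent allelic-lineage partition, so trio-level
    phasability averages over loci rather than hinging on one partition.
    """
    size = max(1_000, min(8_000, length // 12))
    rel = (0.10, 0.28, 0.46, 0.64, 0.82)
    return [Interval(int(r * length), int(r * length) + size, "classical") for r in rel]


def default_control_loci(length: int) -> list[Interval]:
    """Length-matched control loci midway between the balanced ones."""
    size = max(1_000, min(8_000, length // 12))
    rel = (0.19, 0.37, 0.55, 0.73, 0.91)
    return [Interval(int(r * length), int(r * length) + size, "control") for r in rel]


@dataclass
class TrioSimulation:
    panel: FounderPanel
    truth: TrioTruth
    emulation: AssemblyEmulation
    prepped: dict[str, BubbledScaffold]


def simulate_trio(
    seed: int,
    length: int = DEFAULTS["length"],
    n_founders: int = DEFAULTS["n_founders"],
    snv_rate: float = DEFAULTS["snv_rate"],
    indel_rate: float = DEFAULTS["indel_rate"],
    bubble_loss: float = DEFAULTS["bubble_loss"],
    fragments: tuple[int, int] = DEFAULTS["fragments"],
    flip_prob: float = DEFAULTS["flip_prob"],
    gap_rate: float = DEFAULTS["gap_rate"],
    recomb_per_meiosis: float = DEFAULTS["recomb_per_meiosis"],
    maf_gradient: float = DEFAULTS["maf_gradient"],
    classical_loci: list[Interval] | None = None,
    min_aligned: int | None = None,
) -> TrioSimulation:
    """Simulate one trio and rebuild each member's region scaffold.

    ``min_aligned`` defaults to the 50-kb selection threshold, lowered
    automatically for regions too short to fragment into 50-kb pieces.
    """
    loci = classical_loci if classical_loci is not None else default_classical_loci(length)
    panel = generate_founders(
        ancestral_length=length,
        n_haplotypes=n_founders,
        snv_rate=snv_rate,
        indel_rate=indel_rate,
        balanced_loci=loci,
        maf_gradient=maf_gradient,
        seed=seed,
    )
    truth = sample_trio(panel, recomb_per_meiosis=recomb_per_meiosis, seed=seed + 101)
    emu = emulate_assembly(
        truth,
        fragments_per_ind=fragments,
        flip_prob=flip_prob,
        bubble_loss=bubble_loss,
        gap_rate=gap_rate,
        seed=seed + 202,
    )
    if min_aligned is None:
        min_aligned = min(50_000, max(1, length // (fragments[1] + 2)))
    prepped = {}
    for member in MEMBERS:
        ind = emu.individuals[member]
        scaffold_map = {sc.id: sc for sc in ind.scaffolds}
        region, _ = prep_individual(
            read_alignments(ind.alignments),
            scaffold_map,
            min_aligned=min_aligned,
            region_id=f"{member}_region",
        )
        prepped[member] = region
    return TrioSimulation(panel=panel, truth=truth, emulation=emu, prepped=prepped)


def phase_simulated_trio(
    sim: TrioSimulation, rounds: int = 2, ufs_len: int = 40
) -> PhaseOutcome:
    """Run the anchoring/genotyping/phasing cycle on a simulated trio."""
    return run_phasing(sim.prepped, ufs_len=ufs_len, rounds=rounds)


def child_truth_sequences(sim: TrioSimulation) -> tuple[str, str]:
    """The child's two true haplotype sequences (paternal, maternal).

    Without recombination these are the transmitted founder sequences;
    with recombination the mosaic is stitched from the origin map.
    """
    truth = sim.truth
    panel = sim.panel
    out = []
    for segs in (truth.child_paternal_origin, truth.child_maternal_origin):
        if len(segs) == 1:
            out.append(panel.haplotype_sequence(segs[0][2]))
            continue
        # mosaic: copy founder sequence per ancestral segment.  Founder
        # coordinates differ from ancestral ones only through indels; we
        # stitch on the ancestral frame by re-applying each segment's
        # founder variants.
        parts = []
        for start, end, name in segs:
            idx = panel.names.index(name)
            cursor = start
            for v in panel.variants:
                if v.pos < start or v.pos + len(v.ref) > end:
                    continue
                if idx not in v.carriers:
                    continue
                parts.append(panel.ancestral[cursor : v.pos])
                parts.append(v.alt)
                cursor = v.pos + len(v.ref)
            parts.append(panel.ancestral[cursor:end])
        out.append("".join(parts))
    return out[0], out[1]
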