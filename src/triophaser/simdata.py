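"""Synthetic trios of diploid bubbled assemblies with full ground truth.

This module emulates the data a diploid short-read assembler produces over
a large polymorphic region (an MHC-like locus): a panel of founder
haplotypes derived from one ancestral sequence, a parent-offspring trio
drawn from that panel, and per-individual *bubbled scaffolds* — backbone
sequence with heterozygous sites retained as biallelic bubbles, fragmented
into 1-8 pieces with random strand flips and short N-gaps.

Design of the variant frequencies: the minor-allele-frequency distribution
is neutral-like (rare variants dominate) far from designated "classical"
loci and shifts toward intermediate frequencies near them, emulating the
footprint of balancing selection.  The shift decays exponentially with
distance at rate ``maf_gradient`` (per bp); ``maf_gradient=0`` disables
the spatial structure entirely.

Everything is seeded and fully deterministic, and all ground truth (who
transmitted what, where every variant sits in every backbone) is recorded
alongside the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    Bubble,
    BubbledScaffold,
    Interval,
    reverse_complement,
    write_bubbled_fasta,
    write_fasta,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: default exponential decay of the balancing footprint, per bp (~20-kb scale)
DEFAULT_MAF_GRADIENT = 5e-5

#: deep allelic lineages per balanced locus
N_LINEAGES = 8

#: tagging probability of the balancing footprint at zero distance
STRUCT_MAX = 0.5

MAX_INDEL = 50


@dataclass(frozen=True)
class Variant:
    """A registered variant on the ancestral coordinate frame.

    Indels are left-anchored with one base of ancestral context, VCF-style:
    a deletion has ``len(ref) > len(alt) == 1`` and vice versa for an
    insertion.  ``carriers`` indexes the founder haplotypes carrying the
    alternate allele; ``freq`` is the exact empirical alternate frequency
    across the panel.
    """

    pos: int
    ref: str
    alt: str
    freq: float
    vclass: str  # "snv" | "ins" | "del"
    site_class: str  # "synonymous" | "nonsynonymous" | "noncoding"
    carriers: frozenset[int]

    @property
    def is_indel(self) -> bool:
        return self.vclass != "snv"


@dataclass
class FounderPanel:
    """Named founder haplotypes derived from one ancestral sequence."""

    ancestral: str
    names: list[str]
    variants: list[Variant]
    locus_annotations: list[Interval]
    _seq_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_haplotypes(self) -> int:
        return len(self.names)

    def haplotype_sequence(self, name: str) -> str:
        """Founder sequence: ancestral with this founder's alternate alleles."""
        if name in self._seq_cache:
            return self._seq_cache[name]
        idx = self.names.index(name)
        parts: list[str] = []
        cursor = 0
        for v in self.variants:
            if idx not in v.carriers:
                continue
            parts.append(self.ancestral[cursor : v.pos])
            parts.append(v.alt)
            cursor = v.pos + len(v.ref)
        parts.append(self.ancestral[cursor:])
        seq = "".join(parts)
        self._seq_cache[name] = seq
        return seq

    def allele(self, variant: Variant, founder: str) -> str:
        return variant.alt if self.names.index(founder) in variant.carriers else variant.ref


@dataclass
class TrioTruth:
    """Ground truth for one simulated trio."""

    panel: FounderPanel
    father_haps: tuple[str, str]
    mother_haps: tuple[str, str]
    father_transmitted: str
    mother_transmitted: str
    # per child chromosome: list of (start, end, founder_name) on the
    # ancestral frame, half-open, covering the whole region
    child_paternal_origin: list[tuple[int, int, str]]
    child_maternal_origin: list[tuple[int, int, str]]
    breakpoints: list[int]

    def origin_at(self, chromosome: str, pos: int) -> str:
        segs = (
            self.child_paternal_origin
            if chromosome == "paternal"
            else self.child_maternal_origin
        )
        for start, end, name in segs:
            if start <= pos < end:
                return name
        raise ValueError(f"position {pos} outside origin map")

    def child_allele(self, variant: Variant, chromosome: str) -> str:
        return self.panel.allele(variant, self.origin_at(chromosome, variant.pos))

    def member_haplotypes(self, member: str) -> tuple[str, str]:
        """The two founder names (or chromosome tags) behind a trio member."""
        if member == "father":
            return self.father_haps
        if member == "mother":
            return self.mother_haps
        if member == "child":
            return ("paternal", "maternal")
        raise KeyError(member)

    def member_allele_pair(self, variant: Variant, member: str) -> tuple[str, str]:
        """Ordered true allele pair (haplotype 1, haplotype 2) at a variant."""
        if member == "child":
            return (
                self.child_allele(variant, "paternal"),
                self.child_allele(variant, "maternal"),
            )
        h1, h2 = self.member_haplotypes(member)
        return (self.panel.allele(variant, h1), self.panel.allele(variant, h2))


@dataclass
class SiteRecord:
    """Where one registered variant landed in one individual's assembly."""

    variant_index: int
    backbone_pos: int  # position in the un-fragmented diploid backbone
    alleles: tuple[str, str]  # true (hap1, hap2) alleles
    has_bubble: bool  # False if homozygous or bubble lost
    emitted: tuple[str, str] | str  # (left, right) if bubble else the flat allele


@dataclass
class IndividualAssembly:
    member: str
    scaffolds: list[BubbledScaffold]  # emission order
    full_scaffold: BubbledScaffold  # pre-fragmentation diploid scaffold
    site_records: dict[int, SiteRecord]  # variant index -> record
    fragment_plan: list[tuple[str, int, int, str]]  # (id, start, end, strand)
    alignments: pd.DataFrame  # scaffold, ref_start, ref_end, scaf_start, scaf_end, strand
    backbone_to_ancestral: list[tuple[int, int, int]]  # (bb_start, anc_start, length)
    gap_runs: list[tuple[int, int]]


@dataclass
class AssemblyEmulation:
    truth: TrioTruth
    individuals: dict[str, IndividualAssembly]


# ---------------------------------------------------------------------------
# Founder generation


def _distance_to_loci(pos: np.ndarray, loci: Sequence[Interval]) -> np.ndarray:
    """bp distance from each position to the nearest interval edge (0 inside)."""
    if not loci:
        return np.full(len(pos), np.inf)
    d = np.full(len(pos), np.inf)
    for iv in loci:
        inside = (pos >= iv.start) & (pos < iv.end)
        left = np.clip(iv.start - pos, 0, None)
        right = np.clip(pos - (iv.end - 1), 0, None)
        dist = np.where(inside, 0, np.maximum(left, right))
        d = np.minimum(d, dist)
    return d


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_founders(
    ancestral_length: int,
    n_haplotypes: int,
    snv_rate: float,
    indel_rate: float,
    balanced_loci: Sequence[Interval] = (),
    maf_gradient: float = DEFAULT_MAF_GRADIENT,
    seed: int = 0,
    coding_fraction_outside: float = 0.15,
    max_indel: int = MAX_INDEL,
) -> FounderPanel:
    """Generate a founder haplotype panel from a random ancestral sequence.

    Parameters
    ----------
    ancestral_length:
        Region length in bp (>= 10 kb).
    n_haplotypes:
        Panel size (>= 4; a trio consumes four distinct founders).
    snv_rate, indel_rate:
        Per-bp polymorphism rates, each in [0, 0.05]; combined expected
        divergence above 10% is rejected.
    balanced_loci:
        Non-overlapping intervals around which minor allele frequencies are
        elevated (the balancing-selection emulation).
    maf_gradient:
        Exponential decay rate (per bp) of the frequency elevation with
        distance to the nearest balanced locus; 0 removes the gradient.
    """
    if ancestral_length < 10_000:
        raise ValueError("ancestral_length must be >= 10 kb")
    if n_haplotypes < 4:
        raise ValueError("need at least 4 founder haplotypes")
    for rate in (snv_rate, indel_rate):
        if not 0 <= rate <= 0.05:
            raise ValueError("rates must lie in [0, 0.05]")
    mean_indel = (1 + max_indel) / 2
    if snv_rate + indel_rate * mean_indel > 0.10:
        raise ValueError("requested rates imply >10% sequence divergence")
    loci = sorted(balanced_loci, key=lambda iv: iv.start)
    for a, b in zip(loci, loci[1:]):
        if b.start < a.end:
            raise ValueError("balanced loci must not overlap")

    rng = np.random.default_rng(seed)
    ancestral = _random_dna(rng, ancestral_length)

    # Candidate positions: independent per-bp Bernoulli draws (Poisson-like
    # counts), merged, then thinned so no two variant ref spans overlap.
    u = rng.random(ancestral_length)
    snv_pos = np.flatnonzero(u < snv_rate)
    u2 = rng.random(ancestral_length)
    indel_pos = np.flatnonzero(u2 < indel_rate)
    indel_pos = indel_pos[(indel_pos > 0) & (indel_pos < ancestral_length - max_indel - 1)]
    cand = sorted(
        [(int(p), "snv") for p in snv_pos] + [(int(p), "indel") for p in indel_pos]
    )

    positions = np.array([p for p, _ in cand], dtype=float)
    if maf_gradient > 0 and loci:
        dists = np.stack(
            [_distance_to_loci(positions, [iv]) for iv in loci], axis=0
        )
        nearest = np.argmin(dists, axis=0)
        dist = dists[nearest, np.arange(len(cand))]
        # probability that a variant tags the allelic-lineage partition of
        # its nearest balanced locus (the intermediate-frequency, long-
        # haplotype-block footprint of balancing selection)
        q_struct = STRUCT_MAX * np.exp(-maf_gradient * dist)
    else:
        # no gradient (or no loci): neutral background only
        nearest = np.zeros(len(cand), dtype=int)
        q_struct = np.zeros(len(cand))

    # background variants follow the folded neutral spectrum of the panel:
    # P(minor count = j) proportional to 1/j + 1/(n-j)
    j = np.arange(1, n_haplotypes // 2 + 1)
    sfs_w = 1.0 / j + 1.0 / (n_haplotypes - j)
    sfs_w[-1] *= 0.5 if n_haplotypes % 2 == 0 else 1.0
    sfs_w /= sfs_w.sum()

    # balanced allelic lineages per locus: founders fall into deep classes
    # (independent partition per locus), and structured variants tag
    # subsets of those classes
    locus_classes = [
        rng.integers(0, N_LINEAGES, size=n_haplotypes) for _ in loci
    ]

    variants: list[Variant] = []
    blocked_until = -1
    for i, (pos, kind) in enumerate(cand):
        if pos <= blocked_until:
            continue
        carriers: frozenset[int] | None = None
        if q_struct[i] > 0 and rng.random() < q_struct[i]:
            # carriers tag a subset of the allelic lineages of the nearest
            # balanced locus, yielding intermediate frequencies and mutual LD
            cls = locus_classes[nearest[i]]
            n_tag = int(rng.integers(1, N_LINEAGES))
            tagged = rng.choice(N_LINEAGES, size=n_tag, replace=False)
            mask = np.isin(cls, tagged) ^ (rng.random(n_haplotypes) < 0.05)
            if 0 < mask.sum() < n_haplotypes:
                carriers = frozenset(int(c) for c in np.flatnonzero(mask))
        if carriers is None:
            # neutral background: folded-SFS minor count, random allele side
            minor = int(rng.choice(j, p=sfs_w))
            count = minor if rng.random() < 0.5 else n_haplotypes - minor
            count = min(max(count, 1), n_haplotypes - 1)
            carriers = frozenset(
                int(c) for c in rng.choice(n_haplotypes, count, replace=False)
            )

        if kind == "snv":
            ref = ancestral[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            vclass = "snv"
            span = 1
        else:
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:  # deletion
                ref = ancestral[pos : pos + 1 + size]
                alt = ancestral[pos]
                vclass = "del"
            else:  # insertion
                ref = ancestral[pos]
                alt = ancestral[pos] + _random_dna(rng, size)
                vclass = "ins"
            span = len(ref)
        if "N" in ref:
            continue

        in_locus = any(iv.start <= pos < iv.end for iv in loci)
        r = rng.random()
        if in_locus:
            site_class = "nonsynonymous" if r < 0.55 else "synonymous"
        elif r < coding_fraction_outside:
            site_class = (
                "nonsynonymous" if rng.random() < 0.55 else "synonymous"
            )
        else:
            site_class = "noncoding"

        variants.append(
            Variant(
                pos=pos,
                ref=ref,
                alt=str(alt),
                freq=len(carriers) / n_haplotypes,
                vclass=vclass,
                site_class=site_class,
                carriers=carriers,
            )
        )
        blocked_until = pos + span  # keep ref spans disjoint (plus anchor base)

    names = [f"h{i}" for i in range(n_haplotypes)]
    return FounderPanel(
        ancestral=ancestral,
        names=names,
        variants=variants,
        locus_annotations=list(loci),
    )


# ---------------------------------------------------------------------------
# Trio sampling


def sample_trio(
    panel: FounderPanel, recomb_per_meiosis: float = 0.0, seed: int = 0
) -> TrioTruth:
    """Draw a trio: four distinct founders split between the parents.

    Each parent transmits one (possibly recombinant) chromosome; the number
    of crossovers per meiosis is Poisson(``recomb_per_meiosis``) — 0 by
    default, since a few-Mb region rarely recombines within one meiosis.
    """
    if panel.n_haplotypes < 4:
        raise ValueError("panel must hold at least 4 founder haplotypes")
    rng = np.random.default_rng(seed)
    picks = rng.choice(panel.n_haplotypes, 4, replace=False)
    father = (panel.names[picks[0]], panel.names[picks[1]])
    mother = (panel.names[picks[2]], panel.names[picks[3]])
    length = len(panel.ancestral)

    def meiosis(haps: tuple[str, str]) -> tuple[str, list[tuple[int, int, str]], list[int]]:
        start_idx = int(rng.integers(2))
        n_x = int(rng.poisson(recomb_per_meiosis))
        bps = sorted(int(p) for p in rng.integers(1, length, size=n_x))
        bps = sorted(set(bps))
        segments = []
        cur = 0
        idx = start_idx
        for bp in bps:
            segments.append((cur, bp, haps[idx]))
            cur = bp
            idx = 1 - idx
        segments.append((cur, length, haps[idx]))
        return haps[start_idx], segments, bps

    f_trans, pat_origin, f_bps = meiosis(father)
    m_trans, mat_origin, m_bps = meiosis(mother)
    return TrioTruth(
        panel=panel,
        father_haps=father,
        mother_haps=mother,
        father_transmitted=f_trans,
        mother_transmitted=m_trans,
        child_paternal_origin=pat_origin,
        child_maternal_origin=mat_origin,
        breakpoints=sorted(set(f_bps) | set(m_bps)),
    )


# ---------------------------------------------------------------------------
# Assembler emulation


def _build_diploid(
    truth: TrioTruth,
    member: str,
    bubble_loss: float,
    rng: np.random.Generator,
    phase_ordered: bool = False,
) -> tuple[BubbledScaffold, dict[int, SiteRecord], list[tuple[int, int, int]]]:
    """Collapse an individual's two haplotypes into one bubbled scaffold."""
    panel = truth.panel
    parts: list[str] = []
    bubbles: list[Bubble] = []
    records: dict[int, SiteRecord] = {}
    bb_map: list[tuple[int, int, int]] = []  # (backbone_start, anc_start, len)
    cursor = 0  # ancestral frame
    out_len = 0

    for vi, v in enumerate(panel.variants):
        a1, a2 = truth.member_allele_pair(v, member)
        if a1 == v.ref and a2 == v.ref:
            continue  # the site is monomorphic-reference here; plain sequence
        seg = panel.ancestral[cursor : v.pos]
        parts.append(seg)
        bb_map.append((out_len, cursor, len(seg)))
        out_len += len(seg)
        site_pos = out_len
        if a1 != a2:
            lost = rng.random() < bubble_loss
            if lost:
                emitted = a1 if rng.random() < 0.5 else a2
                parts.append(emitted)
                records[vi] = SiteRecord(vi, site_pos, (a1, a2), False, emitted)
                out_len += len(emitted)
            else:
                # the assembler does not know phase: allele order in the
                # bubble is arbitrary unless phase_ordered is requested
                if phase_ordered or rng.random() < 0.5:
                    left, right = a1, a2
                else:
                    left, right = a2, a1
                parts.append(left)
                bubbles.append(Bubble(pos=site_pos, left=left, right=right))
                records[vi] = SiteRecord(vi, site_pos, (a1, a2), True, (left, right))
                out_len += len(left)
        else:
            parts.append(a1)
            records[vi] = SiteRecord(vi, site_pos, (a1, a2), False, a1)
            out_len += len(a1)
        cursor = v.pos + len(v.ref)

    seg = panel.ancestral[cursor:]
    parts.append(seg)
    bb_map.append((out_len, cursor, len(seg)))
    scaffold = BubbledScaffold(id=f"{member}_diploid", backbone="".join(parts), bubbles=bubbles)
    return scaffold, records, bb_map


def _backbone_to_anc(bb_map: list[tuple[int, int, int]], pos: int) -> int:
    """Approximate ancestral coordinate of a backbone position."""
    lo, hi = 0, len(bb_map) - 1
    best = bb_map[0]
    while lo <= hi:
        mid = (lo + hi) // 2
        if bb_map[mid][0] <= pos:
            best = bb_map[mid]
            lo = mid + 1
        else:
            hi = mid - 1
    bb_start, anc_start, length = best
    return anc_start + min(pos - bb_start, max(length - 1, 0))


def _inject_gaps(
    scaffold: BubbledScaffold, gap_rate: float, rng: np.random.Generator
) -> tuple[BubbledScaffold, list[tuple[int, int]]]:
    if gap_rate <= 0:
        return scaffold, []
    length = len(scaffold.backbone)
    n_gaps = int(rng.poisson(gap_rate * length))
    if n_gaps == 0:
        return scaffold, []
    spans = [(b.pos, b.pos + len(b.left)) for b in scaffold.bubbles]
    backbone = bytearray(scaffold.backbone, "ascii")
    runs: list[tuple[int, int]] = []
    for _ in range(n_gaps):
        run = int(rng.integers(1, 21))
        start = int(rng.integers(0, max(1, length - run)))
        end = start + run
        # leave bubble alleles intact so bubbles stay N-free
        if any(s < end and start < s_end for s, s_end in spans):
            continue
        backbone[start:end] = b"N" * run
        runs.append((start, end))
    return (
        BubbledScaffold(scaffold.id, backbone.decode(), list(scaffold.bubbles)),
        sorted(runs),
    )


def emulate_assembly(
    truth: TrioTruth,
    fragments_per_ind: tuple[int, int] = (1, 8),
    flip_prob: float = 0.5,
    bubble_loss: float = 0.05,
    gap_rate: float = 2e-5,
    seed: int = 0,
    phase_ordered: bool = False,
) -> AssemblyEmulation:
    """Emulate diploid assembly output for all three trio members.

    Heterozygous sites become bubbles with probability ``1 - bubble_loss``
    (a lost bubble collapses to one random allele); each individual's
    scaffold is cut into 1-8 fragments, each reverse-complemented with
    probability ``flip_prob``, and short N-gaps are injected at
    ``gap_rate`` per bp.  Synthetic reference alignments (ancestral frame)
    are emitted for scaffold ordering.
    """
    lo, hi = fragments_per_ind
    if not (1 <= lo <= hi <= 8):
        raise ValueError("fragments_per_ind must lie within 1..8")
    for p in (flip_prob, bubble_loss):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0,1]")
    rng = np.random.default_rng(seed)
    individuals: dict[str, IndividualAssembly] = {}

    for member in ("father", "mother", "child"):
        diploid, records, bb_map = _build_diploid(
            truth, member, bubble_loss, rng, phase_ordered=phase_ordered
        )
        diploid, gap_runs = _inject_gaps(diploid, gap_rate, rng)
        length = len(diploid.backbone)

        n_frag = int(rng.integers(lo, hi + 1))
        bubble_spans = [(b.pos, b.pos + len(b.left)) for b in diploid.bubbles]
        # constructive partition: every fragment clears the downstream 50-kb
        # selection threshold whenever the region is long enough
        min_piece = min(55_000, length // (n_frag + 1))
        min_piece = max(min(1000, length // (n_frag + 1)), min_piece)
        slack = length - n_frag * min_piece
        extra = rng.multinomial(slack, np.full(n_frag, 1 / n_frag))
        pieces = [min_piece + int(x) for x in extra]
        cuts = list(np.cumsum(pieces)[:-1])
        # nudge cuts off bubble allele spans
        for idx, c in enumerate(cuts):
            while any(s < c < e for s, e in bubble_spans):
                c += 1
            cuts[idx] = int(c)
        bounds = [0] + sorted(set(cuts)) + [length]

        plan: list[tuple[str, int, int, str]] = []
        frags: list[BubbledScaffold] = []
        rows = []
        for j in range(len(bounds) - 1):
            s, e = bounds[j], bounds[j + 1]
            strand = "-" if rng.random() < flip_prob else "+"
            fid = f"{member}_scaf{j}"
            piece = diploid.slice(s, e, new_id=fid)
            if strand == "-":
                piece = piece.reverse_complement()
            plan.append((fid, s, e, strand))
            frags.append(piece)
            ref_start = _backbone_to_anc(bb_map, s)
            ref_end = _backbone_to_anc(bb_map, e - 1) + 1
            rows.append(
                dict(
                    scaffold=fid,
                    ref_start=ref_start,
                    ref_end=ref_end,
                    scaf_start=0,
                    scaf_end=e - s,
                    strand=strand,
                )
            )
            # occasionally add a short spurious block (below the half-max
            # filter) to exercise downstream block filtering
            if rng.random() < 0.3 and (e - s) > 4000:
                noise_len = int((e - s) * rng.uniform(0.05, 0.4))
                noise_ref = int(rng.integers(0, max(1, len(truth.panel.ancestral) - noise_len)))
                rows.append(
                    dict(
                        scaffold=fid,
                        ref_start=noise_ref,
                        ref_end=noise_ref + noise_len,
                        scaf_start=0,
                        scaf_end=noise_len,
                        strand=strand,
                    )
                )

        order = rng.permutation(len(frags))
        frags = [frags[i] for i in order]
        individuals[member] = IndividualAssembly(
            member=member,
            scaffolds=frags,
            full_scaffold=diploid,
            site_records=records,
            fragment_plan=plan,
            alignments=pd.DataFrame(rows),
            backbone_to_ancestral=bb_map,
            gap_runs=gap_runs,
        )

    return AssemblyEmulation(truth=truth, individuals=individuals)


# ---------------------------------------------------------------------------
# On-disk emission


def write_truth_tsv(truth: TrioTruth, path: str | Path) -> None:
    """Truth map TSV: individual, chromosome, start, end, founder_id, strand."""
    rows = []
    for member in ("father", "mother"):
        for k, hap in enumerate(truth.member_haplotypes(member)):
            rows.append((member, f"hap{k+1}", 0, len(truth.panel.ancestral), hap, "+"))
    for chrom, segs in (
        ("paternal", truth.child_paternal_origin),
        ("maternal", truth.child_maternal_origin),
    ):
        for start, end, hap in segs:
            rows.append(("child", chrom, start, end, hap, "+"))
    with open(path, "w") as fh:
        fh.write("individual\tchromosome\tstart\tend\tfounder_id\tstrand\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def write_registry_vcf(panel: FounderPanel, path: str | Path, contig: str = "ancestral") -> None:
    """Registry as VCF 4.2 with one haploid sample per founder."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(panel.ancestral)}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##INFO=<ID=SCLASS,Number=1,Type=String,Description="Site class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.names) + "\n")
        for v in panel.variants:
            gts = ["1" if i in v.carriers else "0" for i in range(panel.n_haplotypes)]
            fh.write(
                f"{contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"AF={v.freq:.6f};SCLASS={v.site_class}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_simulation(emu: AssemblyEmulation, out_dir: str | Path) -> None:
    """Write founders, scaffolds, alignments, registry and truth to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = emu.truth.panel
    write_fasta(
        [(n, panel.haplotype_sequence(n)) for n in panel.names], out / "founders.fasta"
    )
    write_registry_vcf(panel, out / "registry.vcf")
    write_truth_tsv(emu.truth, out / "truth.tsv")
    with open(out / "pedigree.tsv", "w") as fh:
        fh.write("father\tmother\tchild\nfather\tmother\tchild\n")
    for member, ind in emu.individuals.items():
        write_bubbled_fasta(ind.scaffolds, out / f"{member}.bfasta")
        ind.alignments.to_csv(out / f"{member}.alignments.tsv", sep="\t", index=False)
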