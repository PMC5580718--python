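"""Trio phasing of assembly bubbles by exact flanking-sequence anchoring.

The method: each bubble (heterozygous site retained by a diploid
assembler) is located in every member of a father-mother-child trio by
*exact* matching of its 40-bp upstream flanking sequence (UFS); reverse
complements (RUFS) are matched too, to flag putative inversions.  Only
uniquely matching positions are kept.  Anchored sites are genotyped in
all three individuals (from the bubble if present, else by direct
sequence lookup), biallelic sites are phased by Mendelian transmission,
and six haplotype sequences are emitted: the transmitted and
nontransmitted haplotype of each parent and the two child chromosomes.
Parent-child consensus sequences are built by global alignment of the
segments between phased sites, and the whole cycle can be iterated —
re-anchoring against gap-filled sequence rescues sites whose flanks
initially crossed scaffold joins or N-gaps.

Because a 40-mer flank may straddle a neighbouring bubble, exact matching
is performed against the backbone with bubbles expanded into both allele
paths within a window around each bubble.
"""

from __future__ import annotations

import bisect
import itertools
import logging
import re
from dataclasses import dataclass, field

import edlib

from .io_core import Bubble, BubbledScaffold, StageCounters, reverse_complement

logger = logging.getLogger(__name__)

MEMBERS = ("father", "mother", "child")
UFS_LEN = 40

_MULTI = object()  # sentinel: k-mer with several distinct anchor coordinates


# ---------------------------------------------------------------------------
# Anchor extraction


@dataclass
class AnchorRecord:
    """The flanks of one bubble and its match status across the trio."""

    member: str
    bubble: Bubble
    ufs: str | None
    rufs: str | None
    dfs: str | None  # downstream flank, used as a secondary disambiguator
    anchorable: bool
    # member -> (position, orientation) for unique hits; None if absent/multi
    matches: dict[str, tuple[int, str] | None] = field(default_factory=dict)


@dataclass
class AnchorTable:
    member: str
    ufs_len: int
    records: list[AnchorRecord]


def extract_anchors(
    scaffold: BubbledScaffold, ufs_len: int = UFS_LEN, member: str = ""
) -> AnchorTable:
    """Extract the UFS/RUFS/downstream flank for every bubble.

    A bubble closer than ``ufs_len`` to the scaffold start, or whose
    upstream window contains an N, is marked unanchorable (a status, not
    an error).
    """
    records = []
    bb = scaffold.backbone
    for b in scaffold.bubbles:
        p = b.pos
        if p < ufs_len:
            records.append(AnchorRecord(member, b, None, None, None, False))
            continue
        window = bb[p - ufs_len : p]
        if "N" in window:
            records.append(AnchorRecord(member, b, None, None, None, False))
            continue
        dfs = bb[p + len(b.left) : p + len(b.left) + ufs_len]
        records.append(
            AnchorRecord(member, b, window, reverse_complement(window), dfs, True)
        )
    return AnchorTable(member=member, ufs_len=ufs_len, records=records)


# ---------------------------------------------------------------------------
# Search index: k-mer -> anchor coordinate


def _expanded_kmers(scaffold: BubbledScaffold, k: int, pad: int, max_cluster: int):
    """Yield (k-mer, anchor coordinate) over the scaffold's allele paths.

    The anchor coordinate of a k-mer is the backbone position immediately
    after its last character — i.e. the site a UFS match places a variant
    at.  Besides the plain backbone, alternative spellings are emitted for
    windows around bubbles (both allele paths, combinations within a
    cluster), so a flank straddling a neighbouring heterozygous site still
    matches exactly.  K-mers containing N or ending inside a bubble allele
    are suppressed.
    """
    bb = scaffold.backbone
    n = len(bb)

    # plain backbone, skipping windows containing N
    seg_start = 0
    for m in re.finditer("N+", bb):
        seg_end = m.start()
        for i in range(seg_start, seg_end - k + 1):
            yield bb[i : i + k], i + k
        seg_start = m.end()
    for i in range(seg_start, n - k + 1):
        yield bb[i : i + k], i + k

    # both-allele-path spellings around bubble clusters
    bubbles = scaffold.bubbles
    i = 0
    while i < len(bubbles):
        cluster = [bubbles[i]]
        j = i + 1
        while (
            j < len(bubbles)
            and len(cluster) < max_cluster
            and bubbles[j].pos - (cluster[-1].pos + len(cluster[-1].left)) < k + pad
        ):
            cluster.append(bubbles[j])
            j += 1
        i = j
        start = max(0, cluster[0].pos - (k + pad))
        end = min(n, cluster[-1].pos + len(cluster[-1].left) + k)
        for combo in itertools.product((0, 1), repeat=len(cluster)):
            if not any(combo):
                continue  # all-left == plain backbone, already emitted
            chars: list[str] = []
            coords: list[int] = []  # anchor coordinate after each char
            cursor = start
            for b, which in zip(cluster, combo):
                for ppos in range(cursor, b.pos):
                    chars.append(bb[ppos])
                    coords.append(ppos + 1)
                allele = b.left if which == 0 else b.right
                after = b.pos + len(b.left)
                for ci, ch in enumerate(allele):
                    chars.append(ch)
                    # only the allele's final char anchors a valid coordinate
                    coords.append(after if ci == len(allele) - 1 else -1)
                cursor = after
            for ppos in range(cursor, end):
                chars.append(bb[ppos])
                coords.append(ppos + 1)
            text = "".join(chars)
            for t in range(len(text) - k + 1):
                coord = coords[t + k - 1]
                if coord < 0:
                    continue
                kmer = text[t : t + k]
                if "N" in kmer:
                    continue
                yield kmer, coord


def build_search_index(
    scaffold: BubbledScaffold, k: int = UFS_LEN, pad: int = 60, max_cluster: int = 8
):
    """Map every k-mer (all allele-path spellings) to its anchor coordinate.

    A k-mer observed with several distinct anchor coordinates maps to a
    non-unique sentinel.
    """
    index: dict[str, object] = {}
    for kmer, coord in _expanded_kmers(scaffold, k, pad, max_cluster):
        cur = index.get(kmer)
        if cur is None:
            index[kmer] = coord
        elif cur is not _MULTI and cur != coord:
            index[kmer] = _MULTI
    return index


def bubble_flank_spellings(
    scaffold: BubbledScaffold, k: int = UFS_LEN, pad: int = 60, max_cluster: int = 8
) -> dict[int, set[str]]:
    """All upstream-flank spellings per bubble position.

    A bubble whose flank straddles a neighbouring bubble has one spelling
    per allele path of the neighbours; every spelling is a valid exact-
    match query for this site in the other trio members.
    """
    targets = {b.pos for b in scaffold.bubbles}
    out: dict[int, set[str]] = {}
    for kmer, coord in _expanded_kmers(scaffold, k, pad, max_cluster):
        if coord in targets:
            out.setdefault(coord, set()).add(kmer)
    return out


# ---------------------------------------------------------------------------
# Matching and site assembly


@dataclass
class Site:
    """One variant site anchored at a unique position in every member."""

    positions: dict[str, int]
    ufs_strings: list[str]
    bubbles: dict[str, Bubble | None] = field(default_factory=dict)
    excluded: str | None = None  # reason, if dropped before genotyping


def _downstream_rescue(
    candidates: list[int], dfs: str | None, scaffold: BubbledScaffold
) -> int | None:
    """Pick among multiple UFS hits using the downstream flank."""
    if not dfs:
        return None
    bb = scaffold.backbone
    survivors = [c for c in candidates if dfs in bb[c : c + len(dfs) + 80]]
    return survivors[0] if len(survivors) == 1 else None


def match_anchors(
    tables: dict[str, AnchorTable],
    trio_scaffolds: dict[str, BubbledScaffold],
    indexes: dict[str, dict] | None = None,
    use_downstream: bool = True,
    counters: StageCounters | None = None,
) -> list[Site]:
    """Match every UFS exactly in all trio members and assemble sites.

    UFS strings are deduplicated across the trio; a string must match at
    exactly one position in every individual to anchor a site (multiple
    hits within an individual are discarded there, optionally rescued by
    the downstream flank).  UFS groups anchoring the identical
    (father, mother, child) position triple are one site; triples that
    collide at a coordinate in one individual while disagreeing elsewhere
    are discarded at that individual, which excludes the site.  RUFS-only
    hits are recorded as putative inversions and not phased.
    """
    counters = counters if counters is not None else StageCounters()
    if indexes is None:
        indexes = {m: build_search_index(s, k=tables[m].ufs_len) for m, s in trio_scaffolds.items()}
    spellings = {
        m: bubble_flank_spellings(trio_scaffolds[m], k=tables[m].ufs_len)
        for m in trio_scaffolds
    }
    bubble_positions = {
        m: {b.pos for b in trio_scaffolds[m].bubbles} for m in trio_scaffolds
    }

    anchored: list[tuple[AnchorRecord, tuple[int, ...]]] = []
    for member, table in tables.items():
        for rec in table.records:
            counters.incr("bubbles_total")
            if not rec.anchorable:
                counters.incr("bubbles_unanchorable")
                continue
            spells = spellings[member].get(rec.bubble.pos) or {rec.ufs}
            hit: dict[str, int] = {}
            ok = True
            for m in MEMBERS:
                coords: set[int] = set()
                multi = False
                for s in spells:
                    res = indexes[m].get(s)
                    if res is None:
                        continue
                    if res is _MULTI:
                        multi = True
                    else:
                        coords.add(res)
                if multi or len(coords) > 1:
                    rescued = None
                    if use_downstream:
                        cands = set(coords)
                        for s in spells:
                            cands.update(_all_hits(trio_scaffolds[m], s))
                        # prefer the coordinate carrying a bubble (resolves
                        # the indel-in-repeat anchor shift)
                        with_bubble = [c for c in cands if c in bubble_positions[m]]
                        if len(with_bubble) == 1:
                            rescued = with_bubble[0]
                        else:
                            rescued = _downstream_rescue(
                                sorted(cands), rec.dfs, trio_scaffolds[m]
                            )
                    if rescued is None:
                        rec.matches[m] = None
                        counters.incr("nonunique_matches")
                        ok = False
                    else:
                        hit[m] = rescued
                        rec.matches[m] = (rescued, "forward")
                elif len(coords) == 1:
                    pos = coords.pop()
                    hit[m] = pos
                    rec.matches[m] = (pos, "forward")
                else:
                    # forward absent; check for an inverted (RUFS) hit
                    inv = indexes[m].get(reverse_complement(rec.ufs))
                    rec.matches[m] = (
                        (inv, "inverted") if isinstance(inv, int) else None
                    )
                    if isinstance(inv, int):
                        counters.incr("inversion_candidates")
                    ok = False
            if ok:
                anchored.append((rec, tuple(hit[m] for m in MEMBERS)))

    # group anchored bubbles by their position triple (the same site seen
    # from different individuals collapses here)
    sites: dict[tuple[int, ...], Site] = {}
    for rec, key in anchored:
        site = sites.get(key)
        if site is None:
            sites[key] = Site(
                positions={m: key[i] for i, m in enumerate(MEMBERS)},
                ufs_strings=[rec.ufs],
            )
        else:
            site.ufs_strings.append(rec.ufs)

    # cross-site coordinate collisions: distinct triples sharing a
    # coordinate in one member are discarded there (missing data)
    for mi, m in enumerate(MEMBERS):
        seen: dict[int, int] = {}
        for key in sites:
            seen[key[mi]] = seen.get(key[mi], 0) + 1
        for key, site in sites.items():
            if seen[key[mi]] > 1 and site.excluded is None:
                site.excluded = f"position collision in {m}"
                counters.incr("position_collisions")

    # attach the source bubbles
    out = []
    bubble_at = {
        m: {b.pos: b for b in trio_scaffolds[m].bubbles} for m in MEMBERS
    }
    for key in sorted(sites, key=lambda t: t[2]):  # order by child coordinate
        site = sites[key]
        site.bubbles = {m: bubble_at[m].get(site.positions[m]) for m in MEMBERS}
        if all(b is None for b in site.bubbles.values()):
            continue  # anchor coincidence without any bubble; not a variant
        counters.incr("sites_anchored")
        out.append(site)
    return out


def _all_hits(scaffold: BubbledScaffold, ufs: str) -> list[int]:
    """All backbone match coordinates of a UFS (plain-backbone scan)."""
    hits = []
    start = scaffold.backbone.find(ufs)
    while start != -1:
        hits.append(start + len(ufs))
        start = scaffold.backbone.find(ufs, start + 1)
    return hits


# ---------------------------------------------------------------------------
# Genotyping


@dataclass
class TrioPhaseCall:
    """Genotypes, Mendelian status and transmission phase at one site."""

    pos: int  # child backbone coordinate (VCF frame)
    positions: dict[str, int]
    ref: str
    alt: str
    genotypes: dict[str, tuple[str, str] | None]
    mendel: str = "NA"  # OK | VIOL | NA
    status: str = "excluded"  # phased | unphased | excluded
    phased_samples: dict[str, bool] = field(default_factory=dict)
    child_paternal: str | None = None
    child_maternal: str | None = None
    father_transmitted: str | None = None
    mother_transmitted: str | None = None
    exclusion_reason: str | None = None
    phased_round: int | None = None  # first phasing round that resolved it

    @property
    def is_biallelic(self) -> bool:
        return self.ref is not None and self.alt is not None


def genotype_site(
    trio_scaffolds: dict[str, BubbledScaffold], site: Site
) -> TrioPhaseCall:
    """Read the two resident alleles of every trio member at a site.

    Members carrying a bubble are heterozygous for its two alleles; others
    are genotyped by direct lookup in the backbone, testing the candidate
    alleles longest-first (so a deletion allele is preferred over its
    prefix when the following context supports it).  A lookup hitting an
    N, or a resident allele outside the trio's candidate set, makes the
    individual missing and excludes the site; more than two alleles in the
    union excludes it as multiallelic.
    """
    union: set[str] = set()
    for m in MEMBERS:
        b = site.bubbles.get(m)
        if b is not None:
            union.update((b.left, b.right))
    candidates = sorted(union, key=len, reverse=True)

    genotypes: dict[str, tuple[str, str] | None] = {}
    for m in MEMBERS:
        b = site.bubbles.get(m)
        if b is not None:
            genotypes[m] = (b.left, b.right)
            continue
        bb = trio_scaffolds[m].backbone
        pos = site.positions[m]
        allele = None
        for a in candidates:
            seg = bb[pos : pos + len(a)]
            if "N" in seg:
                allele = None
                break
            if seg == a:
                allele = a
                break
        genotypes[m] = (allele, allele) if allele is not None else None

    child_pos = site.positions["child"]
    cb = site.bubbles.get("child")
    if cb is not None:
        ref, alt = cb.left, cb.right
    else:
        others = sorted(union)
        cg = genotypes.get("child")
        if cg is not None and cg[0] in union:
            ref = cg[0]
            rest = [a for a in others if a != ref]
            alt = rest[0] if rest else None
        else:
            ref, alt = (others + [None, None])[:2]

    call = TrioPhaseCall(
        pos=child_pos,
        positions=dict(site.positions),
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        phased_samples={m: False for m in MEMBERS},
    )
    if site.excluded is not None:
        call.exclusion_reason = site.excluded
        return call
    if any(genotypes[m] is None for m in MEMBERS):
        call.exclusion_reason = "missing data"
        return call
    if len(union) > 2:
        call.exclusion_reason = "multiallelic"
        return call
    call.status = "unphased"
    return call


# ---------------------------------------------------------------------------
# Transmission phasing


def phase_by_transmission(call: TrioPhaseCall) -> TrioPhaseCall:
    """Resolve parent-of-origin by Mendelian transmission.

    A child allele pair must consist of one allele from each parent.  If
    exactly one (paternal, maternal) assignment is consistent, the site is
    phased (this also fixes each parent's transmitted allele); two
    consistent assignments (the triple-heterozygote) leave it unphased;
    none is a Mendelian violation.
    """
    if call.status == "excluded":
        return call
    father = call.genotypes["father"]
    mother = call.genotypes["mother"]
    child = call.genotypes["child"]
    child_sorted = tuple(sorted(child))
    assignments = {
        (cf, cm)
        for cf in set(father)
        for cm in set(mother)
        if tuple(sorted((cf, cm))) == child_sorted
    }
    if not assignments:
        call.mendel = "VIOL"
        call.status = "unphased"
        return call
    call.mendel = "OK"
    if len(assignments) == 1:
        cf, cm = next(iter(assignments))
        call.status = "phased"
        call.child_paternal = cf
        call.child_maternal = cm
        call.father_transmitted = cf
        call.mother_transmitted = cm
        call.phased_samples = {m: True for m in MEMBERS}
    else:
        call.status = "unphased"
    return call


def nontransmitted_allele(call: TrioPhaseCall, parent: str) -> str | None:
    """The parent's allele not passed to the child (multiset complement)."""
    transmitted = (
        call.father_transmitted if parent == "father" else call.mother_transmitted
    )
    if transmitted is None:
        return None
    g = list(call.genotypes[parent])
    g.remove(transmitted)
    return g[0]


# ---------------------------------------------------------------------------
# Haplotype emission


class CoordMap:
    """Monotone backbone -> emitted-sequence coordinate map."""

    def __init__(self):
        self._breaks = [0]
        self._deltas = [0]

    def add_edit(self, backbone_end: int, delta: int):
        self._breaks.append(backbone_end)
        self._deltas.append(self._deltas[-1] + delta)

    def __call__(self, pos: int) -> int:
        i = bisect.bisect_right(self._breaks, pos) - 1
        return pos + self._deltas[i]


HAPLOTYPE_KEYS = (
    "father_transmitted",
    "father_nontransmitted",
    "mother_transmitted",
    "mother_nontransmitted",
    "child_paternal",
    "child_maternal",
)


@dataclass
class HaplotypeSet:
    """The six per-trio haplotype sequences plus consensus pairs."""

    sequences: dict[str, str]
    coord_maps: dict[str, CoordMap]
    calls: list[TrioPhaseCall]
    consensus: dict[str, str] = field(default_factory=dict)
    disagreements: list[tuple[str, int]] = field(default_factory=list)


def _project(
    scaffold: BubbledScaffold, substitutions: dict[int, str]
) -> tuple[str, CoordMap]:
    """Backbone with per-bubble substitutions; unresolved bubbles become Ns.

    Substituting an allele of different length shifts all downstream
    coordinates; the returned :class:`CoordMap` tracks the cumulative
    shift so call positions can be updated.
    """
    parts: list[str] = []
    cmap = CoordMap()
    cursor = 0
    bb = scaffold.backbone
    for b in scaffold.bubbles:
        parts.append(bb[cursor : b.pos])
        rep = substitutions.get(b.pos)
        if rep is None:
            rep = "N" * len(b.left)
        parts.append(rep)
        end = b.pos + len(b.left)
        if len(rep) != len(b.left):
            cmap.add_edit(end, len(rep) - len(b.left))
        cursor = end
    parts.append(bb[cursor:])
    return "".join(parts), cmap


def emit_haplotypes(
    trio_scaffolds: dict[str, BubbledScaffold], calls: list[TrioPhaseCall]
) -> HaplotypeSet:
    """Emit the six haplotype sequences from the phased call set.

    Phased bubbles are substituted by the resolved allele; unphased or
    uncalled bubbles are written as an N-run of the backbone allele's
    length, keeping coordinates stable while marking uncertainty.
    """
    subs: dict[str, dict[int, str]] = {k: {} for k in HAPLOTYPE_KEYS}
    for call in calls:
        if call.status != "phased":
            continue
        fpos, mpos, cpos = (call.positions[m] for m in MEMBERS)
        if call.genotypes["father"][0] != call.genotypes["father"][1]:
            _add_sub(subs["father_transmitted"], fpos, call.father_transmitted)
            _add_sub(subs["father_nontransmitted"], fpos, nontransmitted_allele(call, "father"))
        if call.genotypes["mother"][0] != call.genotypes["mother"][1]:
            _add_sub(subs["mother_transmitted"], mpos, call.mother_transmitted)
            _add_sub(subs["mother_nontransmitted"], mpos, nontransmitted_allele(call, "mother"))
        if call.genotypes["child"][0] != call.genotypes["child"][1]:
            _add_sub(subs["child_paternal"], cpos, call.child_paternal)
            _add_sub(subs["child_maternal"], cpos, call.child_maternal)

    sequences: dict[str, str] = {}
    coord_maps: dict[str, CoordMap] = {}
    source = {
        "father_transmitted": "father",
        "father_nontransmitted": "father",
        "mother_transmitted": "mother",
        "mother_nontransmitted": "mother",
        "child_paternal": "child",
        "child_maternal": "child",
    }
    for key in HAPLOTYPE_KEYS:
        seq, cmap = _project(trio_scaffolds[source[key]], subs[key])
        sequences[key] = seq
        coord_maps[key] = cmap
    return HaplotypeSet(sequences=sequences, coord_maps=coord_maps, calls=calls)


def _add_sub(d: dict[int, str], pos: int, allele: str | None):
    if allele is None:
        return
    if pos in d and d[pos] != allele:
        raise ValueError(f"overlapping allele substitutions at {pos}")
    d[pos] = allele


# ---------------------------------------------------------------------------
# Consensus construction


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _align_merge(parent: str, child: str, base_out: int):
    """Globally align a segment pair and merge per column.

    Agreement keeps the base; an N on one side takes the other side's
    base; a true mismatch takes the child base and logs a disagreement
    (consensus-frame position).  Child-side insertions are kept, parent
    insertions are kept only where the child side is N-free... (deletions
    from the child are honoured unless the parent bases fill an N run).
    """
    disagreements = []
    if parent == child:
        return child, disagreements
    res = edlib.align(child, parent, mode="NW", task="path")
    out: list[str] = []
    out_len = 0
    ci = pi = 0
    for m in _CIGAR_RE.finditer(res["cigar"]):
        ln, op = int(m.group(1)), m.group(2)
        if op in ("=", "M", "X"):
            for _ in range(ln):
                a, b = parent[pi], child[ci]
                if a == b or a == "N":
                    out.append(b)
                elif b == "N":
                    out.append(a)
                else:
                    disagreements.append(base_out + out_len)
                    out.append(b)
                out_len += 1
                pi += 1
                ci += 1
        elif op == "I":  # present in child only
            out.append(child[ci : ci + ln])
            out_len += ln
            ci += ln
        elif op == "D":  # present in parent only
            seg = parent[pi : pi + ln]
            if "N" not in seg:
                # structural disagreement resolved toward the child: drop,
                # but log it once
                disagreements.append(base_out + out_len)
            pi += ln
    return "".join(out), disagreements


def build_consensus(
    parent_seq: str,
    child_seq: str,
    anchors: list[tuple[int, int, int]],
    max_ratio: float = 2.0,
) -> tuple[str, list[int]]:
    """Merge a transmitted parental haplotype with the inherited child one.

    ``anchors`` are (parent_pos, child_pos, allele_length) triples of the
    phased sites shared by both frames; each inter-anchor segment pair is
    globally aligned and merged column-wise.  A segment pair whose length
    ratio exceeds ``max_ratio`` signals structural disagreement and is
    replaced by Ns.
    """
    anchors = sorted(anchors, key=lambda t: t[0])
    out: list[str] = []
    disagreements: list[int] = []
    p_cursor = c_cursor = 0
    cuts = anchors + [(len(parent_seq), len(child_seq), 0)]
    out_len = 0
    for p_pos, c_pos, alen in cuts:
        pseg = parent_seq[p_cursor:p_pos]
        cseg = child_seq[c_cursor:c_pos]
        if min(len(pseg), len(cseg)) == 0 and max(len(pseg), len(cseg)) > 0:
            merged = cseg or pseg
            out.append(merged)
            out_len += len(merged)
        elif len(pseg) and len(cseg):
            if max(len(pseg), len(cseg)) > max_ratio * min(len(pseg), len(cseg)):
                logger.warning(
                    "segment length ratio exceeds %.1f; emitting N gap", max_ratio
                )
                merged = "N" * len(cseg)
                out.append(merged)
                out_len += len(merged)
            else:
                merged, dis = _align_merge(pseg, cseg, out_len)
                disagreements.extend(dis)
                out.append(merged)
                out_len += len(merged)
        allele = child_seq[c_pos : c_pos + alen]
        out.append(allele)
        out_len += alen
        p_cursor = p_pos + alen
        c_cursor = c_pos + alen
    return "".join(out), disagreements


def add_consensus(hapset: HaplotypeSet) -> HaplotypeSet:
    """Fill the two parent-child consensus sequences of a haplotype set."""
    pairs = {
        "paternal": ("father_transmitted", "child_paternal", "father", "child"),
        "maternal": ("mother_transmitted", "child_maternal", "mother", "child"),
    }
    for label, (pkey, ckey, pmember, cmember) in pairs.items():
        anchors = []
        for call in hapset.calls:
            if call.status != "phased":
                continue
            allele = (
                call.child_paternal if label == "paternal" else call.child_maternal
            )
            anchors.append(
                (
                    hapset.coord_maps[pkey](call.positions[pmember]),
                    hapset.coord_maps[ckey](call.positions[cmember]),
                    len(allele),
                )
            )
        consensus, dis = build_consensus(
            hapset.sequences[pkey], hapset.sequences[ckey], anchors
        )
        hapset.consensus[label] = consensus
        hapset.disagreements.extend((label, d) for d in dis)
    return hapset


# ---------------------------------------------------------------------------
# Gap filling and iteration


class ShiftMap:
    """Old -> new coordinate translation after in-place edits."""

    def __init__(self):
        self._pos = [0]
        self._deltas = [0]

    def add(self, old_end: int, delta: int):
        self._pos.append(old_end)
        self._deltas.append(self._deltas[-1] + delta)

    def __call__(self, pos: int) -> int:
        i = bisect.bisect_right(self._pos, pos) - 1
        return pos + self._deltas[i]


def _unique_find(hay: str, needle: str) -> int | None:
    i = hay.find(needle)
    if i == -1:
        return None
    if hay.find(needle, i + 1) != -1:
        return None
    return i


def fill_gaps(
    scaffold: BubbledScaffold,
    donors: list[BubbledScaffold],
    k: int = UFS_LEN,
    max_span: int = 400,
) -> tuple[BubbledScaffold, ShiftMap]:
    """Close N-runs by unique exact matching of their flanks in trio donors.

    For each N-run, the k-bp flanks on both sides are searched in the
    other trio members' backbones; a unique, consistently ordered hit pair
    donates the intervening sequence (which may be empty — scaffold-join
    Ns between truly abutting fragments are thereby removed).
    """
    bb = scaffold.backbone
    edits: list[tuple[int, int, str]] = []  # (start, end, replacement)
    for m in re.finditer("N+", bb):
        s, e = m.start(), m.end()
        left = bb[s - k : s]
        right = bb[e : e + k]
        if len(left) < k or len(right) < k or "N" in left or "N" in right:
            continue
        for donor in donors:
            li = _unique_find(donor.backbone, left)
            if li is None:
                continue
            ri = _unique_find(donor.backbone, right)
            if ri is None:
                continue
            fill_start = li + k
            if not (0 <= ri - fill_start <= (e - s) + max_span):
                continue
            fill = donor.backbone[fill_start:ri]
            if "N" in fill:
                continue
            edits.append((s, e, fill))
            break

    if not edits:
        return scaffold, ShiftMap()
    edits.sort()
    smap = ShiftMap()
    parts: list[str] = []
    cursor = 0
    for s, e, fill in edits:
        parts.append(bb[cursor:s])
        parts.append(fill)
        smap.add(e, len(fill) - (e - s))
        cursor = e
    parts.append(bb[cursor:])
    new_bubbles = [
        Bubble(pos=smap(b.pos), left=b.left, right=b.right) for b in scaffold.bubbles
    ]
    return BubbledScaffold(scaffold.id, "".join(parts), new_bubbles), smap


@dataclass
class PhaseRound:
    calls: list[TrioPhaseCall]
    counters: StageCounters
    scaffolds: dict[str, BubbledScaffold]


@dataclass
class PhaseOutcome:
    """Final call set, haplotypes and per-round phasing report for a trio."""

    calls: list[TrioPhaseCall]
    hapset: HaplotypeSet
    counters: StageCounters
    phased_fraction_per_round: list[float]
    scaffolds: dict[str, BubbledScaffold]

    @property
    def phased_fraction(self) -> float:
        return self.phased_fraction_per_round[-1]

    def bubble_phased_fraction(self) -> float:
        """Fraction of all assembly bubbles phased without violation."""
        total = self.counters.get("bubbles_total", 0)
        if total == 0:
            return float("nan")
        phased_bubbles = 0
        for call in self.calls:
            if call.status != "phased":
                continue
            for m in MEMBERS:
                g = call.genotypes[m]
                if g is not None and g[0] != g[1]:
                    phased_bubbles += 1
        return phased_bubbles / total


def _single_pass(
    trio_scaffolds: dict[str, BubbledScaffold],
    ufs_len: int,
    use_downstream: bool,
) -> PhaseRound:
    counters = StageCounters()
    tables = {
        m: extract_anchors(s, ufs_len=ufs_len, member=m)
        for m, s in trio_scaffolds.items()
    }
    sites = match_anchors(
        tables, trio_scaffolds, use_downstream=use_downstream, counters=counters
    )
    calls = []
    for site in sites:
        call = phase_by_transmission(genotype_site(trio_scaffolds, site))
        calls.append(call)
        counters.incr(f"sites_{call.status}")
        if call.mendel == "VIOL":
            counters.incr("mendelian_violations")
    return PhaseRound(calls=calls, counters=counters, scaffolds=trio_scaffolds)


_STATUS_RANK = {"phased": 2, "unphased": 1, "excluded": 0}


def run_phasing(
    trio_scaffolds: dict[str, BubbledScaffold],
    ufs_len: int = UFS_LEN,
    rounds: int = 1,
    use_downstream: bool = True,
) -> PhaseOutcome:
    """Run ``rounds`` passes of anchoring, genotyping and phasing.

    From the second round on, N-gaps (including scaffold-join Ns) are
    closed by cross-individual exact matching before re-anchoring, which
    rescues sites whose flanks crossed missing sequence.  Calls from
    earlier rounds are carried forward (coordinate-translated), so the
    phased fraction is nondecreasing across rounds.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    scaffolds = dict(trio_scaffolds)
    merged: dict[tuple[int, int, int], TrioPhaseCall] = {}
    fractions: list[float] = []
    counters = StageCounters()

    for r in range(rounds):
        if r > 0:
            new_scaffolds = {}
            shift_maps = {}
            for m in MEMBERS:
                donors = [scaffolds[o] for o in MEMBERS if o != m]
                new_scaffolds[m], shift_maps[m] = fill_gaps(
                    scaffolds[m], donors, k=ufs_len
                )
            scaffolds = new_scaffolds
            translated: dict[tuple[int, int, int], TrioPhaseCall] = {}
            for call in merged.values():
                call.positions = {
                    m: shift_maps[m](call.positions[m]) for m in MEMBERS
                }
                call.pos = call.positions["child"]
                translated[tuple(call.positions[m] for m in MEMBERS)] = call
            merged = translated

        rnd = _single_pass(scaffolds, ufs_len, use_downstream)
        if r == 0:
            counters = rnd.counters
        for call in rnd.calls:
            key = tuple(call.positions[m] for m in MEMBERS)
            old = merged.get(key)
            if old is None or _STATUS_RANK[call.status] >= _STATUS_RANK[old.status]:
                if call.status == "phased":
                    call.phased_round = (
                        old.phased_round
                        if old is not None and old.phased_round is not None
                        else r + 1
                    )
                elif old is not None:
                    call.phased_round = old.phased_round
                merged[key] = call

    calls = sorted(merged.values(), key=lambda c: c.pos)
    # per-round phased fraction over the final call set: the share of all
    # called sites resolved by the end of each round (monotone)
    n_called = sum(c.status != "excluded" for c in calls)
    for r in range(1, rounds + 1):
        resolved = sum(
            c.phased_round is not None and c.phased_round <= r for c in calls
        )
        fractions.append(resolved / n_called if n_called else float("nan"))
    hapset = add_consensus(emit_haplotypes(scaffolds, calls))
    for st in ("phased", "unphased", "excluded"):
        counters[f"final_sites_{st}"] = sum(c.status == st for c in calls)
    return PhaseOutcome(
        calls=calls,
        hapset=hapset,
        counters=counters,
        phased_fraction_per_round=fractions,
        scaffolds=scaffolds,
    )


def iterate_phasing(
    outcome: PhaseOutcome, rounds: int = 1, ufs_len: int = UFS_LEN
) -> PhaseOutcome:
    """Apply ``rounds`` additional re-anchoring rounds to a first pass.

    ``rounds=0`` returns the input unchanged.
    """
    if rounds == 0:
        return outcome
    total = len(outcome.phased_fraction_per_round) + rounds
    return run_phasing(outcome.scaffolds, ufs_len=ufs_len, rounds=total)


# ---------------------------------------------------------------------------
# Nontransmitted back-mapping


def map_to_nontransmitted(
    hapset: HaplotypeSet, ufs_len: int = UFS_LEN
) -> dict[str, float]:
    """Map phased variants onto the nontransmitted parental haplotypes.

    For each phased site at which a parent is heterozygous, the 40-bp
    flank upstream of the site on the transmitted haplotype is searched in
    the nontransmitted haplotype; a unique exact hit maps the variant.
    Returns per-parent and overall mapped fractions.
    """
    results: dict[str, float] = {}
    totals = mapped_all = 0
    for parent in ("father", "mother"):
        tkey, nkey = f"{parent}_transmitted", f"{parent}_nontransmitted"
        tseq = hapset.sequences[tkey]
        nseq = hapset.sequences[nkey]
        # index the nontransmitted haplotype's k-mers once
        index: dict[str, int | None] = {}
        k = ufs_len
        for i in range(len(nseq) - k + 1):
            kmer = nseq[i : i + k]
            if kmer in index:
                index[kmer] = None
            else:
                index[kmer] = i
        n_mapped = n_total = 0
        for call in hapset.calls:
            if call.status != "phased":
                continue
            g = call.genotypes[parent]
            if g is None or g[0] == g[1]:
                continue
            tpos = hapset.coord_maps[tkey](call.positions[parent])
            flank = tseq[tpos - k : tpos]
            n_total += 1
            if len(flank) < k or "N" in flank:
                continue
            hit = index.get(flank, None)
            if hit is not None:
                n_mapped += 1
        results[parent] = n_mapped / n_total if n_total else float("nan")
        totals += n_total
        mapped_all += n_mapped
    results["overall"] = mapped_all / totals if totals else float("nan")
    return results
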