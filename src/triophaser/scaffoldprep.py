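"""Build one diploid region scaffold per individual from assembly pieces.

Scaffolds overlapping the target region are selected by aligned length
(>= 50 kb by default), ordered by the median reference start of their
alignment blocks (blocks shorter than half the scaffold's largest block
are ignored), oriented by the strand carrying the larger summed aligned
length, optionally trimmed around start/end anchor genes, and finally
concatenated with single-N joins into one bubbled scaffold.

Alignments are consumed from a tabular input (scaffold, ref_start,
ref_end, scaf_start, scaf_end, strand) — at desk scale they come from the
simulator; with real data any reference aligner producing block tables
can feed this module.  Anchor location uses a banded infix alignment
(edlib), tolerant of a few percent mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from .io_core import Bubble, BubbledScaffold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Block:
    ref_start: int
    ref_end: int
    scaf_start: int
    scaf_end: int
    strand: str

    def __post_init__(self):
        if self.ref_end < self.ref_start:
            raise ValueError("block with negative length")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class ScaffoldAlignment:
    """All alignment blocks of one scaffold against the reference frame."""

    scaffold: str
    blocks: list[Block]

    @property
    def aligned_length(self) -> int:
        return sum(b.length for b in self.blocks)


def read_alignments(source: str | Path | pd.DataFrame) -> list[ScaffoldAlignment]:
    """Read the tabular alignment format into per-scaffold records."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    out = []
    for name, grp in df.groupby("scaffold", sort=False):
        blocks = [
            Block(
                int(r.ref_start),
                int(r.ref_end),
                int(r.scaf_start),
                int(r.scaf_end),
                str(r.strand),
            )
            for r in grp.itertuples()
        ]
        out.append(ScaffoldAlignment(str(name), blocks))
    return out


@dataclass
class RegionScaffoldSet:
    """Ordered, oriented (and possibly trimmed) scaffolds spanning the region."""

    scaffolds: list[BubbledScaffold]
    medians: list[int]
    join_positions: list[int] = field(default_factory=list)

    def __post_init__(self):
        if any(b < a for a, b in zip(self.medians, self.medians[1:])):
            raise ValueError("scaffolds must be ordered by nondecreasing median")


def select_scaffolds(
    alignments: list[ScaffoldAlignment], min_aligned: int = 50_000
) -> list[ScaffoldAlignment]:
    """Keep scaffolds with at least ``min_aligned`` bp of aligned length.

    The whole scaffold is retained downstream, not only its aligned parts.
    An empty selection means the region is not covered and is an error.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    kept = [a for a in alignments if a.aligned_length >= min_aligned]
    if not kept:
        raise ValueError(
            f"no scaffold reaches {min_aligned} bp of aligned length; "
            "region not covered"
        )
    return kept


def _retained_blocks(aln: ScaffoldAlignment) -> list[Block]:
    """Drop blocks shorter than half this scaffold's largest block."""
    longest = max(b.length for b in aln.blocks)
    return [b for b in aln.blocks if b.length >= longest / 2]


def _lower_median(values: list[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def order_and_orient(
    selected: list[ScaffoldAlignment],
    scaffolds: dict[str, BubbledScaffold],
) -> RegionScaffoldSet:
    """Order scaffolds by median block start and fix their orientation.

    Orientation follows the strand with the larger summed aligned length
    (ties keep '+'); antisense scaffolds are reverse-complemented with
    their bubbles mirrored.
    """
    entries: list[tuple[int, BubbledScaffold]] = []
    for aln in selected:
        if not aln.blocks:
            logger.warning("scaffold %s has no alignment blocks; dropped", aln.scaffold)
            continue
        retained = _retained_blocks(aln)
        median = _lower_median([b.ref_start for b in retained])
        plus = sum(b.length for b in retained if b.strand == "+")
        minus = sum(b.length for b in retained if b.strand == "-")
        seq = scaffolds[aln.scaffold]
        if minus > plus:
            seq = seq.reverse_complement()
        elif minus == plus and minus > 0:
            logger.info("scaffold %s strand tie; keeping + orientation", aln.scaffold)
        entries.append((median, seq))
    entries.sort(key=lambda t: t[0])
    return RegionScaffoldSet(
        scaffolds=[e[1] for e in entries], medians=[e[0] for e in entries]
    )


def locate_anchor(
    backbone: str, anchor: str, max_divergence: float = 0.15
) -> tuple[int, int] | None:
    """Best infix hit of ``anchor`` in ``backbone`` ([start, end) or None)."""
    res = edlib.align(anchor, backbone, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_divergence * len(anchor):
        return None
    start, end = res["locations"][0]
    return start, end + 1


def trim_by_anchors(
    ordered: RegionScaffoldSet,
    start_anchor: str | None,
    end_anchor: str | None,
    upstream_pad: int = 1_000_000,
    downstream_pad: int = 1_000,
) -> RegionScaffoldSet:
    """Trim the first/last scaffold around the region's anchor genes.

    The region starts ``upstream_pad`` bp before the best hit of
    ``start_anchor`` on the first scaffold and ends ``downstream_pad`` bp
    after the best hit of ``end_anchor`` on the last.  A missing anchor
    leaves that end untouched (with a warning).
    """
    for anchor in (start_anchor, end_anchor):
        if anchor is not None and len(anchor) < 100:
            raise ValueError("anchors must be at least 100 bp")
    scaffolds = list(ordered.scaffolds)
    if start_anchor is not None and scaffolds:
        hit = locate_anchor(scaffolds[0].backbone, start_anchor)
        if hit is None:
            logger.warning("start anchor not found; leaving region start untrimmed")
        else:
            start = max(0, hit[0] - upstream_pad)
            scaffolds[0] = scaffolds[0].slice(start, len(scaffolds[0].backbone))
    if end_anchor is not None and scaffolds:
        hit = locate_anchor(scaffolds[-1].backbone, end_anchor)
        if hit is None:
            logger.warning("end anchor not found; leaving region end untrimmed")
        else:
            end = min(len(scaffolds[-1].backbone), hit[1] + downstream_pad)
            scaffolds[-1] = scaffolds[-1].slice(0, end)
    return RegionScaffoldSet(scaffolds=scaffolds, medians=list(ordered.medians))


def concatenate(trimmed: RegionScaffoldSet, region_id: str = "region") -> BubbledScaffold:
    """Concatenate with a single N at each join; bubble coordinates lifted."""
    if not trimmed.scaffolds:
        raise ValueError("nothing to concatenate")
    parts: list[str] = []
    bubbles: list[Bubble] = []
    joins: list[int] = []
    offset = 0
    for i, sc in enumerate(trimmed.scaffolds):
        if i > 0:
            parts.append("N")
            joins.append(offset)
            offset += 1
        parts.append(sc.backbone)
        bubbles.extend(
            Bubble(pos=b.pos + offset, left=b.left, right=b.right) for b in sc.bubbles
        )
        offset += len(sc.backbone)
    trimmed.join_positions = joins
    return BubbledScaffold(id=region_id, backbone="".join(parts), bubbles=bubbles)


def prep_individual(
    alignments: list[ScaffoldAlignment] | pd.DataFrame,
    scaffolds: dict[str, BubbledScaffold],
    min_aligned: int = 50_000,
    start_anchor: str | None = None,
    end_anchor: str | None = None,
    upstream_pad: int = 1_000_000,
    downstream_pad: int = 1_000,
    region_id: str = "region",
) -> tuple[BubbledScaffold, RegionScaffoldSet]:
    """select -> order/orient -> trim -> concatenate, in one call."""
    if isinstance(alignments, pd.DataFrame):
        alignments = read_alignments(alignments)
    kept = select_scaffolds(alignments, min_aligned=min_aligned)
    ordered = order_and_orient(kept, scaffolds)
    trimmed = trim_by_anchors(
        ordered, start_anchor, end_anchor, upstream_pad, downstream_pad
    )
    return concatenate(trimmed, region_id=region_id), trimmed
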