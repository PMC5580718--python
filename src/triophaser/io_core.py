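"""Formats and containers shared across the pipeline.

The central sequence container is :class:`BubbledScaffold`: a scaffold
backbone with embedded biallelic *bubbles*, the places where a diploid
assembler has retained both alleles of a heterozygous site.  On disk a
bubbled scaffold is stored in a "bubbled FASTA" dialect in which a bubble
is written inline as ``[LEFT|RIGHT]``; the backbone is defined as the body
with every token replaced by its LEFT allele.

Also provided: plain FASTA helpers, a VCF 4.2 emitter for trio phase
calls, BED interval and tabular-alignment readers, a flat key=value run
configuration, and per-stage counters used as the pipeline's metric
surface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class BubbledFastaError(ValueError):
    """Raised on malformed bubbled-FASTA input; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Bubble:
    """A biallelic divergence at ``pos`` on the backbone.

    ``backbone[pos : pos + len(left)] == left`` always holds; ``right`` is
    the alternative allele path.  Alleles are nonempty, differ, and are
    N-free.
    """

    pos: int
    left: str
    right: str

    def __post_init__(self):
        if not self.left or not self.right:
            raise ValueError("bubble alleles must be nonempty")
        if self.left == self.right:
            raise ValueError("bubble alleles must differ")
        if "N" in self.left or "N" in self.right:
            raise ValueError("bubble alleles must be N-free")


@dataclass
class BubbledScaffold:
    """A scaffold backbone plus its bubbles, positions strictly increasing."""

    id: str
    backbone: str
    bubbles: list[Bubble] = field(default_factory=list)

    def __post_init__(self):
        last_end = -1
        for b in self.bubbles:
            if b.pos <= last_end:
                raise ValueError(
                    f"{self.id}: bubble at {b.pos} overlaps or is out of order"
                )
            if self.backbone[b.pos : b.pos + len(b.left)] != b.left:
                raise ValueError(
                    f"{self.id}: backbone does not carry left allele at {b.pos}"
                )
            last_end = b.pos + len(b.left) - 1

    def __len__(self) -> int:
        return len(self.backbone)

    @property
    def n_bubbles(self) -> int:
        return len(self.bubbles)

    def reverse_complement(self) -> "BubbledScaffold":
        """Whole-scaffold reverse complement with bubbles mirrored."""
        n = len(self.backbone)
        new_bubbles = [
            Bubble(
                pos=n - (b.pos + len(b.left)),
                left=reverse_complement(b.left),
                right=reverse_complement(b.right),
            )
            for b in reversed(self.bubbles)
        ]
        return BubbledScaffold(
            id=self.id,
            backbone=reverse_complement(self.backbone),
            bubbles=new_bubbles,
        )

    def slice(self, start: int, end: int, new_id: str | None = None) -> "BubbledScaffold":
        """Subscaffold over backbone coordinates [start, end).

        Bubbles not fully contained in the slice are dropped (their allele
        would be truncated); retained bubbles are shifted by ``-start``.
        """
        start = max(0, start)
        end = min(len(self.backbone), end)
        kept = [
            replace(b, pos=b.pos - start)
            for b in self.bubbles
            if b.pos >= start and b.pos + len(b.left) <= end
        ]
        return BubbledScaffold(
            id=new_id or self.id, backbone=self.backbone[start:end], bubbles=kept
        )

    def to_body(self) -> str:
        """Serialize to the bubbled-FASTA body (no header, single line)."""
        parts: list[str] = []
        cursor = 0
        for b in self.bubbles:
            parts.append(self.backbone[cursor : b.pos])
            parts.append(f"[{b.left}|{b.right}]")
            cursor = b.pos + len(b.left)
        parts.append(self.backbone[cursor:])
        return "".join(parts)


_TOKEN_RE = re.compile(r"\[([^\[\]|]*)\|([^\[\]|]*)\]")


def parse_bubbled_body(body: str, record_id: str = "", line: int | None = None) -> BubbledScaffold:
    """Parse a bubbled-FASTA body into a :class:`BubbledScaffold`."""
    backbone_parts: list[str] = []
    bubbles: list[Bubble] = []
    cursor = 0
    pos = 0
    for m in _TOKEN_RE.finditer(body):
        plain = body[cursor : m.start()]
        if "[" in plain or "]" in plain or "|" in plain:
            raise BubbledFastaError(
                f"record {record_id!r}: stray bracket or '|' outside bubble token", line
            )
        left, right = m.group(1), m.group(2)
        if not left or not right:
            raise BubbledFastaError(f"record {record_id!r}: empty bubble allele", line)
        backbone_parts.append(plain)
        pos += len(plain)
        try:
            bubbles.append(Bubble(pos=pos, left=left, right=right))
        except ValueError as exc:
            raise BubbledFastaError(f"record {record_id!r}: {exc}", line) from exc
        backbone_parts.append(left)
        pos += len(left)
        cursor = m.end()
    tail = body[cursor:]
    if "[" in tail or "]" in tail or "|" in tail:
        raise BubbledFastaError(
            f"record {record_id!r}: unbalanced bracket or stray '|'", line
        )
    backbone_parts.append(tail)
    return BubbledScaffold(id=record_id, backbone="".join(backbone_parts), bubbles=bubbles)


def read_bubbled_fasta(path: str | Path) -> list[BubbledScaffold]:
    """Read a bubbled-FASTA file (plain FASTA parses with zero bubbles)."""
    records: list[BubbledScaffold] = []
    header: str | None = None
    body_lines: list[str] = []
    header_line = 0

    def flush():
        if header is not None:
            records.append(
                parse_bubbled_body("".join(body_lines), header, header_line)
            )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                flush()
                header = stripped[1:].split()[0]
                header_line = lineno
                body_lines = []
            else:
                if header is None:
                    raise BubbledFastaError("sequence before first header", lineno)
                body_lines.append(stripped)
    flush()
    return records


def write_bubbled_fasta(
    scaffolds: Iterable[BubbledScaffold], path: str | Path, width: int = 80
) -> None:
    with open(path, "w") as fh:
        for sc in scaffolds:
            fh.write(f">{sc.id}\n")
            body = sc.to_body()
            for i in range(0, len(body), width):
                fh.write(body[i : i + width] + "\n")


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write (name, sequence) pairs as plain FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for raw in fh:
            s = raw.strip()
            if not s:
                continue
            if s.startswith(">"):
                if name is not None:
                    out.append((name, "".join(chunks)))
                name = s[1:].split()[0]
                chunks = []
            else:
                chunks.append(s)
    if name is not None:
        out.append((name, "".join(chunks)))
    return out


# ---------------------------------------------------------------------------
# BED / tabular alignments


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with a class label."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")


def read_bed(path: str | Path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for raw in fh:
            s = raw.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split("\t")
            label = fields[3] if len(fields) > 3 else ""
            intervals.append(Interval(int(fields[1]), int(fields[2]), label))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path, chrom: str = "region") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# VCF emission (4.2, plain text)


def write_vcf(
    calls,
    path: str | Path,
    contig: str,
    contig_length: int,
    sample_names: Sequence[str] = ("father", "mother", "child"),
) -> None:
    """Write trio phase calls as VCF 4.2.

    ``calls`` is an iterable of objects exposing ``pos`` (0-based), ``ref``,
    ``alt``, per-sample genotypes as allele-string pairs (or None), a
    ``phased`` flag per sample and a Mendelian status; in practice these are
    :class:`triophaser.triophase.TrioPhaseCall`.  GT separators encode phase
    (``|`` phased, ``/`` unphased); INFO carries ``MENDEL`` in {OK,VIOL,NA}.
    Input must be coordinate-sorted; unsorted input is rejected.
    """
    calls = list(calls)
    positions = [c.pos for c in calls]
    if positions != sorted(positions):
        raise ValueError("calls must be coordinate-sorted")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        fh.write(
            '##INFO=<ID=MENDEL,Number=1,Type=String,'
            'Description="Mendelian status of the trio genotype">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for c in calls:
            alleles = [c.ref, c.alt]
            gts = []
            for sample in sample_names:
                gt = c.genotypes.get(sample)
                sep = "|" if c.phased_samples.get(sample, False) else "/"
                if gt is None:
                    gts.append(f".{sep}.")
                else:
                    try:
                        idx = [alleles.index(a) for a in gt]
                    except ValueError:
                        gts.append(f".{sep}.")
                        continue
                    gts.append(f"{idx[0]}{sep}{idx[1]}")
            fh.write(
                f"{contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"MENDEL={c.mendel}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Run configuration

#: Constants carried through from the original study design, with provenance.
STUDY_DEFAULTS = {
    "ufs_len": 40,            # exact-match anchor length (bp)
    "min_aligned": 50_000,    # minimum aligned scaffold length (bp)
    "pad_upstream": 1_000_000,
    "pad_downstream": 1_000,
    "pi_window": 5_000,
    "pi_step": 1_000,
    "density_window": 50_000,
    "density_step": 10_000,
    "diff_bin": 10_000,
    "ld_bin": 10_000,
    "maf_bin_size": 25,
    "maf_min": 0.05,
    "frac_nonsyn": 0.73,
    "frac_syn": 0.27,
    "max_align_fail": 0.2,
    "n_mask_frac": 0.5,
    "rounds": 2,
}


@dataclass
class RunConfig:
    """Flat bundle of pipeline tunables with provenance tags.

    Every field defaults to the study constant (tagged ``study-default``);
    fields overridden by the user are tagged ``user``.
    """

    values: dict = field(default_factory=lambda: dict(STUDY_DEFAULTS))
    provenance: dict = field(
        default_factory=lambda: {k: "study-default" for k in STUDY_DEFAULTS}
    )

    def set(self, key: str, value) -> None:
        self.values[key] = value
        self.provenance[key] = "user"

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a flat ``key=value`` file."""
        cfg = cls()
        with open(path) as fh:
            for raw in fh:
                s = raw.strip()
                if not s or s.startswith("#"):
                    continue
                key, _, val = s.partition("=")
                key = key.strip()
                val = val.strip()
                if key not in cfg.values:
                    raise KeyError(f"unknown config key: {key}")
                old = cfg.values[key]
                cfg.set(key, type(old)(float(val)) if isinstance(old, (int, float)) else val)
        return cfg


class StageCounters(dict):
    """Per-stage counters (bubbles total/anchored/phased/violations...).

    A thin dict that supports increments and pretty-printing; these counters
    are the pipeline's reporting surface.
    """

    def incr(self, key: str, by: int = 1) -> None:
        self[key] = self.get(key, 0) + by

    def report(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in sorted(self.items()))
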