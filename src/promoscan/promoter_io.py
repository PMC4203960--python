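"""Promoter sequences, intervals, and the coordinate convention shared by all scanners.

A promoter here is the 2 kb of sequence immediately upstream of a
transcription start site (TSS), written 5'->3' on the gene's strand, so
that the *last* base of the string is the base immediately upstream of
the TSS.  Internally every interval is 0-based half-open on the string;
TSS-relative coordinates place that last base at position -1, i.e.
``tss_pos = index - length`` (index 0 <-> -2000 for a 2,000-bp promoter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

DEFAULT_PROMOTER_LENGTH = 2000

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(raw: str) -> str:
    """Uppercase, map U->T, and close the alphabet: anything outside
    {A,C,G,T} becomes N."""
    s = raw.upper().replace("U", "T")
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on a promoter string."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Promoter:
    """One upstream sequence anchored at the TSS (last base = position -1)."""

    gene_id: str
    seq: str
    species: str = ""

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


def to_tss_coords(iv: Interval, promoter_length: int) -> tuple[int, int]:
    """Map a string interval to TSS-relative coordinates.

    The last promoter base sits at -1, so the mapping is simply
    ``(start - length, end - length)``; its inverse is
    :func:`from_tss_coords`.
    """
    if iv.end > promoter_length:
        raise ValueError(
            f"interval [{iv.start}, {iv.end}) out of bounds for length {promoter_length}"
        )
    return iv.start - promoter_length, iv.end - promoter_length


def from_tss_coords(tss_start: int, tss_end: int, promoter_length: int) -> Interval:
    """Inverse of :func:`to_tss_coords`."""
    return Interval(tss_start + promoter_length, tss_end + promoter_length)


def read_fasta(path: str | Path, species: str = "") -> list[Promoter]:
    """Read promoters from FASTA, one record per gene.

    Sequences are normalized (uppercase, U->T, alphabet closed to
    {A,C,G,T,N}); gene_id is the first whitespace-delimited header token;
    record order is preserved.  Duplicate ids and empty files are errors.
    Records shorter than the conventional 2 kb are accepted with a warning
    (upstream extracts are often truncated at contig edges).
    """
    path = Path(path)
    promoters: list[Promoter] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id in {path}: {gene_id!r}")
        seen.add(gene_id)
        p = Promoter(gene_id=gene_id, seq=str(rec.seq), species=species)
        if p.length < DEFAULT_PROMOTER_LENGTH:
            log.warning(
                "promoter %s is %d bp (< %d); analyzed as-is",
                gene_id, p.length, DEFAULT_PROMOTER_LENGTH,
            )
        promoters.append(p)
    if not promoters:
        raise ValueError(f"no records in {path}")
    return promoters


def write_fasta(promoters: Iterable[Promoter], path: str | Path) -> None:
    """Write promoters back to FASTA (round-trips with :func:`read_fasta`)."""
    records = [
        SeqRecord(Seq(p.seq), id=p.gene_id, description="") for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")


def write_bed(
    calls: Sequence,
    path: str | Path,
    mode: str = "promoter",
    promoter_lengths: dict[str, int] | None = None,
) -> None:
    """Write motif calls as BED6.

    Each call must expose ``gene_id``, ``interval`` and the
    ``bed_name()`` / ``bed_score()`` hooks the scanners provide.  chrom is
    the gene id; coordinates are 0-based half-open, either promoter-relative
    (default) or TSS-relative (``mode="tss"``, both coordinates shifted by
    -length).  Lines are ordered by (gene_id, start, name).
    """
    if mode not in ("promoter", "tss"):
        raise ValueError(f"unknown BED mode {mode!r}")
    rows = []
    for c in calls:
        start, end = c.interval.start, c.interval.end
        if mode == "tss":
            length = (
                promoter_lengths[c.gene_id]
                if promoter_lengths is not None
                else getattr(c, "promoter_length")
            )
            start, end = start - length, end - length
        rows.append(
            (c.gene_id, start, end, c.bed_name(), c.bed_score(), getattr(c, "strand", "+"))
        )
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        fh.write("# BED6: chrom=gene_id, 0-based half-open\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
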