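"""Fixed consensus-motif scanning: IUPAC patterns, polypurine runs, TATA box.

This module scans promoters for *known* motif archetypes -- the TATA box,
poly-A and poly-G blocks, and arbitrary IUPAC consensus strings such as
the distal element CWGCWSWG (= C[A/T]GC[A/T][C/G][A/T]G) -- on the given
strand and optionally its reverse complement.  De novo motif discovery is
out of scope here; the scanner takes the archetypes as input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .promoter_io import Interval, Promoter, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: canonical TATA-box consensus used by default (config-overridable)
TATA_PATTERN = "TATAWAW"
#: distal consensus element C[A/T]GC[A/T][C/G][A/T]G
DISTAL_CONSENSUS = "CWGCWSWG"

DEFAULT_PATTERNS = {"TATA": TATA_PATTERN, "distal_consensus": DISTAL_CONSENSUS}

POLY_MIN_RUN_DEFAULT = 10


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC consensus into a character-class regex.

    N in the *sequence* never matches because every class expands to
    explicit bases only.
    """
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass(frozen=True)
class ConsensusHit:
    gene_id: str
    pattern_id: str
    iupac: str
    interval: Interval  # always forward coordinates
    strand: str
    promoter_length: int

    def bed_name(self) -> str:
        return f"{self.pattern_id}:{self.iupac}"

    def bed_score(self) -> int:
        return 0


def scan_iupac(
    p: Promoter,
    pattern: str,
    pattern_id: str | None = None,
    both_strands: bool = True,
) -> list[ConsensusHit]:
    """All (possibly overlapping) matches of an IUPAC pattern.

    Minus-strand hits (pattern matching the reverse complement) are
    reported on forward coordinates.  Sorted by (start, strand).
    """
    if not pattern:
        raise ValueError("empty pattern")
    pid = pattern_id if pattern_id is not None else pattern
    rx = re.compile(f"(?=({iupac_to_regex(pattern)}))")
    L = len(p.seq)
    w = len(pattern)
    hits = [
        ConsensusHit(gene_id=p.gene_id, pattern_id=pid, iupac=pattern,
                     interval=Interval(m.start(), m.start() + w), strand="+",
                     promoter_length=L)
        for m in rx.finditer(p.seq)
    ]
    if both_strands:
        rc = revcomp(p.seq)
        for m in rx.finditer(rc):
            s = m.start()
            hits.append(
                ConsensusHit(gene_id=p.gene_id, pattern_id=pid, iupac=pattern,
                             interval=Interval(L - s - w, L - s), strand="-",
                             promoter_length=L)
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_polypurine(
    p: Promoter, base: str, min_run: int = POLY_MIN_RUN_DEFAULT
) -> list[ConsensusHit]:
    """Maximal runs of one base (poly-A or poly-G blocks), one hit per run."""
    if base not in "AG":
        raise ValueError("polypurine base must be A or G")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    rx = re.compile(f"{base}{{{min_run},}}")
    L = len(p.seq)
    return [
        ConsensusHit(gene_id=p.gene_id, pattern_id=f"poly{base}",
                     iupac=base * min_run,
                     interval=Interval(m.start(), m.end()), strand="+",
                     promoter_length=L)
        for m in rx.finditer(p.seq)
    ]


def tata_positional_profile(hits: Sequence[ConsensusHit]) -> dict[int, int]:
    """Histogram of hit start positions in TSS-relative coordinates (1-bp bins)."""
    profile: dict[int, int] = {}
    for h in hits:
        pos = h.interval.start - h.promoter_length
        profile[pos] = profile.get(pos, 0) + 1
    return dict(sorted(profile.items()))
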