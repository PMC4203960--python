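"""Positional and contextual structure of promoter motifs.

GC profile along the promoter, binned motif distributions relative to
the TSS, the distal/proximal/core region partition, motif arrangement
relative to CpG islands (upstream / downstream / overlapped / intervened),
trinucleotide GC-class position profiles, and per-gene co-occurrence
contingency tables.

Region partition (TSS-relative, half-open): distal [-2000, -500),
proximal [-500, -100), core [-100, 0).  A motif's anchor for binning and
region assignment defaults to its interval midpoint, which avoids edge
bias for long elements; pass ``anchor="start"`` to anchor at the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cgi_scanner import CgiCall
from .promoter_io import Interval, Promoter
from .pqs_scanner import PqsCall
from .str_scanner import StrCall

#: TSS-relative half-open region boundaries
REGIONS = {"distal": (-2000, -500), "proximal": (-500, -100), "core": (-100, 0)}

CGI_RELATIONS = ("upstream", "downstream", "overlapped", "intervened", "no_cgi")


def region_of(tss_pos: int, length: int = 2000) -> str:
    """Region label of a TSS-relative position (scaled for non-2-kb promoters)."""
    scale = length / 2000
    if tss_pos < -500 * scale:
        return "distal"
    if tss_pos < -100 * scale:
        return "proximal"
    return "core"


def anchor_position(iv: Interval, length: int, anchor: str = "midpoint") -> int:
    """TSS-relative anchor of an interval (midpoint by default)."""
    if anchor == "midpoint":
        return iv.midpoint() - length
    if anchor == "start":
        return iv.start - length
    raise ValueError(f"unknown anchor {anchor!r}")


# ---------------------------------------------------------------------------
# GC profile
# ---------------------------------------------------------------------------

@dataclass
class GcProfile:
    window: int
    values: np.ndarray          # per-position mean GC fraction across promoters
    overall_mean: float
    per_promoter_gc: np.ndarray  # one GC fraction per promoter

    @property
    def gc_range(self) -> tuple[float, float]:
        return float(self.per_promoter_gc.min()), float(self.per_promoter_gc.max())


def gc_profile(promoters: Sequence[Promoter], window: int = 10) -> GcProfile:
    """Mean centered-window GC fraction at each position, averaged over promoters.

    Windows are clipped at the promoter edges.  Promoters must share one
    length.  Also reports the overall mean GC and per-promoter GC values.
    """
    if not promoters:
        raise ValueError("need at least one promoter")
    L = promoters[0].length
    if any(p.length != L for p in promoters):
        raise ValueError("gc_profile requires equal-length promoters")
    half = window // 2
    acc = np.zeros(L)
    per_gc = np.zeros(len(promoters))
    kernel = np.ones(window)
    for i, p in enumerate(promoters):
        arr = np.frombuffer(p.seq.encode("ascii"), dtype="S1")
        gc = ((arr == b"G") | (arr == b"C")).astype(float)
        per_gc[i] = gc.mean()
        num = np.convolve(gc, kernel, mode="full")[half : half + L]
        den = np.convolve(np.ones(L), kernel, mode="full")[half : half + L]
        acc += num / den
    return GcProfile(window=window, values=acc / len(promoters),
                     overall_mean=float(per_gc.mean()), per_promoter_gc=per_gc)


# ---------------------------------------------------------------------------
# Positional binning
# ---------------------------------------------------------------------------

@dataclass
class BinProfile:
    """Counts of motif anchors in fixed-width bins tiling [-length, 0)."""

    bin_width: int
    length: int
    counts: np.ndarray  # counts[i] covers [-length + i*w, -length + (i+1)*w)

    def bin_starts_tss(self) -> np.ndarray:
        return -self.length + self.bin_width * np.arange(len(self.counts))

    def to_frame(self) -> "pd.DataFrame":
        return pd.DataFrame(
            {"bin_start_tss": self.bin_starts_tss(), "count": self.counts}
        )


def bin_positions(
    calls: Sequence, bin_width: int, length: int = 2000, anchor: str = "midpoint"
) -> BinProfile:
    """Histogram motif anchors into bins tiling the promoter (count-conserving)."""
    if length % bin_width != 0:
        raise ValueError("bin_width must tile the promoter length")
    nbins = length // bin_width
    counts = np.zeros(nbins, dtype=int)
    for c in calls:
        pos = anchor_position(c.interval, c.promoter_length, anchor=anchor)
        if not -length <= pos < 0:
            raise ValueError(f"anchor {pos} outside [-{length}, 0)")
        counts[(pos + length) // bin_width] += 1
    return BinProfile(bin_width=bin_width, length=length, counts=counts)


# ---------------------------------------------------------------------------
# Arrangement relative to CpG islands
# ---------------------------------------------------------------------------

def classify_vs_cgi(motif: Interval, cgis: Sequence[Interval]) -> str:
    """Relation of a motif to the promoter's CpG islands.

    overlapped: shares >= 1 base with any island; intervened: no overlap
    but islands lie wholly on both sides; upstream / downstream: 5' / 3'
    of every island; no_cgi: the promoter has no island.  Upstream means
    more distal (smaller coordinate).
    """
    if not cgis:
        return "no_cgi"
    if any(motif.overlaps(c) for c in cgis):
        return "overlapped"
    has_3prime = any(c.start >= motif.end for c in cgis)   # island toward TSS
    has_5prime = any(c.end <= motif.start for c in cgis)   # island distal side
    if has_5prime and has_3prime:
        return "intervened"
    return "upstream" if has_3prime else "downstream"


@dataclass(frozen=True)
class ArrangementRecord:
    gene_id: str
    motif_class: str    # "di-STR", "tri-STR", "tetra+-STR", "PQS"
    cgi_relation: str
    region: str
    start: int
    end: int


def _motif_class(call) -> str:
    if isinstance(call, StrCall):
        if call.period == 2:
            return "di-STR"
        if call.period == 3:
            return "tri-STR"
        return "tetra+-STR"
    if isinstance(call, PqsCall):
        return "PQS"
    raise TypeError(f"unsupported call type {type(call).__name__}")


def arrangement_records(
    str_calls: Sequence[StrCall],
    pqs_calls: Sequence[PqsCall],
    cgi_calls: Sequence[CgiCall],
    anchor: str = "midpoint",
) -> list[ArrangementRecord]:
    """Per-motif arrangement class and promoter region."""
    cgis_by_gene: dict[str, list[Interval]] = {}
    for c in cgi_calls:
        cgis_by_gene.setdefault(c.gene_id, []).append(c.interval)
    records: list[ArrangementRecord] = []
    for call in list(str_calls) + list(pqs_calls):
        rel = classify_vs_cgi(call.interval, cgis_by_gene.get(call.gene_id, []))
        pos = anchor_position(call.interval, call.promoter_length, anchor=anchor)
        records.append(
            ArrangementRecord(
                gene_id=call.gene_id, motif_class=_motif_class(call),
                cgi_relation=rel, region=region_of(pos, call.promoter_length),
                start=call.interval.start, end=call.interval.end,
            )
        )
    return records


def arrangement_table(
    records: Sequence[ArrangementRecord],
    classes: Sequence[str] = ("di-STR", "tri-STR", "PQS"),
    relations: Sequence[str] = ("upstream", "downstream", "overlapped", "intervened"),
) -> "pd.DataFrame":
    """Contingency table of cgi_relation x motif class (no_cgi rows excluded).

    Feeds :func:`promoscan.stats.fisher_exact_rxc` for the location-bias
    test between motif classes.
    """
    counts = pd.DataFrame(0, index=list(classes), columns=list(relations))
    for r in records:
        if r.motif_class in counts.index and r.cgi_relation in counts.columns:
            counts.loc[r.motif_class, r.cgi_relation] += 1
    return counts.loc[counts.sum(axis=1) > 0]


def trinucleotide_gc_positions(
    tri_calls: Sequence[StrCall], bin_width: int = 100, length: int = 2000,
    anchor: str = "midpoint",
) -> dict[str, BinProfile]:
    """100-bp-bin position profiles of trinucleotide repeats by GC class."""
    for c in tri_calls:
        if c.period != 3:
            raise ValueError("trinucleotide profiles require period-3 calls only")
    out: dict[str, BinProfile] = {}
    for klass in ("0%GC", "33%GC", "67%GC", "100%GC"):
        sub = [c for c in tri_calls if c.gc_class == klass]
        out[klass] = bin_positions(sub, bin_width, length=length, anchor=anchor)
    return out


def str_over_pqs_gene_sets(
    str_calls: Sequence[StrCall], pqs_calls: Sequence[PqsCall]
) -> tuple[set[str], set[str]]:
    """Gene sets for functional grouping under the STR-over-PQS rule.

    A locus called by both scanners (shared bases) counts as STR
    evidence only; a gene enters the PQS set iff it has at least one PQS
    locus not overlapped by any of its STR calls.  Returns
    (str_genes, pqs_genes).
    """
    str_by_gene: dict[str, list[Interval]] = {}
    for c in str_calls:
        str_by_gene.setdefault(c.gene_id, []).append(c.interval)
    str_genes = set(str_by_gene)
    pqs_genes: set[str] = set()
    for c in pqs_calls:
        if not any(c.interval.overlaps(iv) for iv in str_by_gene.get(c.gene_id, [])):
            pqs_genes.add(c.gene_id)
    return str_genes, pqs_genes


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------

def per_gene_counts(
    gene_ids: Sequence[str],
    str_calls: Sequence[StrCall],
    cgi_calls: Sequence[CgiCall],
    pqs_calls: Sequence[PqsCall],
) -> "pd.DataFrame":
    df = pd.DataFrame(0, index=list(gene_ids), columns=["STR", "CGI", "PQS"])
    for c in str_calls:
        df.loc[c.gene_id, "STR"] += 1
    for c in cgi_calls:
        df.loc[c.gene_id, "CGI"] += 1
    for c in pqs_calls:
        df.loc[c.gene_id, "PQS"] += 1
    df.index.name = "gene_id"
    return df


def cooccurrence_table(
    counts: "pd.DataFrame", motif_a: str, motif_b: str,
    bands: Sequence[int] = (0, 1),
) -> "pd.DataFrame":
    """Presence/absence of motif A x banded count of motif B.

    Default bands {0, 1, >=2} keep expected cell counts usable at modest
    sample sizes.  Rows: A absent / A present; columns: B count bands.
    """
    a = counts[motif_a] > 0
    labels = [str(b) for b in bands[:-1]] + [f"{bands[-1]}", f">={bands[-1] + 1}"]
    # bands (0,1) -> columns "0", "1", ">=2"
    b_band = np.digitize(counts[motif_b], bins=[x + 0.5 for x in bands])
    table = pd.DataFrame(0, index=[f"{motif_a}-absent", f"{motif_a}-present"],
                         columns=labels)
    for present, band in zip(a, b_band):
        table.iloc[int(present), int(band)] += 1
    table.columns.name = f"{motif_b}_count"
    return table
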