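"""CpG-island calling on promoter sequences.

Islands are defined by the three classical criteria evaluated with a
100-bp sliding window: G+C fraction above 50%, CpG observed/expected
ratio above 0.6 (O/E = N(CpG) * L / (N(C) * N(G))), and a minimum
length of 200 bp.  All thresholds are strict inequalities; boundary
values fail.

Algorithm.  Every 100-bp window (step 1) is scored for GC fraction and
CpG O/E.  Each sequence position is then assigned the mean GC and mean
O/E of all windows covering it, and candidate islands are maximal runs
of positions whose averaged GC and averaged O/E both exceed the
thresholds -- the per-position averaging keeps island edges within a few
bases of the underlying CG-rich block instead of bleeding a whole
window-width into the flanks.  Candidates are then trimmed 1 bp at a
time from whichever end sits in the locally weaker 10-bp context (fewer
C/G bases; ties trim the left end) until the whole reported span itself
satisfies GC > 0.5 and O/E > 0.6, and candidates shorter than 200 bp
are discarded.  An island whose right edge reaches the promoter end is
reported with ``truncated_at_tss`` set and its right edge is never
trimmed: the 3' boundary there is the TSS, not a compositional edge.

N bases count toward length but contribute nothing to the G, C, GC or
CpG counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .promoter_io import Interval, Promoter

log = logging.getLogger(__name__)

WINDOW_DEFAULT = 100
MIN_LEN_DEFAULT = 200
GC_MIN_DEFAULT = 0.5
OE_MIN_DEFAULT = 0.6
LCGI_THRESHOLD_DEFAULT = 800


def gc_fraction(window: str) -> float:
    """G+C fraction of a window; N counts toward length only."""
    if len(window) == 0:
        raise ValueError("empty window")
    return sum(c in "GC" for c in window) / len(window)


def cpg_oe(window: str) -> float:
    """CpG observed/expected ratio: N(CpG) * L / (N(C) * N(G)).

    Returns 0 when the window lacks C or G; any position involving N
    contributes to no count.
    """
    if len(window) < 2:
        raise ValueError("window must be at least 2 bp")
    n_c = window.count("C")
    n_g = window.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cpg = sum(
        1 for i in range(len(window) - 1) if window[i] == "C" and window[i + 1] == "G"
    )
    return n_cpg * len(window) / (n_c * n_g)


@dataclass(frozen=True)
class CgiCall:
    """One CpG island, with whole-span statistics on the reported interval."""

    gene_id: str
    interval: Interval
    gc_fraction: float
    cpg_oe: float
    truncated_at_tss: bool
    promoter_length: int

    def bed_name(self) -> str:
        suffix = ":truncated" if self.truncated_at_tss else ""
        return f"CGI:{len(self.interval)}{suffix}"

    def bed_score(self) -> int:
        return 0


def _span_stats(c_cum, g_cum, cg_cum, s: int, e: int) -> tuple[float, float]:
    length = e - s
    n_c = int(c_cum[e] - c_cum[s])
    n_g = int(g_cum[e] - g_cum[s])
    # CpG dinucleotides fully inside [s, e): pair positions s .. e-2
    n_cg = int(cg_cum[e - 1] - cg_cum[s]) if e - 1 > s else 0
    gc = (n_c + n_g) / length
    oe = (n_cg * length / (n_c * n_g)) if (n_c and n_g) else 0.0
    return gc, oe


def scan_cgis(
    p: Promoter,
    window: int = WINDOW_DEFAULT,
    min_len: int = MIN_LEN_DEFAULT,
    gc_min: float = GC_MIN_DEFAULT,
    oe_min: float = OE_MIN_DEFAULT,
) -> list[CgiCall]:
    """All CpG islands in one promoter, disjoint and sorted by start."""
    seq = p.seq
    L = len(seq)
    if L < window:
        log.warning("promoter %s shorter than window (%d < %d): no CGI scan",
                    p.gene_id, L, window)
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    is_c = (arr == b"C").astype(np.int64)
    is_g = (arr == b"G").astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)  # pair (i, i+1) == CG recorded at i
    if L >= 2:
        is_cg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")
    c_cum = np.concatenate(([0], np.cumsum(is_c)))
    g_cum = np.concatenate(([0], np.cumsum(is_g)))
    cg_cum = np.concatenate(([0], np.cumsum(is_cg)))

    n_win = L - window + 1
    idx = np.arange(n_win)
    win_c = c_cum[idx + window] - c_cum[idx]
    win_g = g_cum[idx + window] - g_cum[idx]
    win_cg = cg_cum[idx + window - 1] - cg_cum[idx]
    win_gc = (win_c + win_g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        win_oe = np.where(
            (win_c > 0) & (win_g > 0), win_cg * window / (win_c * win_g), 0.0
        )

    # per-position mean over covering windows: windows [i, i+window) cover
    # position p for i in [p-window+1, p] clipped to [0, n_win)
    wgc_cum = np.concatenate(([0.0], np.cumsum(win_gc)))
    woe_cum = np.concatenate(([0.0], np.cumsum(win_oe)))
    pos = np.arange(L)
    lo = np.clip(pos - window + 1, 0, n_win)
    hi = np.clip(pos + 1, 0, n_win)
    cover = hi - lo
    avg_gc = (wgc_cum[hi] - wgc_cum[lo]) / cover
    avg_oe = (woe_cum[hi] - woe_cum[lo]) / cover

    flagged = (avg_gc > gc_min) & (avg_oe > oe_min)
    d = np.diff(np.concatenate(([0], flagged.astype(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)

    calls: list[CgiCall] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        truncated = e == L
        s, e = _trim_span(seq, c_cum, g_cum, cg_cum, s, e, gc_min, oe_min,
                          min_len, fixed_right=truncated)
        if s is None or e - s < min_len:
            continue
        gc, oe = _span_stats(c_cum, g_cum, cg_cum, s, e)
        calls.append(
            CgiCall(gene_id=p.gene_id, interval=Interval(s, e), gc_fraction=gc,
                    cpg_oe=oe, truncated_at_tss=(e == L), promoter_length=L)
        )
    return calls


def _trim_span(seq, c_cum, g_cum, cg_cum, s, e, gc_min, oe_min, min_len,
               fixed_right=False):
    """Trim a candidate to a span passing whole-span criteria.

    Removes 1 bp at a time from the end whose terminal 10-bp context has
    fewer C/G bases (ties, or a TSS-fixed right edge, trim the left end)
    until the span passes or falls below min_len.
    """
    while e - s >= min_len:
        gc, oe = _span_stats(c_cum, g_cum, cg_cum, s, e)
        if gc > gc_min and oe > oe_min:
            return s, e
        if fixed_right:
            s += 1
            continue
        left_ctx = seq[s : min(s + 10, e)]
        right_ctx = seq[max(e - 10, s) : e]
        left_cg = sum(c in "GC" for c in left_ctx)
        right_cg = sum(c in "GC" for c in right_ctx)
        if left_cg <= right_cg:
            s += 1
        else:
            e -= 1
    return None, None


def scan_many(promoters: Iterable[Promoter], **kwargs) -> list[CgiCall]:
    out: list[CgiCall] = []
    for p in promoters:
        out.extend(scan_cgis(p, **kwargs))
    return out


@dataclass(frozen=True)
class PromoterCgiClass:
    """LCGI / NCGI / other label with the total island length behind it."""

    gene_id: str
    label: str  # "LCGI", "NCGI", or "other"
    total_cgi_length: int
    n_islands: int


def classify_cgi_promoters(
    promoters: Sequence[Promoter],
    calls: Sequence[CgiCall],
    lcgi_threshold: int = LCGI_THRESHOLD_DEFAULT,
) -> tuple[dict[str, PromoterCgiClass], float]:
    """Per-gene LCGI/NCGI classification.

    A promoter is NCGI when it has no island and LCGI when its summed
    island length strictly exceeds ``lcgi_threshold`` (default 800 bp,
    historically the top-decile cut on chicken promoters).  Also returns
    the empirical quantile of the threshold among island-bearing
    promoters so a top-X% framing can be reproduced on any dataset.
    """
    totals: dict[str, int] = {p.gene_id: 0 for p in promoters}
    n_isl: dict[str, int] = {p.gene_id: 0 for p in promoters}
    for c in calls:
        if c.gene_id not in totals:
            raise KeyError(f"call references unknown gene {c.gene_id!r}")
        totals[c.gene_id] += len(c.interval)
        n_isl[c.gene_id] += 1
    classes: dict[str, PromoterCgiClass] = {}
    for gid, tot in totals.items():
        if n_isl[gid] == 0:
            label = "NCGI"
        elif tot > lcgi_threshold:
            label = "LCGI"
        else:
            label = "other"
        classes[gid] = PromoterCgiClass(gene_id=gid, label=label,
                                        total_cgi_length=tot,
                                        n_islands=n_isl[gid])
    with_cgi = np.array([t for g, t in totals.items() if n_isl[g] > 0])
    quantile = float(np.mean(with_cgi <= lcgi_threshold)) if len(with_cgi) else float("nan")
    return classes, quantile


def calls_frame(calls: Sequence[CgiCall]) -> "pd.DataFrame":
    return pd.DataFrame(
        [{"gene_id": c.gene_id, "start": c.interval.start, "end": c.interval.end,
          "length": len(c.interval), "gc_fraction": c.gc_fraction,
          "cpg_oe": c.cpg_oe, "truncated_at_tss": c.truncated_at_tss}
         for c in calls]
    )
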