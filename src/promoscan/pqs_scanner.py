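"""Potential G-quadruplex sequence (PQS) detection.

A PQS candidate is four ordered, non-overlapping guanine tracts, each of
at least four consecutive G ("tetrad" = number of stacked G-quartets =
length of the shortest tract as used), separated by loops of length >= 0,
the whole placement spanning at most 30 nt.  A longer physical G-run may
contribute a shorter used tract at any offset inside it.  Placements
whose spanned sequence is undisrupted poly-G (which includes every
placement with all three loops zero) fold no loop structure and are
excluded.

Overlap resolution keeps one call per region: candidates are ranked by
(1) larger tetrad, (2) smaller loop-length variance, (3) smaller span,
(4) leftmost start, and kept greedily when base-disjoint from every
already-kept call.  This deterministic rank replaces proprietary
G-scoring schemes; downstream analysis uses only presence and position.

Only the given strand is scanned by default (G-rich strand); set
``both_strands=True`` in :func:`scan_pqs` to also scan the reverse
complement (hits reported on forward coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .promoter_io import Interval, Promoter, revcomp

MAX_SPAN_DEFAULT = 30
MIN_TETRAD_DEFAULT = 4
MIN_LOOP_DEFAULT = 0


@dataclass(frozen=True)
class PqsCall:
    """One (candidate or retained) G-quadruplex motif placement."""

    gene_id: str
    interval: Interval
    tetrad: int
    run_starts: tuple[int, int, int, int]
    run_lengths: tuple[int, int, int, int]
    loops: tuple[int, int, int]
    promoter_length: int
    strand: str = "+"

    def bed_name(self) -> str:
        return f"PQS:t{self.tetrad}:l{'-'.join(map(str, self.loops))}"

    def bed_score(self) -> int:
        return self.tetrad

    def loop_variance(self) -> float:
        m = sum(self.loops) / 3.0
        return sum((l - m) ** 2 for l in self.loops) / 3.0


def _g_runs(seq: str, min_tetrad: int) -> list[tuple[int, int]]:
    """(start, length) of maximal G-runs of length >= min_tetrad."""
    runs: list[tuple[int, int]] = []
    i = 0
    L = len(seq)
    while i < L:
        if seq[i] == "G":
            j = i
            while j < L and seq[j] == "G":
                j += 1
            if j - i >= min_tetrad:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def enumerate_candidates(
    p: Promoter,
    max_span: int = MAX_SPAN_DEFAULT,
    min_tetrad: int = MIN_TETRAD_DEFAULT,
    min_loop: int = MIN_LOOP_DEFAULT,
) -> list[PqsCall]:
    """All four-tract placements satisfying the span/tetrad/loop constraints.

    Poly-G placements (all three loops zero) are removed.  Candidates are
    returned sorted by (start, span).
    """
    seq = p.seq
    L = len(seq)
    runs = _g_runs(seq, min_tetrad)
    # max consecutive-G extent starting at each G position, per physical run
    cands: list[PqsCall] = []

    # used tracts: (abs_start, length) with abs_start inside a physical run
    # and abs_start+length within it
    starts_avail: list[tuple[int, int]] = []  # (tract_start, max_len_from_here)
    for rs, rl in runs:
        for off in range(rl - min_tetrad + 1):
            starts_avail.append((rs + off, rl - off))
    starts_avail.sort()
    abs_starts = [s for s, _ in starts_avail]

    import bisect

    def extend(chosen: list[tuple[int, int]]) -> None:
        first_start = chosen[0][0]
        last_end = chosen[-1][0] + chosen[-1][1]
        if len(chosen) == 4:
            span = last_end - first_start
            loops = tuple(
                chosen[i + 1][0] - (chosen[i][0] + chosen[i][1]) for i in range(3)
            )
            # undisrupted poly-G: the spanned sequence is all G (in
            # particular every placement with all three loops zero)
            if all(c == "G" for c in seq[first_start:last_end]):
                return
            tetrad = min(l for _, l in chosen)
            cands.append(
                PqsCall(
                    gene_id=p.gene_id,
                    interval=Interval(first_start, last_end),
                    tetrad=tetrad,
                    run_starts=tuple(s for s, _ in chosen),
                    run_lengths=tuple(l for _, l in chosen),
                    loops=loops,
                    promoter_length=L,
                )
            )
            return
        lo = bisect.bisect_left(abs_starts, last_end + min_loop)
        budget_end = first_start + max_span
        for k in range(lo, len(abs_starts)):
            s, avail = starts_avail[k]
            if s + min_tetrad > budget_end:
                break
            max_t = min(avail, budget_end - s)
            for t in range(min_tetrad, max_t + 1):
                extend(chosen + [(s, t)])

    for s0, avail0 in starts_avail:
        for t0 in range(min_tetrad, min(avail0, max_span) + 1):
            extend([(s0, t0)])

    cands.sort(key=lambda c: (c.interval.start, len(c.interval)))
    return cands


def resolve_overlaps(candidates: Sequence[PqsCall]) -> list[PqsCall]:
    """Greedy disjoint selection by deterministic rank.

    Rank: larger tetrad, then smaller loop variance, then smaller span,
    then leftmost start.  A candidate is kept iff it shares no base with
    an already-kept call.  Output sorted by start.
    """
    ranked = sorted(
        candidates,
        key=lambda c: (-c.tetrad, c.loop_variance(), len(c.interval),
                       c.interval.start),
    )
    kept: list[PqsCall] = []
    for c in ranked:
        if all(not c.interval.overlaps(k.interval) for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.interval.start)
    return kept


def scan_pqs(
    p: Promoter,
    max_span: int = MAX_SPAN_DEFAULT,
    min_tetrad: int = MIN_TETRAD_DEFAULT,
    min_loop: int = MIN_LOOP_DEFAULT,
    both_strands: bool = False,
) -> list[PqsCall]:
    """Retained (overlap-resolved) PQS calls for one promoter."""
    calls = resolve_overlaps(
        enumerate_candidates(p, max_span=max_span, min_tetrad=min_tetrad,
                             min_loop=min_loop)
    )
    if both_strands:
        rc = Promoter(gene_id=p.gene_id, seq=revcomp(p.seq), species=p.species)
        L = len(p.seq)
        minus = []
        for c in resolve_overlaps(
            enumerate_candidates(rc, max_span=max_span, min_tetrad=min_tetrad,
                                 min_loop=min_loop)
        ):
            iv = Interval(L - c.interval.end, L - c.interval.start)
            minus.append(
                PqsCall(gene_id=c.gene_id, interval=iv, tetrad=c.tetrad,
                        run_starts=c.run_starts, run_lengths=c.run_lengths,
                        loops=c.loops, promoter_length=L, strand="-")
            )
        calls = sorted(calls + minus, key=lambda c: c.interval.start)
    return calls


def scan_many(promoters: Iterable[Promoter], **kwargs) -> list[PqsCall]:
    out: list[PqsCall] = []
    for p in promoters:
        out.extend(scan_pqs(p, **kwargs))
    return out


def pqs_presence(calls: Sequence[PqsCall], gene_ids: Iterable[str]) -> "pd.DataFrame":
    """Per-gene PQS count and presence flag over a fixed gene universe."""
    counts: dict[str, int] = {g: 0 for g in gene_ids}
    for c in calls:
        counts[c.gene_id] = counts.get(c.gene_id, 0) + 1
    return pd.DataFrame(
        {"gene_id": list(counts), "pqs_count": list(counts.values()),
         "pqs_present": [v > 0 for v in counts.values()]}
    )


def calls_frame(calls: Sequence[PqsCall]) -> "pd.DataFrame":
    return pd.DataFrame(
        [{"gene_id": c.gene_id, "start": c.interval.start, "end": c.interval.end,
          "tetrad": c.tetrad, "loops": ",".join(map(str, c.loops)),
          "strand": c.strand} for c in calls]
    )
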