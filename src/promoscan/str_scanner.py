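"""Perfect short tandem repeat (STR / microsatellite) detection.

Scans promoters for perfect tandem repeats of primitive 2-6 bp units with
at least six complete units, and canonicalizes each repeat unit into a
motif family (lexicographic minimum over all cyclic rotations of the unit
and of its reverse complement), so e.g. GT, TG, CA and AC all report as
the AC family.  Mononucleotide runs are never called: a run of one base
has a non-primitive unit at every period >= 2.

Scanning semantics (fixed, deterministic):

* a run is reported once, anchored at its leftmost full unit, at its
  primitive period only -- (AG)12 is a single period-2 call, never also a
  period-4 (AGAG)6 call;
* trailing partial units are excluded; the reported interval is exactly
  ``units * period`` bases;
* N acts as a universal mismatch, breaking runs;
* when two runs would share bases (adjacent runs of different motifs, or
  phase-shifted continuations), the left run is extended greedily first
  and the right run is trimmed to start where the left one's reported
  interval ends, then re-checked against the minimum unit count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .promoter_io import Interval, Promoter, revcomp
from .stats import FrequencyTable

MIN_UNITS_DEFAULT = 6
PERIODS_DEFAULT = (2, 3, 4, 5, 6)

#: GC classes for trinucleotide repeat units, keyed by the number of G/C
#: bases in the unit.
GC_CLASSES = {0: "0%GC", 1: "33%GC", 2: "67%GC", 3: "100%GC"}


def is_primitive(unit: str) -> bool:
    """True if ``unit`` is not a whole-number repetition of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonicalize(motif: str) -> str:
    """Family representative of a repeat unit.

    Returns the lexicographically smallest string among all cyclic
    rotations of ``motif`` and all cyclic rotations of its reverse
    complement.  Idempotent; invariant under rotation and strand flip of
    the input.
    """
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"unit length must be 2-6, got {motif!r}")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"unit must be over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"unit must be primitive, got {motif!r}")
    n = len(motif)
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(n)]
    candidates += [rc[i:] + rc[:i] for i in range(n)]
    return min(candidates)


def unit_gc_class(unit: str) -> str:
    """0/33/67/100%GC class of a trinucleotide unit (rotation/strand invariant)."""
    if len(unit) != 3:
        raise ValueError("GC classes are defined for trinucleotide units only")
    return GC_CLASSES[sum(c in "GC" for c in unit)]


@dataclass(frozen=True)
class StrCall:
    """One perfect tandem repeat call."""

    gene_id: str
    interval: Interval
    period: int
    units: int
    observed_motif: str
    canonical_motif: str
    promoter_length: int
    gc_class: str | None = None  # period-3 calls only

    def bed_name(self) -> str:
        return f"STR:{self.canonical_motif}:{self.units}"

    def bed_score(self) -> int:
        return 0


def scan_strs(
    p: Promoter,
    min_units: int = MIN_UNITS_DEFAULT,
    periods: Sequence[int] = PERIODS_DEFAULT,
) -> list[StrCall]:
    """All perfect STR calls in one promoter, sorted by start."""
    seq = p.seq
    L = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    notN = arr != b"N"

    # Raw maximal periodic runs: for period per, m[j] marks seq[j]==seq[j+per]
    # (N never matches).  A maximal True-run [i, i+r) means seq[i, i+r+per)
    # is per-periodic and cannot be extended left or right.
    raw: list[tuple[int, int, int]] = []  # (start, period, raw_end)
    for per in sorted(periods):
        if L < per * min_units:
            continue
        m = (arr[:-per] == arr[per:]) & notN[:-per] & notN[per:]
        mi = m.astype(np.int8)
        d = np.diff(np.concatenate(([0], mi, [0])))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for i, j in zip(starts, ends):
            extent = (j - i) + per  # periodic stretch length in bases
            if extent // per >= min_units:
                raw.append((int(i), per, int(i) + extent))

    raw.sort(key=lambda t: (t[0], t[1]))
    calls: list[StrCall] = []
    occupied_end = 0
    for start, per, raw_end in raw:
        s = int(max(start, occupied_end))
        units = int((raw_end - s) // per)
        if units < min_units:
            continue
        unit = seq[s : s + per]
        if not is_primitive(unit):
            continue  # reported at its primitive period instead
        end = s + units * per
        calls.append(
            StrCall(
                gene_id=p.gene_id,
                interval=Interval(s, end),
                period=per,
                units=units,
                observed_motif=unit,
                canonical_motif=canonicalize(unit),
                promoter_length=L,
                gc_class=unit_gc_class(unit) if per == 3 else None,
            )
        )
        occupied_end = max(occupied_end, end)
    calls.sort(key=lambda c: (c.interval.start, c.period))
    return calls


def scan_many(
    promoters: Iterable[Promoter],
    min_units: int = MIN_UNITS_DEFAULT,
    periods: Sequence[int] = PERIODS_DEFAULT,
) -> list[StrCall]:
    out: list[StrCall] = []
    for p in promoters:
        out.extend(scan_strs(p, min_units=min_units, periods=periods))
    return out


def frequency_table(calls: Sequence[StrCall], n_promoters: int) -> FrequencyTable:
    """Canonical-motif frequency table (count, percent, STRs per sequence)."""
    if n_promoters < 1:
        raise ValueError("n_promoters must be >= 1")
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.canonical_motif] = counts.get(c.canonical_motif, 0) + 1
    return FrequencyTable.from_counts(counts, n_promoters=n_promoters)


@dataclass
class UnitCountSummary:
    """Per-period unit-count means and the di- vs tetra+ contrast samples.

    ``mean_units[per]`` is None when no call of that period exists (flagged
    as undefined rather than silently zero).  ``di_units`` and
    ``tetra_plus_units`` are the two raw samples (periods {2} vs {4,5,6},
    the "tetranucleotide" grouping) for a rank test downstream.
    """

    mean_units: dict[int, float | None]
    n_calls: dict[int, int]
    di_units: list[int]
    tetra_plus_units: list[int]


def unit_count_summary(calls: Sequence[StrCall]) -> UnitCountSummary:
    by_period: dict[int, list[int]] = {per: [] for per in PERIODS_DEFAULT}
    for c in calls:
        by_period.setdefault(c.period, []).append(c.units)
    mean_units = {
        per: (sum(u) / len(u) if u else None) for per, u in sorted(by_period.items())
    }
    n_calls = {per: len(u) for per, u in sorted(by_period.items())}
    di = list(by_period.get(2, []))
    tetra = [u for per in (4, 5, 6) for u in by_period.get(per, [])]
    return UnitCountSummary(
        mean_units=mean_units, n_calls=n_calls, di_units=di, tetra_plus_units=tetra
    )
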