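"""Seeded synthetic promoter generator with ground truth.

Emulates the statistical structure the promoter-motif analysis assumes,
so every pipeline stage is testable without genome downloads:

* a 2,000-bp background whose GC fraction rises linearly toward the TSS
  (defaults 0.48 -> 0.57), generated by a first-order chain that
  depletes CpG dinucleotides (vertebrate methylation-deamination
  background, default observed/expected ~ 0.25) while preserving the
  per-position base composition exactly in expectation;
* planted perfect STRs drawn from a configurable motif-frequency table
  (default: the packaged chicken promoter counts), with unit counts
  drawn per period class;
* planted CG-rich islands with target GC and CpG O/E, re-drawn until the
  realized segment satisfies the island-calling criteria on its own span;
* planted four-tract G4 blocks (loops 1-3 nt) and a TATA box at a fixed
  TSS-relative position in a configurable fraction of promoters;
* a gene -> GO-term annotation table with configurable log-odds
  enrichment planted in the motif-bearing gene groups.

Planted elements replace background bases (total length stays fixed) at
uniform-random non-overlapping positions, and each STR/PQS element is
flanked by 1-bp guard bases chosen so the background cannot silently
extend the planted motif.  All randomness flows from one seeded
generator stream, so a fixed seed reproduces the output byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .promoter_io import Promoter
from .reference import chicken_motif_distribution

_CODE2CHAR = np.array([b"A", b"C", b"G", b"T"], dtype="S1")

GROUP_NAMES = ("PQS", "STR", "LCGI", "NCGI")


def _default_motif_distribution() -> dict[str, float]:
    return chicken_motif_distribution()


def _default_unit_ranges() -> dict[int, tuple[int, int]]:
    # inclusive ranges; tetra+ repeats run longer than di, di longer than
    # tri -- the avian pattern the generator emulates
    return {2: (6, 9), 3: (6, 7), 4: (6, 12), 5: (6, 12), 6: (6, 12)}


def _default_planted_or() -> dict[str, dict[str, float]]:
    return {
        "PQS": {"T000": 5.0},
        "STR": {"T001": 5.0},
        "LCGI": {"T002": 5.0},
        "NCGI": {"T003": 5.0},
    }


@dataclass
class GeneratorConfig:
    n_promoters: int = 1000
    length: int = 2000
    seed: int = 0
    # background
    gc_start: float = 0.48
    gc_end: float = 0.57
    background_cpg_depletion: float = 0.25  # background CpG O/E target
    # TATA box
    tata_position: int = -31
    tata_rate: float = 0.10
    tata_sequence: str = "TATAAAA"  # one concrete realization of TATAWAW
    # STRs
    str_rate_per_promoter: float = 0.114
    str_motif_distribution: dict[str, float] = field(
        default_factory=_default_motif_distribution
    )
    str_unit_ranges: dict[int, tuple[int, int]] = field(
        default_factory=_default_unit_ranges
    )
    # CpG islands
    cgi_rate: float = 0.583
    cgi_length_range: tuple[int, int] = (200, 900)
    cgi_gc: float = 0.65
    cgi_oe_target: float = 1.2
    lcgi_threshold: int = 800
    # G4 blocks
    pqs_rate: float = 0.078
    pqs_run_length: int = 4
    pqs_loop_range: tuple[int, int] = (1, 3)
    # GO annotations
    n_go_terms: int = 50
    term_prevalence: float = 0.10
    planted_odds_ratios: dict[str, dict[str, float]] = field(
        default_factory=_default_planted_or
    )

    def validate(self) -> None:
        for name in ("tata_rate", "str_rate_per_promoter", "cgi_rate",
                     "pqs_rate", "term_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        psum = sum(self.str_motif_distribution.values())
        if self.str_motif_distribution and abs(psum - 1.0) > 1e-6:
            raise ValueError(f"str_motif_distribution sums to {psum}, not 1")
        if not 0 < self.background_cpg_depletion <= 1.0:
            raise ValueError("background_cpg_depletion must be in (0, 1]")
        if self.cgi_length_range[0] < 200:
            raise ValueError("planted islands must be at least 200 bp")
        if not -self.length <= self.tata_position < 0:
            raise ValueError("tata_position must be TSS-relative negative")


def zeroed(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of a config with every planting rate set to zero (pure background)."""
    import dataclasses

    return dataclasses.replace(
        config, tata_rate=0.0, str_rate_per_promoter=0.0, cgi_rate=0.0,
        pqs_rate=0.0,
    )


# ---------------------------------------------------------------------------
# background chain
# ---------------------------------------------------------------------------

def _background_matrix(
    rng: np.random.Generator, n: int, L: int, gc: np.ndarray, depletion: float
) -> np.ndarray:
    """(n, L) base codes from the CpG-depleted gradient chain.

    The G emission probability after a C is scaled by ``depletion``; after
    any other base it is raised to compensate, so the marginal composition
    at every position stays (pA, pC, pG, pT) = ((1-gc)/2, gc/2, gc/2,
    (1-gc)/2) exactly in expectation.
    """
    codes = np.empty((n, L), dtype=np.int8)
    pC0 = gc[0] / 2.0
    u = rng.random(n)
    pa = (1 - gc[0]) / 2.0
    codes[:, 0] = (u >= pa).astype(np.int8) + (u >= pa + pC0) + (u >= pa + 2 * pC0)
    for x in range(1, L):
        pG = gc[x] / 2.0
        pC = gc[x] / 2.0
        pC_prev = gc[x - 1] / 2.0
        pG_after_C = depletion * pG
        pG_other = pG * (1.0 - pC_prev * depletion) / (1.0 - pC_prev)
        prev_is_c = codes[:, x - 1] == 1
        pg = np.where(prev_is_c, pG_after_C, pG_other)
        pa = (1.0 - pC - pg) / 2.0
        u = rng.random(n)
        codes[:, x] = (
            (u >= pa).astype(np.int8) + (u >= pa + pC) + (u >= pa + pC + pg)
        )
    return codes


def _segment(
    rng: np.random.Generator, length: int, gc: float, oe_factor: float,
) -> np.ndarray:
    """Base codes for a planted CG-rich segment with target GC and CpG O/E."""
    pC = pG = gc / 2.0
    pG_after_C = min(oe_factor * pG, 0.95 * (1.0 - pC))
    pG_other = max(pG * (1.0 - pC * oe_factor) / (1.0 - pC), 0.0)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    prev_c = False
    for i in range(length):
        pg = pG_after_C if prev_c else pG_other
        pa = (1.0 - pC - pg) / 2.0
        ui = u[i]
        c = 0 if ui < pa else (1 if ui < pa + pC else (2 if ui < pa + pC + pg else 3))
        out[i] = c
        prev_c = c == 1
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _CODE2CHAR[codes].tobytes().decode("ascii")


def _segment_passes_cgi(seg: str) -> bool:
    """Accept a planted island only if it is cleanly callable in isolation.

    The island scanner, run on the bare segment, must report exactly one
    island covering >= 95% of it.  This rejects segments whose realized
    composition is marginal or whose interior dips below the calling
    criteria, so planted truth is unambiguous.
    """
    from .cgi_scanner import scan_cgis
    from .promoter_io import Promoter as _P

    calls = scan_cgis(_P(gene_id="_seg", seq=seg))
    if len(calls) != 1:
        return False
    return len(calls[0].interval) >= 0.95 * len(seg)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    span: int,
    L: int,
    lo: int = 1,
) -> int:
    """Uniform-random non-overlapping start for a span (guards included)."""
    hi = L - 1 - span
    if hi < lo:
        raise ValueError("planted element does not fit; lower rates or lengths")
    for _ in range(500):
        s = int(rng.integers(lo, hi + 1))
        if all(s + span <= a or s >= b for a, b in occupied):
            occupied.append((s, s + span))
            return s
    raise ValueError(
        "could not place planted elements without overlap; lower rates/lengths"
    )


def _suppress_flanking_g_runs(
    row: np.ndarray, start: int, end: int, occupied: list[tuple[int, int]],
    flank: int = 30,
) -> None:
    """Break background G-runs >= 4 within ``flank`` bp of a planted G4 block.

    A chance G-tract just outside the block would offer the scanner an
    alternative four-tract placement, so the generator owns the local
    context and disrupts such runs (middle base -> A), never touching
    other planted elements.
    """
    L = len(row)
    for lo, hi in ((max(0, start - flank), start), (end, min(L, end + flank))):
        i = lo
        while i < hi:
            if row[i] == 2:
                j = i
                while j < hi and row[j] == 2:
                    j += 1
                if j - i >= 4:
                    mid = (i + j) // 2
                    if all(mid < a or mid >= b for a, b in occupied):
                        row[mid] = 0
                i = j
            else:
                i += 1


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(
    config: GeneratorConfig,
) -> tuple[list[Promoter], "pd.DataFrame", "pd.DataFrame"]:
    """Generate (promoters, truth table, GO annotations).

    The truth table has one row per planted element (gene_id, kind, start,
    end plus kind-specific columns); the annotation table has one
    (gene_id, term_id) row per assigned term.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, L = config.n_promoters, config.length
    gc = np.linspace(config.gc_start, config.gc_end, L)
    codes = _background_matrix(rng, n, L, gc, config.background_cpg_depletion)

    motifs = list(config.str_motif_distribution)
    motif_p = np.array([config.str_motif_distribution[m] for m in motifs])

    truth_rows: list[dict] = []
    gene_ids = [f"g{i:05d}" for i in range(n)]
    for i, gid in enumerate(gene_ids):
        row = codes[i]
        occupied: list[tuple[int, int]] = []

        plant_tata = rng.random() < config.tata_rate
        plant_str = rng.random() < config.str_rate_per_promoter
        plant_cgi = rng.random() < config.cgi_rate
        plant_pqs = rng.random() < config.pqs_rate

        if plant_tata:
            s = L + config.tata_position
            tata = config.tata_sequence
            occupied.append((s, s + len(tata)))
            row[s : s + len(tata)] = [_CODE[c] for c in tata]
            truth_rows.append(
                {"gene_id": gid, "kind": "TATA", "start": s, "end": s + len(tata)}
            )

        if plant_cgi:
            lo, hi = config.cgi_length_range
            clen = int(rng.integers(lo, hi + 1))
            s = _place(rng, occupied, clen, L, lo=0)
            for _ in range(20):
                seg = _segment(rng, clen, config.cgi_gc, config.cgi_oe_target)
                if _segment_passes_cgi(_codes_to_str(seg)):
                    break
            else:
                raise RuntimeError("planted island never satisfied criteria")
            row[s : s + clen] = seg
            seg_s = _codes_to_str(seg)
            truth_rows.append(
                {"gene_id": gid, "kind": "CGI", "start": s, "end": s + clen,
                 "cgi_len": clen}
            )

        if plant_str:
            motif = str(rng.choice(motifs, p=motif_p))
            per = len(motif)
            ulo, uhi = config.str_unit_ranges[per]
            units = int(rng.integers(ulo, uhi + 1))
            slen = per * units
            s = _place(rng, occupied, slen + 2, L) + 1  # +2 for guard bases
            row[s : s + slen] = [_CODE[c] for c in motif] * units
            # guards: background must not extend the planted run
            left_block = _CODE[motif[per - 1]]
            right_block = _CODE[motif[0]]
            row[s - 1] = int(rng.choice([c for c in range(4) if c != left_block]))
            row[s + slen] = int(rng.choice([c for c in range(4) if c != right_block]))
            truth_rows.append(
                {"gene_id": gid, "kind": "STR", "start": s, "end": s + slen,
                 "motif": motif, "period": per, "units": units}
            )

        if plant_pqs:
            t = config.pqs_run_length
            loops = [int(rng.integers(config.pqs_loop_range[0],
                                      config.pqs_loop_range[1] + 1))
                     for _ in range(3)]
            loop_bases = [
                [int(rng.choice([0, 1, 3])) for _ in range(l)] for l in loops
            ]  # loops avoid G so tracts stay exact
            block: list[int] = []
            for k in range(4):
                block += [2] * t
                if k < 3:
                    block += loop_bases[k]
            blen = len(block)
            s = _place(rng, occupied, blen + 2, L) + 1
            row[s : s + blen] = block
            row[s - 1] = int(rng.choice([0, 1, 3]))
            row[s + blen] = int(rng.choice([0, 1, 3]))
            _suppress_flanking_g_runs(row, s, s + blen, occupied)
            truth_rows.append(
                {"gene_id": gid, "kind": "PQS", "start": s, "end": s + blen,
                 "loops": ",".join(map(str, loops))}
            )

    promoters = [
        Promoter(gene_id=gid, seq=_codes_to_str(codes[i]), species="synthetic")
        for i, gid in enumerate(gene_ids)
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "kind", "start", "end", "motif", "period", "units",
                 "cgi_len", "loops"],
    )
    groups = truth_groups(truth, gene_ids, lcgi_threshold=config.lcgi_threshold)
    annotations = generate_annotations(rng, gene_ids, groups, config)
    return promoters, truth, annotations


def truth_groups(
    truth: "pd.DataFrame", gene_ids: Sequence[str], lcgi_threshold: int = 800
) -> dict[str, set[str]]:
    """The four planted motif groups implied by a truth table."""
    if len(truth):
        str_genes = set(truth.loc[truth["kind"] == "STR", "gene_id"])
        pqs_genes = set(truth.loc[truth["kind"] == "PQS", "gene_id"])
        cgi = truth[truth["kind"] == "CGI"].copy()
        cgi_total = cgi.assign(l=cgi["end"] - cgi["start"]).groupby("gene_id")["l"].sum()
        lcgi_genes = set(cgi_total[cgi_total > lcgi_threshold].index)
        cgi_genes = set(cgi["gene_id"])
    else:
        str_genes = pqs_genes = lcgi_genes = cgi_genes = set()
    ncgi_genes = set(gene_ids) - cgi_genes
    return {"PQS": pqs_genes, "STR": str_genes, "LCGI": lcgi_genes,
            "NCGI": ncgi_genes}


def generate_annotations(
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    groups: Mapping[str, set[str]],
    config: GeneratorConfig,
) -> "pd.DataFrame":
    """Draw a gene -> GO-term table with planted group enrichment.

    Each term has base prevalence ``term_prevalence``; for a gene inside
    a group with a planted odds ratio for a term, the assignment odds are
    multiplied by that ratio.
    """
    terms = [f"T{j:03d}" for j in range(config.n_go_terms)]
    base = config.term_prevalence
    base_odds = base / (1.0 - base)
    n, T = len(gene_ids), len(terms)
    probs = np.full((n, T), base)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for gname, planted in config.planted_odds_ratios.items():
        members = [gidx[g] for g in groups.get(gname, set()) if g in gidx]
        for term, oratio in planted.items():
            if term not in terms:
                raise ValueError(f"planted term {term} outside go term universe")
            j = terms.index(term)
            odds = base_odds * oratio
            probs[members, j] = odds / (1.0 + odds)
    draws = rng.random((n, T)) < probs
    gi, tj = np.nonzero(draws)
    return pd.DataFrame(
        {"gene_id": [gene_ids[i] for i in gi], "term_id": [terms[j] for j in tj]}
    )


# ---------------------------------------------------------------------------
# background rates
# ---------------------------------------------------------------------------

def background_rates(
    config: GeneratorConfig,
) -> dict[str, tuple[float, tuple[float, float]]]:
    """Per-scanner mean calls/promoter on pure background, with 95% CIs.

    Runs the generator with all planting rates zeroed and each scanner
    over the result.  These rates are the subtrahend for planted-rate
    recovery: random sequence spawns spurious calls that must not be
    attributed to planting.
    """
    from . import cgi_scanner, consensus_scanner, pqs_scanner, str_scanner

    promoters, _, _ = generate(zeroed(config))
    n = len(promoters)
    per_scanner = {
        "STR": np.array([len(str_scanner.scan_strs(p)) for p in promoters]),
        "CGI": np.array([len(cgi_scanner.scan_cgis(p)) for p in promoters]),
        "PQS": np.array([len(pqs_scanner.scan_pqs(p)) for p in promoters]),
        "TATA": np.array(
            [len(consensus_scanner.scan_iupac(p, consensus_scanner.TATA_PATTERN,
                                              "TATA", both_strands=False))
             for p in promoters]
        ),
    }
    out = {}
    for name, counts in per_scanner.items():
        mean = float(counts.mean())
        se = float(counts.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        out[name] = (mean, (mean - 1.96 * se, mean + 1.96 * se))
    return out
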