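"""Comparative and enrichment statistics for motif-frequency tables and gene sets.

Covers the statistical layer of the promoter-motif analysis: motif
frequency-table comparison across species (minor-motif pruning, Pearson/
Spearman r, Kendall tau-b), Mann-Whitney U with a tie-corrected normal z,
Fisher's exact test on 2x2 and r x c tables, and Fisher-exact GO-term
over-representation with the raw p < 0.01 convention (Benjamini-Hochberg
q-values are emitted as a clearly optional extra column).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# Frequency tables (the unit of cross-species comparison)
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Canonical motif -> count table with derived percentages.

    ``freq_percent`` is 100 * count / total; ``str_per_seq`` is
    total / n_promoters when the number of scanned promoters is known.
    """

    counts: "pd.Series"  # index: canonical motif (str), values: int counts
    n_promoters: int | None = None

    def __post_init__(self) -> None:
        self.counts = pd.Series(self.counts).astype(int)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate motifs in frequency table")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], n_promoters: int | None = None
    ) -> "FrequencyTable":
        s = pd.Series(dict(counts), dtype=int).sort_values(ascending=False)
        # deterministic: count desc, then motif alphabetical
        s = s.iloc[np.lexsort((s.index.to_numpy(), -s.to_numpy()))]
        return cls(counts=s, n_promoters=n_promoters)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        motif_col: str = "motif",
        count_col: str = "count",
        n_promoters: int | None = None,
    ) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t")
        return cls.from_counts(
            dict(zip(df[motif_col], df[count_col])), n_promoters=n_promoters
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def freq_percent(self) -> "pd.Series":
        total = self.total
        if total == 0:
            return self.counts.astype(float)
        return 100.0 * self.counts / total

    @property
    def str_per_seq(self) -> float:
        if self.n_promoters is None:
            raise ValueError("n_promoters not set")
        return self.total / self.n_promoters

    def to_frame(self) -> "pd.DataFrame":
        return pd.DataFrame(
            {"motif": self.counts.index, "count": self.counts.to_numpy(),
             "freq_percent": self.freq_percent.to_numpy()}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def prune_minor_motifs(
    ref: FrequencyTable, others: Mapping[str, FrequencyTable] | None = None,
    fraction: float = 0.10,
) -> tuple[list[str], np.ndarray, dict[str, np.ndarray]]:
    """Drop the bottom ``fraction`` of minor motifs by reference count.

    Motifs are ranked by reference count descending (ties broken
    alphabetically so the pruning is deterministic); the lowest
    ``floor(fraction * m)`` motifs are removed.  The remaining motifs are
    aligned across all tables; a motif absent from another table
    contributes a zero there.
    """
    if len(ref.counts) == 0:
        raise ValueError("reference table is empty")
    m = len(ref.counts)
    n_drop = int(math.floor(fraction * m))
    order = sorted(ref.counts.index, key=lambda mo: (-int(ref.counts[mo]), mo))
    keep = order[: m - n_drop] if n_drop else order
    if not keep:
        raise ValueError("all motifs pruned")
    ref_vec = np.array([int(ref.counts[mo]) for mo in keep])
    aligned: dict[str, np.ndarray] = {}
    for name, tab in (others or {}).items():
        aligned[name] = np.array(
            [int(tab.counts.get(mo, 0)) for mo in keep]
        )
    return keep, ref_vec, aligned


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KendallResult:
    tau: float
    p_two_sided: float
    n: int


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> KendallResult:
    """Kendall tau-b with tie correction.

    Two-sided p uses the tie-corrected normal approximation; for n <= 8
    tie-free inputs the exact permutation null is used.  Zero variance in
    either vector is undefined and flagged with NaNs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return KendallResult(math.nan, math.nan, n)
    no_ties = len(set(x)) == n and len(set(y)) == n
    method = "exact" if (n <= 8 and no_ties) else "asymptotic"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return KendallResult(float(res.statistic), float(res.pvalue), n)


def kendall_distance_from_tau(tau: float, n: int) -> float:
    """Convenience: D = (1 - tau) * n(n-1)/4, the tie-free Kendall distance."""
    return (1.0 - tau) * n * (n - 1) / 4.0


def correlation_r(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> float:
    """Product-moment (default) or Spearman rank correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class ComparisonResult:
    """Table-1-shaped comparison of one frequency table against a reference."""

    r: float
    tau: float
    p_two_sided: float
    n_motifs_used: int


def compare_frequency_tables(
    ref: FrequencyTable,
    other: FrequencyTable,
    prune_fraction: float = 0.10,
    method: str = "pearson",
) -> ComparisonResult:
    """Prune minor motifs by the reference, align, correlate.

    Correlations are computed on the aligned count vectors (motifs absent
    from ``other`` count as zero).
    """
    keep, ref_vec, aligned = prune_minor_motifs(
        ref, {"other": other}, fraction=prune_fraction
    )
    ov = aligned["other"]
    r = correlation_r(ref_vec, ov, method=method)
    kr = kendall_tau_b(ref_vec, ov)
    return ComparisonResult(r=r, tau=kr.tau, p_two_sided=kr.p_two_sided,
                            n_motifs_used=len(keep))


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float          # U statistic for sample a (pairs where a beats b)
    z: float          # tie-corrected normal deviate with continuity correction
    p_two_sided: float
    p_one_sided: float
    method: str


def mann_whitney_z(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Mann-Whitney U with tie-corrected z and exact small-sample p.

    z is signed: positive when sample ``a`` tends to exceed ``b``.  The
    p-value is exact (enumeration of all labelings, ties included) when
    both samples have <= 8 observations, otherwise a normal approximation
    with tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    U = float(ranks[:n].sum() - n * (n + 1) / 2)
    mu = n * m / 2.0
    # tie-corrected variance
    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return MannWhitneyResult(U=U, z=0.0, p_two_sided=1.0, p_one_sided=0.5,
                                 method="degenerate")
    diff = U - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var) if diff != 0 else 0.0

    if n <= 8 and m <= 8:
        # exact enumeration over all C(N, n) labelings (handles ties)
        base = n * (n + 1) / 2
        us = np.array(
            [sum(ranks[list(idx)]) - base
             for idx in itertools.combinations(range(N), n)]
        )
        obs_dev = abs(U - mu)
        p_two = float(np.mean(np.abs(us - mu) >= obs_dev - 1e-9))
        p_lo = float(np.mean(us <= U + 1e-9))
        p_hi = float(np.mean(us >= U - 1e-9))
        p_one = min(p_lo, p_hi)
        return MannWhitneyResult(U=U, z=z, p_two_sided=p_two, p_one_sided=p_one,
                                 method="exact")
    p_two = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(U=U, z=z, p_two_sided=min(1.0, p_two),
                             p_one_sided=min(1.0, sps.norm.sf(abs(z))),
                             method="normal")


# ---------------------------------------------------------------------------
# Fisher's exact tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """(one-sided greater, two-sided) hypergeometric exact p for a 2x2 table.

    Two-sided p sums all tables with the observed margins whose
    probability does not exceed the observed one.  A zero margin gives
    p = 1 (only one table is possible).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, 1.0
    p_greater = float(sps.fisher_exact(t, alternative="greater").pvalue)
    p_two = float(sps.fisher_exact(t, alternative="two-sided").pvalue)
    return p_greater, min(1.0, p_two)


@dataclass(frozen=True)
class RxCResult:
    p_two_sided: float | None
    method: str                    # "exact", "monte-carlo", or "skipped"
    se: float | None = None        # Monte-Carlo standard error
    message: str | None = None


def _log_table_prob(table: np.ndarray, lgr: np.ndarray, lgc: np.ndarray,
                    lgn: float) -> float:
    return float(lgr.sum() + lgc.sum() - lgn - gammaln(table + 1).sum())


def _exact_2xc(table: np.ndarray) -> float:
    """Vectorized exact p for a 2 x c table (enumerate first-row vectors)."""
    r1 = int(table[0].sum())
    cols = table.sum(axis=0).astype(np.int64)
    c = len(cols)
    n = int(cols.sum())
    # log P(a | margins) = sum_j logC(cols_j, a_j) - logC(n, r1)
    lognr1 = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)
    grids = np.meshgrid(*[np.arange(cj + 1) for cj in cols[:-1]], indexing="ij")
    a_rest = r1 - sum(g for g in grids)
    valid = (a_rest >= 0) & (a_rest <= cols[-1])
    logp = -lognr1
    for j, g in enumerate(grids):
        cj = cols[j]
        logp = logp + (gammaln(cj + 1) - gammaln(g + 1) - gammaln(cj - g + 1))
    with np.errstate(invalid="ignore"):
        last = np.where(valid, a_rest, 0)
        cj = cols[-1]
        logp = logp + (gammaln(cj + 1) - gammaln(last + 1) - gammaln(cj - last + 1))
    logp = np.where(valid, logp, -np.inf)
    obs = table[0].astype(np.int64)
    logp_obs = -lognr1 + float(
        np.sum(gammaln(cols + 1) - gammaln(obs + 1) - gammaln(cols - obs + 1))
    )
    mask = logp <= logp_obs + 1e-9
    p = float(np.exp(logp[mask & np.isfinite(logp)]).sum())
    return min(1.0, p)


def _enumerate_rxc(table: np.ndarray, budget: int) -> float | None:
    """DFS exact p for small r x c tables; None if the budget is exceeded."""
    rows = table.sum(axis=1).astype(int)
    cols = table.sum(axis=0).astype(int)
    n = int(table.sum())
    lgr = gammaln(rows + 1)
    lgc = gammaln(cols + 1)
    lgn = gammaln(n + 1)
    logp_obs = _log_table_prob(table, lgr, lgc, lgn)
    total = 0.0
    count = 0

    def rec(ri: int, remaining_cols: np.ndarray, acc: list[np.ndarray]) -> bool:
        nonlocal total, count
        if ri == len(rows) - 1:
            t = np.array(acc + [remaining_cols])
            count += 1
            if count > budget:
                return False
            lp = _log_table_prob(t, lgr, lgc, lgn)
            if lp <= logp_obs + 1e-9:
                total += math.exp(lp)
            return True
        # enumerate row ri compositions bounded by remaining column sums
        row_total = rows[ri]

        def comp(j: int, left: int, row: list[int]) -> bool:
            if j == len(cols) - 1:
                if left > remaining_cols[j]:
                    return True
                return rec(ri + 1, remaining_cols - np.array(row + [left]),
                           acc + [np.array(row + [left])])
            for v in range(min(left, remaining_cols[j]) + 1):
                if not comp(j + 1, left - v, row + [v]):
                    return False
            return True

        return comp(0, row_total, [])

    ok = rec(0, cols.copy(), [])
    return min(1.0, total) if ok else None


def fisher_exact_rxc(
    table: Sequence[Sequence[int]],
    seed: int | None = None,
    n_mc: int = 100_000,
    exact_budget: int = 2_000_000,
) -> RxCResult:
    """Exact (or Monte-Carlo) two-sided Fisher test for an r x c table.

    Exact enumeration of the margin-preserving null when feasible
    (2 x c tables are enumerated vectorized; general tables by bounded
    DFS); otherwise a seeded Monte-Carlo permutation p with its standard
    error.  Degenerate tables (a single non-empty row or column) are
    skipped with a message rather than tested.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("need a nonnegative 2-D table")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return RxCResult(None, "skipped",
                         message="degenerate table (single row or column)")
    if t.shape == (2, 2):
        _, p2 = fisher_exact_2x2(t)
        return RxCResult(p2, "exact")
    if t.shape[0] == 2:
        n_states = int(np.prod(t.sum(axis=0)[:-1] + 1))
        if n_states <= exact_budget:
            return RxCResult(_exact_2xc(t), "exact")
    else:
        p = _enumerate_rxc(t, budget=200_000)
        if p is not None:
            return RxCResult(p, "exact")

    # Monte-Carlo permutation of the margin-preserving null
    rng = np.random.default_rng(seed)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    lgr, lgc, lgn = gammaln(rows + 1), gammaln(cols + 1), gammaln(n + 1)
    logp_obs = _log_table_prob(t, lgr, lgc, lgn)
    labels = np.repeat(np.arange(len(cols)), cols)
    row_ix = np.repeat(np.arange(len(rows)), rows)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(labels)
        sim = np.zeros_like(t)
        np.add.at(sim, (row_ix, labels), 1)
        if _log_table_prob(sim, lgr, lgc, lgn) <= logp_obs + 1e-9:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return RxCResult(min(1.0, p), "monte-carlo", se=se)


# ---------------------------------------------------------------------------
# GO-term over-representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentRecord:
    group: str
    term_id: str
    k: int   # group genes annotated with the term
    K: int   # background genes annotated with the term
    n: int   # group size
    N: int   # background size
    p: float  # one-sided Fisher-exact p (over-representation)
    significant: bool
    q_bh: float | None = None  # optional Benjamini-Hochberg extension


def motif_groups(
    str_genes: Iterable[str],
    pqs_genes: Iterable[str],
    lcgi_genes: Iterable[str],
    ncgi_genes: Iterable[str],
) -> dict[str, set[str]]:
    """The four promoter subgroups used for functional enrichment.

    Membership is non-exclusive across groups except that a gene whose
    only G4 evidence is a locus also called as an STR belongs to the STR
    group; callers should therefore pass ``pqs_genes`` already excluding
    genes whose every PQS locus coincides with an STR call (see
    :func:`promoscan.arrangement.str_over_pqs_gene_sets`).
    """
    return {
        "STR": set(str_genes),
        "PQS": set(pqs_genes),
        "LCGI": set(lcgi_genes),
        "NCGI": set(ncgi_genes),
    }


def go_enrichment(
    groups: Mapping[str, set[str]],
    annotations: Mapping[str, set[str]] | "pd.DataFrame",
    background: set[str],
    cutoff: float = 0.01,
    ease: bool = False,
    with_bh: bool = True,
) -> tuple[list[EnrichmentRecord], "pd.DataFrame"]:
    """One-sided Fisher-exact over-representation of terms in each gene group.

    For each (group, term): the 2x2 table [[k, n-k], [K-k, (N-n)-(K-k)]]
    is tested one-sided for excess of annotated genes in the group;
    records with p < cutoff are flagged.  With ``ease=True`` the
    DAVID-style EASE variant (one success removed) is used.  Returns the
    records and a group x term matrix of -log10 p for heat-map export.
    Terms with no annotated gene in the background are skipped.
    """
    if isinstance(annotations, pd.DataFrame):
        ann: dict[str, set[str]] = {}
        gcol, tcol = annotations.columns[:2]
        for g, t in zip(annotations[gcol], annotations[tcol]):
            ann.setdefault(str(g), set()).add(str(t))
        annotations = ann
    if not annotations:
        raise ValueError("annotation table is empty")
    term_genes: dict[str, set[str]] = {}
    for g, terms in annotations.items():
        if g in background:
            for t in terms:
                term_genes.setdefault(t, set()).add(g)
    N = len(background)
    records: list[EnrichmentRecord] = []
    skipped: list[str] = []
    for gname in sorted(groups):
        gset = set(groups[gname]) & background
        n = len(gset)
        group_records: list[EnrichmentRecord] = []
        for term in sorted(term_genes):
            tg = term_genes[term]
            K = len(tg)
            if K == 0:
                skipped.append(term)
                continue
            k = len(gset & tg)
            if k == 0 or n == 0:
                p = 1.0
            else:
                kk = k - 1 if ease else k
                # P(X >= kk) for X ~ Hypergeom(N, K, n)
                p = float(sps.hypergeom.sf(kk - 1, N, K, n)) if kk > 0 else 1.0
            group_records.append(
                EnrichmentRecord(group=gname, term_id=term, k=k, K=K, n=n, N=N,
                                 p=min(1.0, p), significant=p < cutoff)
            )
        if with_bh and group_records:
            ps = np.array([r.p for r in group_records])
            qs = sps.false_discovery_control(ps, method="bh")
            group_records = [
                EnrichmentRecord(**{**r.__dict__, "q_bh": float(q)})
                for r, q in zip(group_records, qs)
            ]
        records.extend(group_records)
    if not records:
        raise ValueError("no testable (group, term) pairs")
    df = pd.DataFrame(
        [{"group": r.group, "term_id": r.term_id,
          "neglog10_p": -math.log10(max(r.p, 1e-300))} for r in records]
    )
    matrix = df.pivot(index="group", columns="term_id", values="neglog10_p")
    return records, matrix


def enrichment_records_frame(records: Sequence[EnrichmentRecord]) -> "pd.DataFrame":
    return pd.DataFrame([r.__dict__ for r in records])
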