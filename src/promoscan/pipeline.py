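"""End-to-end orchestration: scan -> arrange -> compare -> enrich.

``run_all`` executes the whole promoter-motif workflow on a FASTA input
or a simulated dataset, writes every result table plus a machine-readable
manifest, and is deterministic: identical inputs and config produce
byte-identical outputs.  Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import arrangement as arr
from . import cgi_scanner, consensus_scanner, pqs_scanner, simulate, str_scanner
from . import stats as st
from .promoter_io import Promoter, read_fasta, write_bed, write_fasta

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All parameters of a full run; defaults are the standard scanner settings."""

    fasta: str | None = None
    simulate: dict | None = None          # GeneratorConfig overrides
    annotations: str | None = None        # gene<TAB>term TSV
    reference_tables: dict[str, str] = field(default_factory=dict)
    species: str = ""
    seed: int = 0
    # scanner parameters
    str_min_units: int = 6
    str_periods: tuple[int, ...] = (2, 3, 4, 5, 6)
    cgi_window: int = 100
    cgi_min_len: int = 200
    cgi_gc_min: float = 0.5
    cgi_oe_min: float = 0.6
    lcgi_threshold: int = 800
    pqs_max_span: int = 30
    pqs_min_tetrad: int = 4
    pqs_min_loop: int = 0
    poly_min_run: int = 10
    patterns: dict[str, str] = field(
        default_factory=lambda: dict(consensus_scanner.DEFAULT_PATTERNS)
    )
    enrichment_cutoff: float = 0.01

    def __post_init__(self) -> None:
        for name in ("str_min_units", "cgi_window", "cgi_min_len",
                     "lcgi_threshold", "pqs_max_span", "pqs_min_tetrad",
                     "poly_min_run"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fasta is None and self.simulate is None:
            raise ValueError("config needs either 'fasta' or a 'simulate' block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "str_periods" in raw:
            raw["str_periods"] = tuple(raw["str_periods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["str_periods"] = list(self.str_periods)
        return d


@dataclass
class ResultBundle:
    config: RunConfig
    promoters: list[Promoter]
    truth: "pd.DataFrame | None"
    annotations: "pd.DataFrame | None"
    str_calls: list
    cgi_calls: list
    pqs_calls: list
    consensus_hits: dict[str, list]
    freq_table: st.FrequencyTable
    unit_summary: str_scanner.UnitCountSummary
    di_vs_tetra: st.MannWhitneyResult | None
    gc_profile: arr.GcProfile
    bin_profiles: dict[str, arr.BinProfile]
    tata_profile: dict[int, int]
    arrangement_records: list
    arrangement_counts: "pd.DataFrame"
    arrangement_fet: st.RxCResult | None
    trinuc_profiles: dict[str, arr.BinProfile]
    cooccurrence: dict[str, "pd.DataFrame"]
    cooccurrence_fet: dict[str, st.RxCResult]
    cgi_classes: dict
    lcgi_quantile: float
    comparisons: "pd.DataFrame | None"
    enrichment: "pd.DataFrame | None"
    enrichment_matrix: "pd.DataFrame | None"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def run_all(config: RunConfig) -> ResultBundle:
    """Execute every analysis stage; see the module docstring."""

    def stage(name, fn):
        try:
            out = fn()
            log.info("stage %s done", name)
            return out
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, e) from e

    truth = annotations = None
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        gen_cfg = simulate.GeneratorConfig(**sim_kwargs)
        promoters, truth, annotations = stage(
            "simulate", lambda: simulate.generate(gen_cfg)
        )
    else:
        promoters = stage(
            "read_fasta", lambda: read_fasta(config.fasta, species=config.species)
        )
    if config.annotations is not None:
        annotations = stage(
            "read_annotations",
            lambda: pd.read_csv(config.annotations, sep="\t"),
        )

    gene_ids = [p.gene_id for p in promoters]
    str_calls = stage("scan_str", lambda: str_scanner.scan_many(
        promoters, min_units=config.str_min_units, periods=config.str_periods))
    cgi_calls = stage("scan_cgi", lambda: cgi_scanner.scan_many(
        promoters, window=config.cgi_window, min_len=config.cgi_min_len,
        gc_min=config.cgi_gc_min, oe_min=config.cgi_oe_min))
    pqs_calls = stage("scan_pqs", lambda: pqs_scanner.scan_many(
        promoters, max_span=config.pqs_max_span,
        min_tetrad=config.pqs_min_tetrad, min_loop=config.pqs_min_loop))

    def _consensus():
        hits: dict[str, list] = {}
        for pid, pattern in sorted(config.patterns.items()):
            hits[pid] = []
            for p in promoters:
                hits[pid].extend(
                    consensus_scanner.scan_iupac(p, pattern, pid, both_strands=True)
                )
        for base in "AG":
            key = f"poly{base}"
            hits[key] = []
            for p in promoters:
                hits[key].extend(
                    consensus_scanner.scan_polypurine(p, base, config.poly_min_run)
                )
        return hits

    consensus_hits = stage("scan_consensus", _consensus)

    freq_table = stage("frequency_table", lambda: str_scanner.frequency_table(
        str_calls, n_promoters=len(promoters)))
    unit_summary = stage("unit_summary",
                         lambda: str_scanner.unit_count_summary(str_calls))
    di_vs_tetra = None
    if unit_summary.di_units and unit_summary.tetra_plus_units:
        di_vs_tetra = stage("mann_whitney", lambda: st.mann_whitney_z(
            unit_summary.tetra_plus_units, unit_summary.di_units))

    gc_prof = stage("gc_profile", lambda: arr.gc_profile(promoters))
    L = promoters[0].length

    def _bins():
        wanted = {
            "STR_10bp": (str_calls, 10), "PQS_10bp": (pqs_calls, 10),
            "STR_100bp": (str_calls, 100), "PQS_100bp": (pqs_calls, 100),
            "CGI_100bp": (cgi_calls, 100),
        }
        out = {}
        for name, (calls, width) in wanted.items():
            if L % width == 0:
                out[name] = arr.bin_positions(calls, width, length=L)
            else:
                log.warning("skipping %s: %d-bp bins do not tile %d bp",
                            name, width, L)
        return out

    bin_profiles = stage("bin_profiles", _bins)
    tata_profile = stage("tata_profile", lambda: consensus_scanner.
                         tata_positional_profile(consensus_hits.get("TATA", [])))

    records = stage("arrangement", lambda: arr.arrangement_records(
        str_calls, pqs_calls, cgi_calls))
    arr_counts = stage("arrangement_table", lambda: arr.arrangement_table(records))
    arrangement_fet = None
    if len(arr_counts) >= 2:
        arrangement_fet = stage("arrangement_fet", lambda: st.fisher_exact_rxc(
            arr_counts.to_numpy(), seed=config.seed))
    tri_calls = [c for c in str_calls if c.period == 3]
    if L % 100 == 0:
        trinuc = stage("trinuc_profiles", lambda: arr.trinucleotide_gc_positions(
            tri_calls, 100, length=L))
    else:
        trinuc = {}

    counts_df = stage("per_gene_counts", lambda: arr.per_gene_counts(
        gene_ids, str_calls, cgi_calls, pqs_calls))

    def _cooc():
        tables, fets = {}, {}
        for a, b in (("PQS", "CGI"), ("STR", "CGI"), ("PQS", "STR")):
            t = arr.cooccurrence_table(counts_df, a, b)
            key = f"{a}_vs_{b}"
            tables[key] = t
            fets[key] = st.fisher_exact_rxc(t.to_numpy(), seed=config.seed)
        return tables, fets

    cooccurrence, cooccurrence_fet = stage("cooccurrence", _cooc)

    cgi_classes, lcgi_q = stage("cgi_classes", lambda: cgi_scanner.
                                classify_cgi_promoters(promoters, cgi_calls,
                                                       config.lcgi_threshold))

    comparisons = None
    if config.reference_tables:
        def _compare():
            rows = []
            for name, path in sorted(config.reference_tables.items()):
                other = st.FrequencyTable.from_tsv(path)
                res = st.compare_frequency_tables(freq_table, other)
                rows.append({"reference": name, "r": res.r, "tau": res.tau,
                             "p_two_sided": res.p_two_sided,
                             "n_motifs_used": res.n_motifs_used})
            return pd.DataFrame(rows)

        comparisons = stage("compare", _compare)

    enrichment = enrichment_matrix = None
    if annotations is not None:
        def _enrich():
            str_genes, pqs_genes = arr.str_over_pqs_gene_sets(str_calls, pqs_calls)
            lcgi = {g for g, c in cgi_classes.items() if c.label == "LCGI"}
            ncgi = {g for g, c in cgi_classes.items() if c.label == "NCGI"}
            groups = st.motif_groups(str_genes, pqs_genes, lcgi, ncgi)
            recs, matrix = st.go_enrichment(
                groups, annotations, set(gene_ids),
                cutoff=config.enrichment_cutoff)
            return st.enrichment_records_frame(recs), matrix

        enrichment, enrichment_matrix = stage("enrichment", _enrich)

    return ResultBundle(
        config=config, promoters=promoters, truth=truth, annotations=annotations,
        str_calls=str_calls, cgi_calls=cgi_calls, pqs_calls=pqs_calls,
        consensus_hits=consensus_hits, freq_table=freq_table,
        unit_summary=unit_summary, di_vs_tetra=di_vs_tetra, gc_profile=gc_prof,
        bin_profiles=bin_profiles, tata_profile=tata_profile,
        arrangement_records=records, arrangement_counts=arr_counts,
        arrangement_fet=arrangement_fet, trinuc_profiles=trinuc,
        cooccurrence=cooccurrence, cooccurrence_fet=cooccurrence_fet,
        cgi_classes=cgi_classes, lcgi_quantile=lcgi_q, comparisons=comparisons,
        enrichment=enrichment, enrichment_matrix=enrichment_matrix,
    )


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: "pd.DataFrame", path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def write_outputs(bundle: ResultBundle, out_dir: str | Path) -> Path:
    """Write every result table, BED files, manifest and summary report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    L = bundle.promoters[0].length
    lengths = {p.gene_id: p.length for p in bundle.promoters}

    if cfg.simulate is not None:
        write_fasta(bundle.promoters, out / "promoters.fasta")
        _write_tsv(bundle.truth, out / "truth.tsv")
        _write_tsv(bundle.annotations, out / "annotations.tsv")

    _write_tsv(pd.DataFrame(
        [{"gene_id": c.gene_id, "start": c.interval.start,
          "end": c.interval.end, "period": c.period, "units": c.units,
          "observed_motif": c.observed_motif,
          "canonical_motif": c.canonical_motif,
          "gc_class": c.gc_class or ""} for c in bundle.str_calls]),
        out / "str_calls.tsv")
    write_bed(bundle.str_calls, out / "str_calls.bed",
              promoter_lengths=lengths)
    _write_tsv(cgi_scanner.calls_frame(bundle.cgi_calls), out / "cgi_calls.tsv")
    write_bed(bundle.cgi_calls, out / "cgi_calls.bed", promoter_lengths=lengths)
    _write_tsv(pqs_scanner.calls_frame(bundle.pqs_calls), out / "pqs_calls.tsv")
    write_bed(bundle.pqs_calls, out / "pqs_calls.bed", promoter_lengths=lengths)
    all_hits = [h for hits in bundle.consensus_hits.values() for h in hits]
    write_bed(all_hits, out / "consensus_hits.bed", promoter_lengths=lengths)

    bundle.freq_table.to_tsv(out / "str_frequency_table.tsv")
    _write_tsv(pd.DataFrame(
        {"position_tss": np.arange(-L, 0),
         "mean_gc": bundle.gc_profile.values}), out / "gc_profile.tsv")
    for name, prof in sorted(bundle.bin_profiles.items()):
        _write_tsv(prof.to_frame(), out / f"bins_{name}.tsv")
    _write_tsv(pd.DataFrame(
        {"position_tss": list(bundle.tata_profile),
         "count": list(bundle.tata_profile.values())}), out / "tata_profile.tsv")

    _write_tsv(pd.DataFrame(
        [r.__dict__ for r in bundle.arrangement_records]),
        out / "arrangement_records.tsv")
    _write_tsv(bundle.arrangement_counts, out / "arrangement_table.tsv", index=True)
    for klass, prof in sorted(bundle.trinuc_profiles.items()):
        safe = klass.replace("%", "pct")
        _write_tsv(prof.to_frame(), out / f"trinuc_{safe}.tsv")
    for key, table in sorted(bundle.cooccurrence.items()):
        _write_tsv(table, out / f"cooccurrence_{key}.tsv", index=True)
    _write_tsv(pd.DataFrame(
        [{"gene_id": c.gene_id, "label": c.label,
          "total_cgi_length": c.total_cgi_length, "n_islands": c.n_islands}
         for c in bundle.cgi_classes.values()]), out / "cgi_classes.tsv")
    if bundle.comparisons is not None:
        _write_tsv(bundle.comparisons, out / "comparisons.tsv")
    if bundle.enrichment is not None:
        _write_tsv(bundle.enrichment, out / "enrichment.tsv")
        _write_tsv(bundle.enrichment_matrix, out / "enrichment_matrix.tsv",
                   index=True)

    (out / "report.txt").write_text(report(bundle))

    manifest: dict[str, Any] = {
        "package": "promoscan",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": cfg.to_dict(),
        "inputs": {},
        "outputs": {},
    }
    if cfg.fasta:
        manifest["inputs"][cfg.fasta] = _sha256(Path(cfg.fasta))
    if cfg.annotations:
        manifest["inputs"][cfg.annotations] = _sha256(Path(cfg.annotations))
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def report(bundle: ResultBundle) -> str:
    """Human-readable run summary (a pure function of the bundle)."""
    n = len(bundle.promoters)
    str_genes = {c.gene_id for c in bundle.str_calls}
    cgi_genes = {c.gene_id for c in bundle.cgi_calls}
    pqs_genes = {c.gene_id for c in bundle.pqs_calls}
    labels = [c.label for c in bundle.cgi_classes.values()]
    lines = [
        "promoscan run summary",
        "=====================",
        f"promoters analyzed:        {n}",
        f"mean GC fraction:          {bundle.gc_profile.overall_mean:.4f}",
        f"STR calls:                 {len(bundle.str_calls)}",
        f"STR per sequence:          {bundle.freq_table.str_per_seq:.4f}",
        f"% genes with >=1 STR:      {100 * len(str_genes) / n:.2f}",
        f"CGI calls:                 {len(bundle.cgi_calls)}",
        f"% genes with CGI:          {100 * len(cgi_genes) / n:.2f}",
        f"LCGI promoters:            {labels.count('LCGI')}",
        f"NCGI promoters:            {labels.count('NCGI')}",
        f"PQS calls:                 {len(bundle.pqs_calls)}",
        f"% genes with PQS:          {100 * len(pqs_genes) / n:.2f}",
    ]
    if bundle.di_vs_tetra is not None:
        mw = bundle.di_vs_tetra
        lines.append(
            f"tetra+ vs di unit counts:  z = {mw.z:.3f}, p = {mw.p_two_sided:.3g}"
        )
    if len(bundle.arrangement_counts):
        top = bundle.arrangement_counts.sum(axis=0).idxmax()
        lines.append(f"most common CGI relation:  {top}")
    if bundle.enrichment is not None:
        sig = bundle.enrichment[bundle.enrichment["significant"]]
        lines.append(f"significant GO terms:      {len(sig)}")
        for _, r in sig.iterrows():
            lines.append(
                f"  {r['group']:>5} {r['term_id']}  p = {r['p']:.3g}"
            )
    return "\n".join(lines) + "\n"
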