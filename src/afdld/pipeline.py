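"""Pipeline stages behind the command-line interface.

Each stage reads and writes plain files so the stages are independently
testable and resumable:

* ``stats``    — genotype matrix -> per-SNP statistics table (+ thresholds),
* ``annotate`` — adds site classes and the constraint flag to the table,
* ``enrich``   — circular-permutation enrichment tests + distance decay,
* ``scan``     — sliding-window candidate-density scan,
* ``simulate`` — writes a complete synthetic input bundle,
* ``all``      — simulate nothing, run stats -> annotate -> enrich -> scan.

All randomness flows from a single seed via named substreams, and a run
manifest (parameters, input checksums, package version) is written next to
every output, so reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, enrichment, io_formats, popgen_stats

logger = logging.getLogger("afdld")

__all__ = ["PipelineConfig", "run_stats", "run_annotate", "run_enrich",
           "run_scan", "run_all", "stage_rng"]

_STAGE_STREAMS = {"simulate": 0, "stats": 1, "annotate": 2, "enrich": 3, "scan": 4}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named, independent random substream for one pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGE_STREAMS[stage],))
    )


@dataclass
class PipelineConfig:
    """Analysis parameters; the defaults are the method's canonical values.

    MAF strictly > 0.05; 20-kb LD window; ancestral probability strictly
    > 0.6; AFD/LD thresholds at the 95th genome-wide percentiles (or the
    fixed historical pair 0.70 / 0.19 in fixed mode); conserved blocks at
    score >= 0.8 over >= 10 nt; 1 kb upstream cis intervals; 100-kb QTL
    proximity; 20-kb / 1-kb scan windows; 1,000 circular permutations;
    significance at q < 0.1.
    """

    maf_threshold: float = 0.05
    het_policy: str = "missing"
    ploidy: int = 1
    ld_window_bp: int = 20_000
    ld_neighbor_mode: str = "distance"
    anc_prob_threshold: float = 0.6
    threshold_mode: str = "percentile"      # "percentile" | "fixed"
    afd_percentile: float = 95.0
    ld_percentile: float = 95.0
    afd_fixed_threshold: float = 0.70
    ld_fixed_threshold: float = 0.19
    cons_min_score: float = 0.8
    cons_min_len: int = 10
    cis_bp: int = 1_000
    qtl_max_dist_bp: int = 100_000
    scan_window_bp: int = 20_000
    scan_step_bp: int = 1_000
    n_perm: int = 1_000
    fdr: float = 0.1
    decay_bin_width_bp: int = 100_000
    decay_n_bins: int = 10
    pop_a: str = "popA"
    pop_b: str = "popB"
    seed: int = 1
    dump_null: bool = False

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("percentile", "fixed"):
            raise ValueError("threshold_mode must be 'percentile' or 'fixed'")
        if self.het_policy not in ("missing", "ref", "alt"):
            raise ValueError("bad het_policy")
        if self.ld_neighbor_mode not in ("distance", "centered"):
            raise ValueError("bad ld_neighbor_mode")
        for name in ("maf_threshold", "fdr"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} outside [0, 1)")
        for name in ("ld_window_bp", "cons_min_len", "cis_bp", "qtl_max_dist_bp",
                     "scan_window_bp", "scan_step_bp", "n_perm",
                     "decay_bin_width_bp", "decay_n_bins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.scan_window_bp < self.scan_step_bp:
            raise ValueError("scan window must be >= scan step")
        if not (0 < self.anc_prob_threshold < 1):
            raise ValueError("anc_prob_threshold outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def fixed_thresholds(self) -> tuple[float, float] | None:
        if self.threshold_mode == "fixed":
            return (self.afd_fixed_threshold, self.ld_fixed_threshold)
        return None


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig,
                    inputs: dict[str, Path], extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": config.to_dict(),
        # file names only: absolute paths would break run-to-run comparison
        "inputs": {k: {"file": Path(p).name, "sha256": _sha256(Path(p))}
                   for k, p in inputs.items() if p is not None},
    }
    if extra:
        manifest.update(extra)
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(paths: dict[str, Path | None], *names: str) -> None:
    for name in names:
        p = paths.get(name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {p}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_stats(
    vcf: str | Path,
    popmap: str | Path,
    outdir: str | Path,
    config: PipelineConfig,
    ancestral: str | Path | None = None,
    qvalues: str | Path | None = None,
) -> Path:
    """MAF filter, per-SNP statistics, candidate calling -> variant_table.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"vcf": Path(vcf), "popmap": Path(popmap)}
    if ancestral:
        inputs["ancestral"] = Path(ancestral)
    if qvalues:
        inputs["qvalues"] = Path(qvalues)
    _require(inputs, *inputs.keys())

    matrix = io_formats.read_vcf(vcf, config.het_policy, config.ploidy)
    pm = io_formats.read_popmap(popmap, config.pop_a, config.pop_b)
    pm.validate_against(matrix)
    matrix = popgen_stats.maf_filter(matrix, config.maf_threshold)
    anc_base = anc_prob = None
    if ancestral:
        anc = pd.read_csv(ancestral, sep="\t",
                          dtype={"chrom": str, "pos": np.int64})
        merged = matrix.variant_frame().merge(anc, on=["chrom", "pos"], how="left")
        anc_base = merged["anc_base"].fillna("N").to_numpy(dtype=object)
        anc_prob = merged["anc_prob"].to_numpy(dtype=float)
    table, call = popgen_stats.build_variant_table(
        matrix, pm,
        ld_window_bp=config.ld_window_bp,
        neighbor_mode=config.ld_neighbor_mode,
        anc_base=anc_base, anc_prob=anc_prob,
        anc_prob_threshold=config.anc_prob_threshold,
        afd_percentile=config.afd_percentile,
        ld_percentile=config.ld_percentile,
        fixed_thresholds=config.fixed_thresholds(),
    )
    if qvalues:
        table["qvalue"] = io_formats.read_score_column(qvalues, matrix, "qvalue")
    out = outdir / "variant_table.tsv"
    table.to_csv(out, sep="\t", index=False, na_rep="NA")
    _write_manifest(outdir, "stats", config, inputs, extra={
        "n_snps": int(len(table)),
        "afd_threshold": call.afd_threshold,
        "ld_threshold": call.ld_threshold,
        "n_candidates": int(table["afdld_candidate"].sum()),
    })
    return out


def run_annotate(
    variant_table: str | Path,
    gff3: str | Path,
    conservation: str | Path,
    fasta: str | Path,
    outdir: str | Path,
    config: PipelineConfig,
) -> Path:
    """Site classification and constraint flags -> variant_table_annotated.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"variant_table": Path(variant_table), "gff3": Path(gff3),
              "conservation": Path(conservation), "fasta": Path(fasta)}
    _require(inputs, *inputs.keys())

    table = pd.read_csv(variant_table, sep="\t",
                        dtype={"chrom": str, "pos": np.int64})
    genes = io_formats.read_gff3(gff3)
    track = io_formats.read_conservation(conservation)
    seqs = io_formats.read_fasta(fasta)
    cis = annotation.build_cis_intervals(genes, config.cis_bp)
    blocks = annotation.conserved_blocks(track, config.cons_min_score,
                                         config.cons_min_len)
    table = annotation.classify_sites(table, genes, cis, blocks, seqs)
    out = outdir / "variant_table_annotated.tsv"
    table.to_csv(out, sep="\t", index=False, na_rep="NA")
    cis.to_bed().to_csv(outdir / "cis_intervals.bed", sep="\t",
                        index=False, header=False)
    blocks.to_bed().to_csv(outdir / "conserved_blocks.bed", sep="\t",
                           index=False, header=False)
    _write_manifest(outdir, "annotate", config, inputs, extra={
        "n_cis": int((table["site_class"] == "cis_regulatory").sum()),
        "n_nonsyn": int((table["site_class"] == "nonsynonymous").sum()),
        "n_syn": int((table["site_class"] == "synonymous").sum()),
        "n_constrained": int(table["constrained"].sum()),
    })
    return out


def _selections(table: pd.DataFrame, config: PipelineConfig) -> dict[str, np.ndarray]:
    sel = {"afdld": table["afdld_candidate"].to_numpy(dtype=bool)}
    if "qvalue" in table.columns and table["qvalue"].notna().any():
        q = table["qvalue"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            sel["qvalue"] = q < config.fdr
    return sel


def run_enrich(
    variant_table: str | Path,
    outdir: str | Path,
    config: PipelineConfig,
    peaks: str | Path | None = None,
    gff3: str | Path | None = None,
    gene_list: str | Path | None = None,
) -> Path:
    """Circular-permutation enrichment tests -> enrichment.tsv.

    Tests run for every available selection (the AFD.LD indicator, and
    q < fdr when a q-value column is present): QTL-peak proximity (needs
    ``peaks``), constrained cis-regulatory and constrained nonsynonymous
    sites (need an annotated table), and the gene-list count test (needs
    ``gff3`` + ``gene_list``).  Degenerate tests are flagged, not fatal.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, Path] = {"variant_table": Path(variant_table)}
    _require(inputs, "variant_table")
    table = pd.read_csv(variant_table, sep="\t",
                        dtype={"chrom": str, "pos": np.int64})
    chrom = table["chrom"].to_numpy(dtype=object)
    pos = table["pos"].to_numpy(dtype=np.int64)
    rng = stage_rng(config.seed, "enrich")
    selections = _selections(table, config)
    rows = []
    null_dump = {}

    def record(test: str, selection: str, res: enrichment.EnrichmentResult) -> None:
        rows.append({
            "test": test, "selection": selection,
            "observed": res.observed, "null_mean": res.null_mean,
            "null_p95": res.null_p95, "pvalue": res.pvalue,
            "significant": res.significant, "valid": res.valid,
            "n_selected": res.n_selected, "n_perm": len(res.null),
        })
        if config.dump_null:
            null_dump[f"{test}.{selection}"] = res.null.tolist()

    peak_set = None
    if peaks is not None:
        inputs["peaks"] = Path(peaks)
        _require(inputs, "peaks")
        peak_set = io_formats.read_qtl_peaks(peaks)
        member = enrichment.qtl_proximity_category(
            chrom, pos, peak_set, config.qtl_max_dist_bp
        )
        for name, sel in selections.items():
            record("qtl_proximity", name,
                   enrichment.permutation_test(sel, member, config.n_perm, rng=rng))

    if "site_class" in table.columns:
        constrained = table["constrained"].to_numpy(dtype=bool)
        cls = table["site_class"].to_numpy(dtype=object)
        for test, mask in (
            ("constrained_cisreg", (cls == "cis_regulatory") & constrained),
            ("constrained_nonsyn", (cls == "nonsynonymous") & constrained),
        ):
            for name, sel in selections.items():
                record(test, name,
                       enrichment.permutation_test(sel, mask, config.n_perm, rng=rng))

    if gene_list is not None:
        if gff3 is None:
            raise FileNotFoundError("gene-list test requested without a gff3")
        inputs["gff3"] = Path(gff3)
        inputs["gene_list"] = Path(gene_list)
        _require(inputs, "gff3", "gene_list")
        genes = io_formats.read_gff3(gff3)
        cis = annotation.build_cis_intervals(genes, config.cis_bp)
        assign = annotation.gene_snp_assignment(table, genes, cis)
        gl = io_formats.read_gene_list(gene_list)
        functional = (
            np.isin(table["site_class"].to_numpy(dtype=object),
                    ["cis_regulatory", "nonsynonymous"])
            if "site_class" in table.columns
            else np.ones(len(table), dtype=bool)
        )
        for name, sel in selections.items():
            record("gene_list", name,
                   enrichment.gene_level_test(gl, assign, sel & functional,
                                              config.n_perm, rng=rng))

    out = outdir / "enrichment.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, na_rep="NA")
    if config.dump_null:
        with open(outdir / "null_distributions.json", "w") as fh:
            json.dump(null_dump, fh)

    if peak_set is not None:
        decay = enrichment.distance_decay(
            chrom, pos, selections["afdld"], peak_set,
            config.decay_bin_width_bp, config.decay_n_bins,
        )
        dd = pd.DataFrame({
            "bin_start": decay.bin_edges[:-1],
            "bin_end": decay.bin_edges[1:],
            "n_total": decay.n_total,
            "n_candidates": decay.n_candidates,
            "proportion": decay.proportions,
        })
        dd.to_csv(outdir / "distance_decay.tsv", sep="\t", index=False, na_rep="NA")
        with open(outdir / "distance_decay_fit.json", "w") as fh:
            json.dump({"slope_per_bp": decay.slope, "r_squared": decay.r_squared,
                       "pvalue": decay.pvalue}, fh, indent=2)
    _write_manifest(outdir, "enrich", config, inputs,
                    extra={"n_tests": len(rows)})
    return out


def run_scan(
    variant_table: str | Path,
    outdir: str | Path,
    config: PipelineConfig,
) -> Path:
    """Sliding-window AFD.LD candidate density -> window_scan.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"variant_table": Path(variant_table)}
    _require(inputs, "variant_table")
    table = pd.read_csv(variant_table, sep="\t",
                        dtype={"chrom": str, "pos": np.int64})
    scan = popgen_stats.window_scan(
        table["chrom"].to_numpy(dtype=object),
        table["pos"].to_numpy(dtype=np.int64),
        table["afdld_candidate"].to_numpy(dtype=bool),
        config.scan_window_bp, config.scan_step_bp,
    )
    out = outdir / "window_scan.tsv"
    scan.to_csv(out, sep="\t", index=False, na_rep="NA")
    _write_manifest(outdir, "scan", config, inputs,
                    extra={"n_windows": int(len(scan))})
    return out


def run_all(
    indir: str | Path,
    outdir: str | Path,
    config: PipelineConfig,
) -> Path:
    """stats -> annotate -> enrich -> scan over a standard input bundle.

    ``indir`` must hold genotypes.vcf, popmap.tsv, reference.fa, genes.gff3,
    conservation.bedgraph, ancestral.tsv, qvalues.tsv, qtl_peaks.tsv and
    gene_list.tsv (the layout the synthetic generator writes).
    """
    indir = Path(indir)
    outdir = Path(outdir)
    vt = run_stats(indir / "genotypes.vcf", indir / "popmap.tsv", outdir, config,
                   ancestral=_opt(indir / "ancestral.tsv"),
                   qvalues=_opt(indir / "qvalues.tsv"))
    vt = run_annotate(vt, indir / "genes.gff3", indir / "conservation.bedgraph",
                      indir / "reference.fa", outdir, config)
    run_enrich(vt, outdir, config,
               peaks=_opt(indir / "qtl_peaks.tsv"),
               gff3=indir / "genes.gff3",
               gene_list=_opt(indir / "gene_list.tsv"))
    run_scan(vt, outdir, config)
    return outdir


def _opt(path: Path) -> Path | None:
    return path if path.exists() else None
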