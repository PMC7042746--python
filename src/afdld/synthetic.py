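"""Synthetic two-population cohort generator with planted structure.

The generator emulates the statistical structure the pipeline assumes in a
real resequencing panel — two focal populations nested in a wider panel —
without any coalescent machinery: every statistic downstream depends only on
allele-frequency and correlation structure, so genotypes are simulated
directly at the frequency level.

Planted features, each recorded in a truth table:

* **divergent loci** with focal-population allele frequencies at a target
  (default 0.95 / 0.05, i.e. AFD 0.90), embedded in LD blocks built by
  copying the planted dosage column to the following SNPs with a per-sample
  flip probability ``ld_epsilon`` — giving the closed-form expected
  source-to-member r-squared of about ``(1 - 2 * eps)**2`` at intermediate
  frequency;
* **low-derived-frequency variants** (panel DAF below 0.1) with confident
  ancestral calls, mimicking the rare-allele tail of a derived-allele
  spectrum;
* neutral background drawn from a shared ancestral frequency with weak
  Balding-Nichols drift between the focal populations;
* gene models (valid CDS phase, length divisible by three), conservation
  blocks placed over a configurable fraction of planted loci, QTL peaks
  linked to planted loci plus decoys, and externally-supplied-style q-values
  whose significant fraction is biased toward the low-frequency class.

Identical config + seed reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, io_formats
from .io_formats import (
    ConservationTrack,
    GeneModel,
    GenotypeMatrix,
    PopulationMap,
    QTLPeakSet,
)

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort",
           "simulate_genotypes", "simulate_annotations", "simulate_qtl_and_scores"]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    25 + 40 focal samples inside an 875-sample panel, 20,000 SNPs over two
    1-Mb chromosomes, 100 planted divergent loci at target frequencies
    0.95 / 0.05, LD blocks of 10 SNPs with flip probability 0.05, a tenth of
    SNPs in the low-derived-frequency class, and 10 QTL peaks of which 6 are
    linked to planted loci.
    """

    seed: int
    n_pop_a: int = 25
    n_pop_b: int = 40
    n_total: int = 875
    n_snps: int = 20_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"Chr1": 1_000_000, "Chr2": 1_000_000}
    )
    bg_freq_range: tuple[float, float] = (0.05, 0.95)
    drift_f: float = 0.005
    n_planted: int = 100
    planted_f_a: float = 0.95
    planted_f_b: float = 0.05
    planted_panel_freq: float = 0.5
    ld_block_size: int = 10
    ld_epsilon: float = 0.05
    low_freq_fraction: float = 0.10
    low_freq_max: float = 0.10
    anc_uncallable_fraction: float = 0.15
    missing_rate: float = 0.02
    n_genes: int = 60
    gene_min_len: int = 1_500
    gene_max_len: int = 3_000
    conserved_overlap_fraction: float = 0.5
    n_bg_conserved: int = 40
    n_lowscore_intervals: int = 40
    n_peaks: int = 10
    n_linked_peaks: int = 6
    peak_link_dist: int = 10_000
    q_sig_fraction: float = 0.05
    q_lowfreq_weight: float = 0.5
    n_list_genes: int = 20
    list_planted_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_pop_a", "n_pop_b", "n_total", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_pop_a + self.n_pop_b > self.n_total:
            raise ValueError("focal populations exceed the panel size")
        for f in (self.planted_f_a, self.planted_f_b, self.planted_panel_freq):
            if not (0.0 <= f <= 1.0):
                raise ValueError("target frequencies must lie in [0, 1]")
        if not (0.0 <= self.ld_epsilon <= 0.5):
            raise ValueError("ld_epsilon must lie in [0, 0.5]")
        if self.n_linked_peaks > self.n_peaks:
            raise ValueError("n_linked_peaks exceeds n_peaks")


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated study comprises."""

    config: SimulationConfig
    matrix: GenotypeMatrix
    popmap: PopulationMap
    truth: pd.DataFrame
    seqs: dict[str, str]
    genes: list[GeneModel]
    track: ConservationTrack
    cis: annotation.CisRegulatoryIntervals
    peaks: QTLPeakSet
    qvalues: np.ndarray
    anc_base: np.ndarray
    anc_prob: np.ndarray
    gene_list: list[str]
    env: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every input file the pipeline consumes; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "genotypes.vcf",
            "popmap": outdir / "popmap.tsv",
            "fasta": outdir / "reference.fa",
            "gff3": outdir / "genes.gff3",
            "conservation": outdir / "conservation.bedgraph",
            "ancestral": outdir / "ancestral.tsv",
            "qvalues": outdir / "qvalues.tsv",
            "peaks": outdir / "qtl_peaks.tsv",
            "gene_list": outdir / "gene_list.tsv",
            "truth": outdir / "truth.tsv",
            "env": outdir / "env.tsv",
            "sim_config": outdir / "sim_config.yaml",
        }
        io_formats.write_vcf(self.matrix, paths["vcf"], self.config.chrom_lengths)
        io_formats.write_popmap(self.popmap, paths["popmap"])
        io_formats.write_fasta(self.seqs, paths["fasta"])
        io_formats.write_gff3(self.genes, paths["gff3"])
        io_formats.write_conservation_bedgraph(self.track, paths["conservation"])
        anc = self.matrix.variant_frame()[["chrom", "pos"]].copy()
        anc["anc_base"] = self.anc_base
        anc["anc_prob"] = np.round(self.anc_prob, 4)
        anc.to_csv(paths["ancestral"], sep="\t", index=False)
        io_formats.write_score_column(self.matrix, np.round(self.qvalues, 6),
                                      paths["qvalues"], "qvalue")
        io_formats.write_qtl_peaks(self.peaks, paths["peaks"])
        pd.DataFrame({"gene_id": self.gene_list}).to_csv(
            paths["gene_list"], sep="\t", index=False
        )
        self.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep="NA")
        self.env.to_csv(paths["env"], sep="\t", index=False, float_format="%.4f")
        with open(paths["sim_config"], "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _positions(config: SimulationConfig, rng: np.random.Generator):
    """Sorted unique SNP positions, allocated proportionally to chromosome length."""
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(config.n_snps * lengths / lengths.sum()).astype(int)
    counts[0] += config.n_snps - counts.sum()
    chrom_col, pos_col = [], []
    for c, k in zip(chroms, counts):
        L = config.chrom_lengths[c]
        if k > L:
            raise ValueError(f"cannot place {k} SNPs on {c} of length {L}")
        pos = np.sort(rng.choice(L, size=k, replace=False) + 1)
        chrom_col.extend([c] * k)
        pos_col.extend(pos.tolist())
    return np.array(chrom_col, dtype=object), np.array(pos_col, dtype=np.int64)


def _plant_classes(config: SimulationConfig, chrom: np.ndarray,
                   rng: np.random.Generator):
    """Choose planted-divergent, block-member and low-frequency SNP indices.

    Divergent loci are spread over evenly sized strata of each chromosome's
    SNP index range so their LD blocks (the following ``ld_block_size``
    SNPs) never collide.
    """
    n = len(chrom)
    planted: list[int] = []
    blocks: dict[int, list[int]] = {}
    chroms = pd.unique(chrom)
    per_chrom = np.full(len(chroms), config.n_planted // len(chroms))
    per_chrom[: config.n_planted % len(chroms)] += 1
    for c, k in zip(chroms, per_chrom):
        rows = np.where(chrom == c)[0]
        if k == 0:
            continue
        strata = np.array_split(rows, k)
        for s in strata:
            margin = config.ld_block_size + 2
            if len(s) <= 2 * margin:
                raise ValueError("too few SNPs per stratum for planted loci")
            i = int(rng.integers(margin, len(s) - margin))
            src = int(s[i])
            planted.append(src)
            blocks[src] = [src + j for j in range(1, config.ld_block_size + 1)]
    planted_arr = np.array(planted, dtype=int)
    block_members = np.array(
        [j for mem in blocks.values() for j in mem], dtype=int
    )
    taken = set(planted_arr.tolist()) | set(block_members.tolist())
    free = np.array([i for i in range(n) if i not in taken], dtype=int)
    n_low = int(round(config.low_freq_fraction * n))
    low = rng.choice(free, size=min(n_low, len(free)), replace=False)
    return planted_arr, blocks, np.sort(low)


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator,
    seqs: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Draw the haploid dosage matrix, population map and truth table."""
    if seqs is None:
        seqs = simulate_reference(config, rng)
    chrom, pos = _positions(config, rng)
    n = len(pos)
    planted, blocks, low = _plant_classes(config, chrom, rng)

    lo, hi = config.bg_freq_range
    p_anc = rng.uniform(lo, hi, size=n)
    F = config.drift_f
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        f_a = rng.beta(a, b)
        f_b = rng.beta(a, b)
    else:
        f_a = p_anc.copy()
        f_b = p_anc.copy()
    f_panel = p_anc.copy()

    cls = np.array(["neutral"] * n, dtype=object)
    cls[planted] = "divergent"
    f_a[planted] = config.planted_f_a
    f_b[planted] = config.planted_f_b
    f_panel[planted] = config.planted_panel_freq

    cls[low] = "low_freq"
    # the low-frequency class is defined on the *derived* allele; whether the
    # derived allele is ref or alt is randomised below
    f_derived = rng.uniform(0.01, max(config.low_freq_max - 0.01, 0.02), size=len(low))
    derived_is_alt = rng.random(len(low)) < 0.5
    f_low_alt = np.where(derived_is_alt, f_derived, 1.0 - f_derived)
    f_a[low] = f_low_alt
    f_b[low] = f_low_alt
    f_panel[low] = f_low_alt

    n_a, n_b = config.n_pop_a, config.n_pop_b
    n_rest = config.n_total - n_a - n_b
    dosage = np.empty((n, config.n_total), dtype=float)
    dosage[:, :n_a] = (rng.random((n, n_a)) < f_a[:, None]).astype(float)
    dosage[:, n_a : n_a + n_b] = (rng.random((n, n_b)) < f_b[:, None]).astype(float)
    if n_rest:
        dosage[:, n_a + n_b :] = (rng.random((n, n_rest)) < f_panel[:, None]).astype(float)

    block_id = np.array([""] * n, dtype=object)
    eps = config.ld_epsilon
    for src, members in blocks.items():
        label = f"{chrom[src]}:{pos[src]}"
        block_id[src] = label
        for j in members:
            flips = rng.random(config.n_total) < eps
            dosage[j] = np.where(flips, 1.0 - dosage[src], dosage[src])
            block_id[j] = label

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    # alleles from the reference sequence
    ref = np.array([seqs[c][p - 1] for c, p in zip(chrom, pos)], dtype=object)
    alt = np.empty(n, dtype=object)
    for i in range(n):
        others = [b for b in "ACGT" if b != ref[i]]
        alt[i] = others[int(rng.integers(3))]

    samples = (
        [f"A{i:03d}" for i in range(1, n_a + 1)]
        + [f"B{i:03d}" for i in range(1, n_b + 1)]
        + [f"P{i:04d}" for i in range(1, n_rest + 1)]
    )
    mapping = {s: "popA" for s in samples[:n_a]}
    mapping.update({s: "popB" for s in samples[n_a : n_a + n_b]})
    mapping.update({s: "panel" for s in samples[n_a + n_b :]})
    popmap = PopulationMap(mapping, "popA", "popB")
    matrix = GenotypeMatrix(chrom, pos, ref, alt, dosage, samples, ploidy=1)

    # ancestral calls
    anc_base = np.empty(n, dtype=object)
    anc_prob = np.empty(n)
    callable_ = rng.random(n) >= config.anc_uncallable_fraction
    anc_is_ref = rng.random(n) < 0.5
    anc_prob[:] = np.where(
        callable_, rng.uniform(0.61, 0.99, n), rng.uniform(0.40, 0.60, n)
    )
    anc_base[:] = np.where(anc_is_ref, ref, alt)
    # the low-frequency class must be confidently polarised with the minor
    # allele derived
    anc_prob[low] = rng.uniform(0.7, 0.99, size=len(low))
    anc_base[low] = np.where(derived_is_alt, ref[low], alt[low])

    truth = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "class": cls,
            "target_f_a": np.where(cls == "divergent", config.planted_f_a, np.nan),
            "target_f_b": np.where(cls == "divergent", config.planted_f_b, np.nan),
            "block_id": block_id,
            "anc_base": anc_base,
            "anc_prob": anc_prob,
        }
    )
    return matrix, popmap, truth


def simulate_reference(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """Uniform-random reference sequence per chromosome."""
    return {
        c: "".join(_BASES[rng.integers(0, 4, size=L)])
        for c, L in sorted(config.chrom_lengths.items())
    }


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[list[GeneModel], ConservationTrack, annotation.CisRegulatoryIntervals]:
    """Place non-overlapping gene models and a conservation track.

    A fraction ``conserved_overlap_fraction`` of planted divergent loci is
    covered by a conserved block (score in [0.8, 1], length >= 10); all other
    conserved/low-score intervals avoid planted loci, so at fraction 0 no
    planted locus is constrained and at 1 every one is.
    """
    chroms = sorted(config.chrom_lengths)
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    per_chrom = np.full(len(chroms), config.n_genes // len(chroms))
    per_chrom[: config.n_genes % len(chroms)] += 1
    for c, k in zip(chroms, per_chrom):
        L = config.chrom_lengths[c]
        placed = 0
        attempts = 0
        while placed < k:
            attempts += 1
            if attempts > 200 * max(k, 1):
                raise RuntimeError(
                    f"gene packing failure on {c}: placed {placed} of {k} genes"
                )
            glen = int(rng.integers(config.gene_min_len, config.gene_max_len + 1))
            start = int(rng.integers(1, max(L - glen, 2)))
            end = start + glen - 1
            if any(s <= end + 1 and start - 1 <= e for s, e in occupied[c]):
                continue
            occupied[c].append((start, end))
            placed += 1
            genes.append(_make_gene(f"G{c}_{placed:03d}", c, start, end, rng))
    genes.sort(key=lambda g: (g.chrom, g.start))

    track = _make_track(config, truth, genes, rng)
    cis = annotation.build_cis_intervals(genes, cis_bp=1_000)
    return genes, track, cis


def _make_gene(gene_id: str, chrom: str, start: int, end: int,
               rng: np.random.Generator) -> GeneModel:
    """Two-exon gene with UTR margins and CDS total length divisible by 3."""
    strand = "+" if rng.random() < 0.5 else "-"
    glen = end - start + 1
    utr5 = int(rng.integers(50, 150))
    utr3 = int(rng.integers(50, 150))
    intron = int(rng.integers(60, 200))
    coding_total = glen - utr5 - utr3 - intron
    coding_total -= coding_total % 3
    if coding_total < 6:
        raise ValueError(f"gene {gene_id} too short for a CDS")
    len1 = 3 * int(rng.integers(1, max(coding_total // 3, 2)))
    len1 = max(3, min(len1, coding_total - 3))
    len2 = coding_total - len1
    c1s = start + utr5
    c1e = c1s + len1 - 1
    c2s = c1e + intron + 1
    c2e = c2s + len2 - 1
    # phases in transcript order: first segment 0, second (3 - len1 % 3) % 3
    if strand == "+":
        cds = [(c1s, c1e, 0), (c2s, c2e, (3 - len1 % 3) % 3)]
    else:
        # transcript order runs right-to-left: the rightmost exon is first
        cds = [(c1s, c1e, (3 - len2 % 3) % 3), (c2s, c2e, 0)]
    return GeneModel(gene_id, chrom, strand, start, end, cds)


def _make_track(config: SimulationConfig, truth: pd.DataFrame,
                genes: list[GeneModel], rng: np.random.Generator) -> ConservationTrack:
    planted = truth[truth["class"] == "divergent"]
    intervals: dict[str, list[tuple[int, int, float]]] = {
        c: [] for c in sorted(config.chrom_lengths)
    }
    forbidden: dict[str, list[tuple[int, int]]] = {
        c: [] for c in sorted(config.chrom_lengths)
    }

    def collides(c: str, s: int, e: int) -> bool:
        return any(s <= fe and fs <= e for fs, fe in forbidden[c])

    def reserve(c: str, s: int, e: int) -> None:
        forbidden[c].append((s, e))

    # keep every planted locus clear unless deliberately covered
    for _, row in planted.iterrows():
        reserve(row["chrom"], int(row["pos"]) - 60, int(row["pos"]) + 60)

    n_cover = int(round(config.conserved_overlap_fraction * len(planted)))
    cover_rows = planted.iloc[
        np.sort(rng.choice(len(planted), size=n_cover, replace=False))
    ] if len(planted) else planted
    for _, row in cover_rows.iterrows():
        c, p = row["chrom"], int(row["pos"])
        half = int(rng.integers(6, 20))
        s, e = max(1, p - half), min(config.chrom_lengths[c], p + half)
        score = float(np.round(rng.uniform(0.82, 0.99), 2))
        intervals[c].append((s, e, score))

    for c in sorted(config.chrom_lengths):
        L = config.chrom_lengths[c]
        placed = 0
        attempts = 0
        want = config.n_bg_conserved // len(config.chrom_lengths)
        while placed < want and attempts < 50 * max(want, 1):
            attempts += 1
            length = int(rng.integers(10, 60))
            s = int(rng.integers(1, max(L - length, 2)))
            e = s + length - 1
            if collides(c, s, e):
                continue
            reserve(c, s, e)
            score = float(np.round(rng.uniform(0.80, 1.00), 2))
            intervals[c].append((s, e, score))
            placed += 1
        placed = 0
        attempts = 0
        want = config.n_lowscore_intervals // len(config.chrom_lengths)
        while placed < want and attempts < 50 * max(want, 1):
            attempts += 1
            length = int(rng.integers(10, 60))
            s = int(rng.integers(1, max(L - length, 2)))
            e = s + length - 1
            if collides(c, s, e):
                continue
            reserve(c, s, e)
            score = float(np.round(rng.uniform(0.10, 0.70), 2))
            intervals[c].append((s, e, score))
            placed += 1
    return ConservationTrack(intervals)


# ---------------------------------------------------------------------------
# QTL peaks and q-values
# ---------------------------------------------------------------------------

def simulate_qtl_and_scores(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[QTLPeakSet, np.ndarray]:
    """Place QTL peaks (linked + decoys) and draw per-SNP q-values.

    Linked peaks land within ``peak_link_dist`` of a planted divergent locus.
    A fraction ``q_sig_fraction`` of q-values is significant (< 0.1), and a
    weight of those significant q-values is spent on the low-derived-
    frequency class, mimicking the rare-allele skew real association scans
    show.
    """
    planted = truth.index[truth["class"] == "divergent"].to_numpy()
    n = len(truth)
    rows = []
    chosen = rng.choice(planted, size=min(config.n_linked_peaks, len(planted)),
                        replace=False) if len(planted) else np.empty(0, int)
    k = 0
    for idx in np.sort(chosen):
        c = truth.at[int(idx), "chrom"]
        p = int(truth.at[int(idx), "pos"])
        L = config.chrom_lengths[c]
        if config.peak_link_dist > 0:
            shift = int(rng.integers(-config.peak_link_dist, config.peak_link_dist + 1))
        else:
            shift = 0
        k += 1
        rows.append((f"Q{k:02d}", c, int(np.clip(p + shift, 1, L)), f"{c}:{p}"))
    chroms = sorted(config.chrom_lengths)
    while k < config.n_peaks:
        c = chroms[int(rng.integers(len(chroms)))]
        p = int(rng.integers(1, config.chrom_lengths[c] + 1))
        k += 1
        rows.append((f"Q{k:02d}", c, p, "decoy"))
    peaks = QTLPeakSet(pd.DataFrame(rows, columns=["peak_id", "chrom", "pos", "parent"]))

    qvalues = rng.uniform(0.1, 1.0, size=n)
    n_sig = int(round(config.q_sig_fraction * n))
    low = truth.index[truth["class"] == "low_freq"].to_numpy()
    n_low_sig = min(int(round(config.q_lowfreq_weight * n_sig)), len(low))
    sig_low = rng.choice(low, size=n_low_sig, replace=False) if n_low_sig else np.empty(0, int)
    others = np.setdiff1d(np.arange(n), sig_low)
    n_other_sig = max(n_sig - n_low_sig, 0)
    sig_other = rng.choice(others, size=n_other_sig, replace=False) if n_other_sig else np.empty(0, int)
    sig = np.concatenate([sig_low, sig_other]).astype(int)
    qvalues[sig] = rng.uniform(1e-4, 0.0999, size=len(sig))
    return peaks, qvalues


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run the full generator with named substreams off the single seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_annot, rng_qtl, rng_env = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    seqs = simulate_reference(config, rng_geno)
    matrix, popmap, truth = simulate_genotypes(config, rng_geno, seqs)
    genes, track, cis = simulate_annotations(config, truth, rng_annot)
    peaks, qvalues = simulate_qtl_and_scores(config, truth, rng_qtl)
    gene_list = _pick_gene_list(config, genes, truth, rng_qtl)
    env = _env_covariate(matrix, popmap, rng_env)
    return SyntheticCohort(
        config=config, matrix=matrix, popmap=popmap, truth=truth, seqs=seqs,
        genes=genes, track=track, cis=cis, peaks=peaks, qvalues=qvalues,
        anc_base=truth["anc_base"].to_numpy(dtype=object),
        anc_prob=truth["anc_prob"].to_numpy(dtype=float),
        gene_list=gene_list, env=env,
    )


def _pick_gene_list(config: SimulationConfig, genes: list[GeneModel],
                    truth: pd.DataFrame, rng: np.random.Generator) -> list[str]:
    """A gene list biased toward genes whose span or upstream kb holds a
    planted divergent locus (emulating a curated candidate-gene list)."""
    planted = truth[truth["class"] == "divergent"]
    linked, unlinked = [], []
    for g in genes:
        sub = planted[planted["chrom"] == g.chrom]
        lo = g.start - 1_000 if g.strand == "+" else g.start
        hi = g.end if g.strand == "+" else g.end + 1_000
        if ((sub["pos"] >= lo) & (sub["pos"] <= hi)).any():
            linked.append(g.gene_id)
        else:
            unlinked.append(g.gene_id)
    n_linked = min(int(round(config.list_planted_fraction * config.n_list_genes)),
                   len(linked))
    pick = list(rng.choice(linked, size=n_linked, replace=False)) if n_linked else []
    n_fill = min(config.n_list_genes - len(pick), len(unlinked))
    pick += list(rng.choice(unlinked, size=n_fill, replace=False)) if n_fill else []
    return sorted(pick)


def _env_covariate(matrix: GenotypeMatrix, popmap: PopulationMap,
                   rng: np.random.Generator) -> pd.DataFrame:
    """One scalar environmental covariate per sample (population offset + noise)."""
    offsets = {popmap.pop_a: -1.0, popmap.pop_b: 1.0}
    vals = [
        offsets.get(popmap.mapping.get(s, ""), 0.0) + rng.normal(0.0, 0.5)
        for s in matrix.samples
    ]
    return pd.DataFrame({"sample": matrix.samples, "env": vals})
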