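"""Readers and writers for the external formats the pipeline touches.

Internal conventions
--------------------
* Coordinates are 1-based inclusive everywhere (VCF/GFF3 native).
  BED-family inputs (BEDGraph) are 0-based half-open and converted at the
  boundary.
* Genotypes are stored as a float dosage matrix (variants x samples) with
  ``numpy.nan`` marking missing calls.  Under the default haploid encoding
  dosages are {0, 1}; the diploid mode uses {0, 1, 2}.  The study organism
  (a highly selfing annual) is treated as effectively haploid: residual
  heterozygous calls are most likely errors and default to missing.
* Variants are kept strictly sorted by (chromosome, position), chromosomes
  lexicographically unless an explicit chromosome order is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import gffutils
from Bio import SeqIO
from cyvcf2 import VCF

logger = logging.getLogger("afdld")

__all__ = [
    "GenotypeMatrix",
    "PopulationMap",
    "GeneModel",
    "ConservationTrack",
    "QTLPeakSet",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_gff3",
    "write_gff3",
    "read_conservation",
    "write_conservation_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_qtl_peaks",
    "write_qtl_peaks",
    "read_score_column",
    "write_score_column",
    "read_gene_list",
    "chrom_sort_key",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

def chrom_sort_key(chrom: str, chrom_order: Sequence[str] | None = None):
    """Sort key for chromosome labels: explicit order if given, else lexicographic."""
    if chrom_order is not None:
        return (list(chrom_order).index(chrom),)
    return (chrom,)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP x sample dosage matrix with coordinates and alleles.

    Invariants: variants sorted by (chrom, pos) with unique positions per
    chromosome; all sites single-base biallelic; dosages in {0..ploidy} or NaN.
    """

    chrom: np.ndarray          # (n_variants,) str
    pos: np.ndarray            # (n_variants,) int64, 1-based
    ref: np.ndarray            # (n_variants,) str, single base
    alt: np.ndarray            # (n_variants,) str, single base
    dosage: np.ndarray         # (n_variants, n_samples) float, NaN = missing
    samples: list[str]
    ploidy: int = 1

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError("dosage shape does not match variants x samples")
        self.validate()

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        # chromosomes must form contiguous blocks, positions strictly
        # ascending within each (strictness also enforces uniqueness)
        seen: set[str] = set()
        prev_c, prev_p = None, None
        for c, p in zip(self.chrom, self.pos):
            if c != prev_c:
                if c in seen:
                    raise ValueError(f"chromosome {c} not contiguous")
                seen.add(c)
                prev_c, prev_p = c, p
                continue
            if p <= prev_p:
                raise ValueError(f"positions not strictly sorted on {c}")
            prev_p = p
        d = self.dosage
        ok = np.isnan(d) | ((d >= 0) & (d <= self.ploidy) & (d == np.floor(d)))
        if not ok.all():
            raise ValueError("dosages outside {0..ploidy} / missing")

    def sorted_copy(self, chrom_order: Sequence[str] | None = None) -> "GenotypeMatrix":
        key = [chrom_sort_key(c, chrom_order) + (p,) for c, p in zip(self.chrom, self.pos)]
        idx = np.array(sorted(range(self.n_variants), key=lambda i: key[i]))
        return self.take(idx)

    def take(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[idx],
            samples=list(self.samples),
            ploidy=self.ploidy,
        )

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"sample {exc} not in genotype matrix") from exc

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )


@dataclass
class PopulationMap:
    """Sample -> population labels plus the named focal pair (pop_a, pop_b)."""

    mapping: dict[str, str]
    pop_a: str
    pop_b: str

    def __post_init__(self) -> None:
        pops = set(self.mapping.values())
        for label in (self.pop_a, self.pop_b):
            if label not in pops:
                raise ValueError(f"focal population {label!r} absent from map")

    def samples_in(self, pop: str) -> list[str]:
        if pop not in set(self.mapping.values()):
            raise KeyError(f"unknown population label {pop!r}")
        return [s for s, p in self.mapping.items() if p == pop]

    def focal_samples(self) -> list[str]:
        return self.samples_in(self.pop_a) + self.samples_in(self.pop_b)

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = [s for s in self.focal_samples() if s not in matrix.samples]
        if missing:
            raise ValueError(f"focal samples absent from genotype matrix: {missing[:5]}")


@dataclass
class GeneModel:
    """One gene: strand, genic span, and ordered CDS intervals with phase.

    ``cds`` holds (start, end, phase) triples in genomic order, 1-based
    inclusive.  ``codable`` is False when there is no CDS or the summed CDS
    length is not a multiple of three; such genes are excluded from coding
    classification.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.cds = sorted(self.cds)
        prev_end = None
        for s, e, _ in self.cds:
            if s < self.start or e > self.end:
                raise ValueError(f"CDS outside genic span in {self.gene_id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site: genic start on +, genic end on -."""
        return self.start if self.strand == "+" else self.end

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    @property
    def codable(self) -> bool:
        return bool(self.cds) and self.cds_length % 3 == 0


@dataclass
class ConservationTrack:
    """Per-base conservation score over declared intervals.

    Stored as sorted, non-overlapping 1-based inclusive intervals per
    chromosome; a base outside every interval has *no score* (distinct from
    score 0).
    """

    intervals: dict[str, list[tuple[int, int, float]]]

    def __post_init__(self) -> None:
        clean: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, ivs in self.intervals.items():
            ivs = sorted(ivs)
            merged: list[tuple[int, int, float]] = []
            for s, e, v in ivs:
                if s > e:
                    raise ValueError(f"empty interval {s}..{e} on {chrom}")
                if merged and s <= merged[-1][1]:
                    ps, pe, pv = merged[-1]
                    if pv != v:
                        raise ValueError(
                            f"conflicting scores overlap at {chrom}:{s} ({pv} vs {v})"
                        )
                    merged[-1] = (ps, max(pe, e), pv)
                else:
                    merged.append((s, e, v))
            clean[chrom] = merged
        self.intervals = clean

    def score_at(self, chrom: str, pos: int) -> float | None:
        ivs = self.intervals.get(chrom)
        if not ivs:
            return None
        starts = [s for s, _, _ in ivs]
        import bisect

        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and ivs[i][0] <= pos <= ivs[i][1]:
            return ivs[i][2]
        return None

    def chroms(self) -> list[str]:
        return sorted(self.intervals)


@dataclass
class QTLPeakSet:
    """Point positions of QTL peaks (markers with the highest LOD score)."""

    table: pd.DataFrame  # columns: peak_id, chrom, pos [, parent]

    def __post_init__(self) -> None:
        required = {"peak_id", "chrom", "pos"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        if self.table["peak_id"].duplicated().any():
            raise ValueError("duplicate peak ids")
        self.table = self.table.reset_index(drop=True)

    def validate_lengths(self, chrom_lengths: Mapping[str, int]) -> None:
        for _, row in self.table.iterrows():
            L = chrom_lengths.get(row["chrom"])
            if L is None or not (1 <= row["pos"] <= L):
                raise ValueError(f"peak {row['peak_id']} outside declared chromosome")

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.table[self.table["chrom"] == chrom]
        return np.sort(sub["pos"].to_numpy(dtype=np.int64))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    het_policy: str = "missing",
    ploidy: int = 1,
    chrom_order: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Non-SNP and multiallelic records are skipped (count logged).  Under the
    default haploid mode hom-ref -> 0, hom-alt -> 1, missing -> NaN, and
    heterozygous calls follow ``het_policy`` ("missing", "ref" or "alt").
    Diploid mode (ploidy=2) encodes {0, 1, 2} with heterozygotes as 1.
    """
    if het_policy not in ("missing", "ref", "alt"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
    if ploidy == 1:
        het_code = {"missing": np.nan, "ref": 0.0, "alt": 1.0}[het_policy]
        code = np.array([0.0, het_code, 1.0, np.nan])
    else:
        code = np.array([0.0, 1.0, 2.0, np.nan])
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(code[np.asarray(rec.gt_types)])
    if skipped:
        logger.info("read_vcf: skipped %d non-SNP/multiallelic records", skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    key = sorted(
        range(len(poss)),
        key=lambda i: chrom_sort_key(chroms[i], chrom_order) + (poss[i],),
    )
    idx = np.array(key)
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object)[idx],
        pos=np.array(poss, dtype=np.int64)[idx],
        ref=np.array(refs, dtype=object)[idx],
        alt=np.array(alts, dtype=object)[idx],
        dosage=np.vstack(rows)[idx],
        samples=samples,
        ploidy=ploidy,
    )


_GT_HAPLOID = {0.0: "0/0", 1.0: "1/1"}
_GT_DIPLOID = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              chrom_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 that round-trips through :func:`read_vcf`."""
    gt_map = _GT_HAPLOID if matrix.ploidy == 1 else _GT_DIPLOID
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_lengths:
            for c in sorted(chrom_lengths):
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
        else:
            for c in sorted(set(matrix.chrom.tolist())):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_variants):
            gts = "\t".join(
                "./." if np.isnan(d) else gt_map[d] for d in matrix.dosage[i]
            )
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# population map / gene lists / score columns / peaks (simple TSVs)
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path, pop_a: str, pop_b: str) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "population"}.issubset(df.columns):
        raise ValueError("population map needs columns: sample, population")
    return PopulationMap(dict(zip(df["sample"], df["population"])), pop_a, pop_b)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(popmap.mapping), "population": list(popmap.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise ValueError("gene list needs a gene_id column")
    return df["gene_id"].tolist()


def read_qtl_peaks(path: str | Path) -> QTLPeakSet:
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str, "chrom": str, "pos": np.int64})
    return QTLPeakSet(df)


def write_qtl_peaks(peaks: QTLPeakSet, path: str | Path) -> None:
    peaks.table.to_csv(path, sep="\t", index=False)


def read_score_column(
    path: str | Path, matrix: GenotypeMatrix, value_col: str = "qvalue"
) -> np.ndarray:
    """Read a per-SNP score TSV (chrom, pos, <value_col>) aligned to the matrix.

    Positions absent from the TSV get NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64})
    if value_col not in df.columns:
        raise ValueError(f"score file lacks column {value_col!r}")
    merged = matrix.variant_frame().merge(
        df[["chrom", "pos", value_col]], on=["chrom", "pos"], how="left"
    )
    return merged[value_col].to_numpy(dtype=float)


def write_score_column(
    matrix: GenotypeMatrix, values: np.ndarray, path: str | Path, value_col: str = "qvalue"
) -> None:
    out = matrix.variant_frame()[["chrom", "pos"]].copy()
    out[value_col] = values
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/CDS features).

    For genes with several transcripts the first mRNA carrying CDS features
    (by id) is used.  Genes whose summed CDS length is not divisible by three
    keep their CDS but are flagged non-codable by :class:`GeneModel`.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        cds: list[tuple[int, int, int]] = []
        mrnas = sorted(db.children(g, featuretype="mRNA"), key=lambda m: m.id)
        chosen = None
        for m in mrnas:
            m_cds = list(db.children(m, featuretype="CDS", order_by="start"))
            if m_cds:
                chosen = m_cds
                break
        if chosen is None:  # CDS attached directly to the gene, or none at all
            chosen = list(db.children(g, featuretype="CDS", order_by="start"))
        for c in chosen:
            phase = int(c.frame) if c.frame not in (".", None) else 0
            cds.append((c.start, c.end, phase))
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                cds=cds,
            )
        )
    n_bad = sum(not g.codable for g in genes)
    if n_bad:
        logger.info("read_gff3: %d gene(s) non-codable (no CDS or length %% 3 != 0)", n_bad)
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tafdld\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tafdld\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for j, (s, e, ph) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tafdld\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\t"
                    f"ID={mrna}.cds{j};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# conservation tracks (BEDGraph / wiggle)
# ---------------------------------------------------------------------------

def read_conservation(path: str | Path) -> ConservationTrack:
    """Read a per-base conservation track from BEDGraph or wiggle.

    BEDGraph intervals (0-based half-open) are converted to 1-based inclusive.
    Overlapping intervals with conflicting scores abort.
    """
    text = Path(path).read_text().splitlines()
    is_wig = any(
        ln.startswith(("fixedStep", "variableStep")) for ln in text[:50]
    )
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    if is_wig:
        mode = None
        chrom = None
        start = step = span = 1
        for ln in text:
            ln = ln.strip()
            if not ln or ln.startswith(("track", "#")):
                continue
            if ln.startswith("fixedStep"):
                kv = dict(f.split("=") for f in ln.split()[1:])
                mode, chrom = "fixed", kv["chrom"]
                start = int(kv["start"])
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if ln.startswith("variableStep"):
                kv = dict(f.split("=") for f in ln.split()[1:])
                mode, chrom = "variable", kv["chrom"]
                span = int(kv.get("span", 1))
                continue
            if mode == "fixed":
                intervals.setdefault(chrom, []).append(
                    (start, start + span - 1, float(ln))
                )
                start += step
            elif mode == "variable":
                p, v = ln.split()
                p = int(p)
                intervals.setdefault(chrom, []).append((p, p + span - 1, float(v)))
            else:
                raise ValueError("wiggle data before any step declaration")
    else:
        for ln in text:
            ln = ln.strip()
            if not ln or ln.startswith(("track", "#")):
                continue
            c, s, e, v = ln.split()[:4]
            s, e = int(s), int(e)
            if e <= s:
                raise ValueError(f"empty BEDGraph interval {ln!r}")
            intervals.setdefault(c, []).append((s + 1, e, float(v)))
    return ConservationTrack(intervals)


def write_conservation_bedgraph(track: ConservationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for s, e, v in track.intervals[chrom]:
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
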