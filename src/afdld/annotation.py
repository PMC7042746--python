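"""Functional classification of SNPs.

Three annotation layers are combined:

* **cis-regulatory intervals** — for each gene, the up-to-1-kb stretch
  immediately upstream of its transcription start site (strand-aware),
  minus any bases falling inside another gene's genic span;
* **coding effect** — synonymous vs nonsynonymous, decided by rebuilding
  the codon containing the SNP from the gene's CDS intervals and phase,
  reverse-complementing on the minus strand and translating both alleles
  with the standard genetic code (stop is a distinct symbol, so stop
  gain/loss counts as nonsynonymous);
* **selective constraint** — maximal runs of >= ``min_len`` consecutive
  scored bases with conservation score >= ``min_score`` (defaults 10 nt at
  0.8); unscored bases break runs.

Per-SNP classes follow the precedence coding > cis_regulatory > other, and
every SNP carries an independent ``constrained`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io_formats import ConservationTrack, GeneModel

logger = logging.getLogger("afdld")

__all__ = [
    "CisRegulatoryIntervals",
    "ConservedBlocks",
    "build_cis_intervals",
    "classify_coding_change",
    "conserved_blocks",
    "classify_sites",
    "gene_snp_assignment",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


# ---------------------------------------------------------------------------
# cis-regulatory intervals
# ---------------------------------------------------------------------------

@dataclass
class CisRegulatoryIntervals:
    """Per-gene upstream intervals (1-based inclusive), possibly fragmented
    by the exclusion of other genes' genic spans."""

    by_gene: dict[str, list[tuple[str, int, int]]]

    def trees(self) -> dict[str, IntervalTree]:
        """chrom -> IntervalTree over half-open [start, end+1) with gene_id data."""
        trees: dict[str, IntervalTree] = {}
        for gid, ivs in self.by_gene.items():
            for chrom, s, e in ivs:
                trees.setdefault(chrom, IntervalTree()).addi(s, e + 1, gid)
        return trees

    def to_bed(self) -> pd.DataFrame:
        rows = [
            (chrom, s - 1, e, gid)
            for gid, ivs in sorted(self.by_gene.items())
            for chrom, s, e in ivs
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).sort_values(
            ["chrom", "start"], ignore_index=True
        )


def build_cis_intervals(
    genes: list[GeneModel], cis_bp: int = 1_000
) -> CisRegulatoryIntervals:
    """Upstream-of-TSS intervals, excluding bases inside other genes.

    A plus-strand gene with TSS t gets the raw interval [t-cis_bp, t-1]; a
    minus-strand gene [t+1, t+cis_bp].  The interval is clipped at the
    chromosome start and every base lying within another gene's genic span
    is removed, which may fragment or empty the interval.
    """
    genic: dict[str, IntervalTree] = {}
    for g in genes:
        genic.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    out: dict[str, list[tuple[str, int, int]]] = {}
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss - cis_bp, g.tss - 1
        else:
            lo, hi = g.tss + 1, g.tss + cis_bp
        lo = max(lo, 1)
        pieces: list[tuple[int, int]] = [(lo, hi)] if lo <= hi else []
        for iv in sorted(genic.get(g.chrom, IntervalTree()).overlap(lo, hi + 1)):
            if iv.data == g.gene_id:
                continue
            span = (iv.begin, iv.end - 1)
            pieces = _subtract(pieces, span)
        out[g.gene_id] = [(g.chrom, s, e) for s, e in pieces]
    return CisRegulatoryIntervals(out)


def _subtract(
    pieces: list[tuple[int, int]], cut: tuple[int, int]
) -> list[tuple[int, int]]:
    """Remove closed interval ``cut`` from each closed interval in ``pieces``."""
    cs, ce = cut
    result: list[tuple[int, int]] = []
    for s, e in pieces:
        if ce < s or cs > e:
            result.append((s, e))
            continue
        if s < cs:
            result.append((s, cs - 1))
        if ce < e:
            result.append((ce + 1, e))
    return result


# ---------------------------------------------------------------------------
# coding change classification
# ---------------------------------------------------------------------------

def classify_coding_change(
    gene: GeneModel, pos: int, ref: str, alt: str, chrom_seq: str
) -> str:
    """Classify a SNP inside a codable CDS as synonymous or nonsynonymous.

    ``chrom_seq`` is the full reference chromosome sequence (Python string,
    index 0 = position 1).  The codon containing the SNP is reassembled from
    the spliced CDS in transcript orientation, honouring the phase of the
    first CDS segment; both alleles are translated with the standard genetic
    code.  Returns "synonymous", "nonsynonymous", or "other" when the gene is
    non-codable or the position falls in a phase overhang.
    """
    if not gene.codable:
        logger.debug("gene %s non-codable; SNP %s:%d left unclassified",
                     gene.gene_id, gene.chrom, pos)
        return "other"
    segments = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    phase = segments[0][2]
    # genomic coordinates of the spliced CDS in transcript order
    coords: list[int] = []
    for s, e, _ in segments:
        rng = range(s, e + 1) if gene.strand == "+" else range(e, s - 1, -1)
        coords.extend(rng)
    try:
        cds_index = coords.index(pos)
    except ValueError:
        raise ValueError(f"position {pos} not inside CDS of {gene.gene_id}")
    if cds_index < phase:
        return "other"  # partial codon before the first complete frame
    codon_no = (cds_index - phase) // 3
    within = (cds_index - phase) % 3
    codon_coords = coords[phase + 3 * codon_no : phase + 3 * codon_no + 3]
    if len(codon_coords) < 3:
        return "other"  # trailing partial codon

    def base_at(gpos: int) -> str:
        b = chrom_seq[gpos - 1].upper()
        return b if gene.strand == "+" else _COMPLEMENT[b]

    ref_t = ref.upper() if gene.strand == "+" else _COMPLEMENT[ref.upper()]
    alt_t = alt.upper() if gene.strand == "+" else _COMPLEMENT[alt.upper()]
    ref_codon = [base_at(g) for g in codon_coords]
    if ref_codon[within] != ref_t:
        logger.warning(
            "reference mismatch at %s:%d (sequence %s, VCF ref %s); using VCF ref",
            gene.chrom, pos, ref_codon[within], ref_t,
        )
        ref_codon[within] = ref_t
    alt_codon = list(ref_codon)
    alt_codon[within] = alt_t
    aa_ref = str(Seq("".join(ref_codon)).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


# ---------------------------------------------------------------------------
# conserved blocks
# ---------------------------------------------------------------------------

@dataclass
class ConservedBlocks:
    """Maximal runs of consecutive scored bases above the score floor."""

    blocks: dict[str, list[tuple[int, int]]]
    min_score: float = 0.8
    min_len: int = 10

    def trees(self) -> dict[str, IntervalTree]:
        return {
            chrom: IntervalTree.from_tuples((s, e + 1) for s, e in ivs)
            for chrom, ivs in self.blocks.items()
            if ivs
        }

    def contains(self, chrom: str, pos: int) -> bool:
        for s, e in self.blocks.get(chrom, []):
            if s <= pos <= e:
                return True
        return False

    def to_bed(self) -> pd.DataFrame:
        rows = [
            (chrom, s - 1, e)
            for chrom in sorted(self.blocks)
            for s, e in self.blocks[chrom]
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def conserved_blocks(
    track: ConservationTrack, min_score: float = 0.8, min_len: int = 10
) -> ConservedBlocks:
    """Call maximal runs of >= ``min_len`` consecutive bases scoring >= ``min_score``.

    Unscored bases break runs (absence of evidence, not evidence of score 0),
    as do scored bases below the floor.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in track.intervals.items():
        blocks: list[tuple[int, int]] = []
        run_start = run_end = None
        for s, e, v in ivs:  # sorted, non-overlapping
            qualifies = v >= min_score
            contiguous = run_end is not None and s == run_end + 1
            if qualifies and contiguous:
                run_end = e
            elif qualifies:
                if run_start is not None and run_end - run_start + 1 >= min_len:
                    blocks.append((run_start, run_end))
                run_start, run_end = s, e
            else:
                if run_start is not None and run_end - run_start + 1 >= min_len:
                    blocks.append((run_start, run_end))
                run_start = run_end = None
        if run_start is not None and run_end - run_start + 1 >= min_len:
            blocks.append((run_start, run_end))
        out[chrom] = blocks
    return ConservedBlocks(out, min_score, min_len)


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------

def classify_sites(
    table: pd.DataFrame,
    genes: list[GeneModel],
    cis: CisRegulatoryIntervals,
    blocks: ConservedBlocks,
    seqs: dict[str, str],
) -> pd.DataFrame:
    """Append ``site_class`` and ``constrained`` columns to a variant table.

    ``site_class`` is one of nonsynonymous / synonymous / cis_regulatory /
    other with precedence coding > cis-regulatory > other; a SNP inside the
    CDS of a codable gene is classified by translation, a SNP only inside
    non-codable CDS stays "other".  ``constrained`` flags positions inside a
    conserved block.  Gene order breaks ties when CDS of two codable genes
    overlap (first by gene id).
    """
    cds_trees: dict[str, IntervalTree] = {}
    for g in genes:
        for s, e, _ in g.cds:
            cds_trees.setdefault(g.chrom, IntervalTree()).addi(s, e + 1, g)
    cis_trees = cis.trees()
    block_trees = blocks.trees()

    classes: list[str] = []
    constrained: list[bool] = []
    for chrom, pos, ref, alt in zip(
        table["chrom"], table["pos"], table["ref"], table["alt"]
    ):
        pos = int(pos)
        cls = "other"
        hits = sorted(
            cds_trees.get(chrom, IntervalTree()).overlap(pos, pos + 1),
            key=lambda iv: iv.data.gene_id,
        )
        codable_hits = [iv.data for iv in hits if iv.data.codable]
        if codable_hits:
            cls = classify_coding_change(codable_hits[0], pos, ref, alt, seqs[chrom])
        elif hits:
            cls = "other"  # inside CDS of non-codable gene(s) only
        elif chrom in cis_trees and cis_trees[chrom].overlap(pos, pos + 1):
            cls = "cis_regulatory"
        classes.append(cls)
        tree = block_trees.get(chrom)
        constrained.append(bool(tree.overlap(pos, pos + 1)) if tree else False)
    out = table.copy()
    out["site_class"] = classes
    out["constrained"] = constrained
    return out


def gene_snp_assignment(
    table: pd.DataFrame,
    genes: list[GeneModel],
    cis: CisRegulatoryIntervals,
) -> dict[str, np.ndarray]:
    """Map gene id -> indices of SNPs in its cis interval or CDS.

    A SNP overlapping the cis intervals of several genes is assigned to each
    of them (gene-level tests count genes, not SNPs).
    """
    assign: dict[str, set[int]] = {g.gene_id: set() for g in genes}
    cds_trees: dict[str, IntervalTree] = {}
    for g in genes:
        for s, e, _ in g.cds:
            cds_trees.setdefault(g.chrom, IntervalTree()).addi(s, e + 1, g.gene_id)
    cis_trees = cis.trees()
    for i, (chrom, pos) in enumerate(zip(table["chrom"], table["pos"])):
        pos = int(pos)
        for tree in (cds_trees.get(chrom), cis_trees.get(chrom)):
            if tree is None:
                continue
            for iv in tree.overlap(pos, pos + 1):
                assign[iv.data].add(i)
    return {gid: np.array(sorted(idx), dtype=int) for gid, idx in assign.items()}
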