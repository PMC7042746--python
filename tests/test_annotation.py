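import numpy as np
import pandas as pd
import pytest

from afdld.annotation import (
    build_cis_intervals,
    classify_coding_change,
    classify_sites,
    conserved_blocks,
    gene_snp_assignment,
)
from afdld.io_formats import ConservationTrack, GeneModel
from afdld.synthetic import SimulationConfig, simulate_annotations

from conftest import small_sim_config


def gene(gene_id="g1", chrom="c1", strand="+", start=5_001, end=6_000, cds=()):
    return GeneModel(gene_id, chrom, strand, start, end, list(cds))


class TestCisIntervals:
    def test_plus_strand_upstream_kilobase(self):
        cis = build_cis_intervals([gene()])
        assert cis.by_gene["g1"] == [("c1", 4_001, 5_000)]

    def test_minus_strand_downstream_of_genic_end(self):
        cis = build_cis_intervals([gene(strand="-", start=1_001, end=2_000)])
        assert cis.by_gene["g1"] == [("c1", 2_001, 3_000)]

    def test_neighbor_genic_span_excluded(self):
        g1 = gene()
        g2 = gene("g2", start=4_500, end=6_000 + 1_500)  # overlaps upstream of g1
        cis = build_cis_intervals([g1, g2])
        assert cis.by_gene["g1"] == [("c1", 4_001, 4_499)]

    def test_clipped_at_chromosome_start(self):
        cis = build_cis_intervals([gene(start=400, end=900)])
        assert cis.by_gene["g1"] == [("c1", 1, 399)]

    def test_interval_can_be_emptied(self):
        g1 = gene()
        blocker = gene("g2", start=3_000, end=5_000)
        cis = build_cis_intervals([g1, blocker])
        assert cis.by_gene["g1"] == []

    def test_no_cis_base_inside_any_genic_span_random_genomes(self):
        for seed in (3, 4):
            cfg = small_sim_config(seed=seed)
            rng = np.random.default_rng(seed)
            truth = pd.DataFrame({"chrom": [], "pos": [], "class": []})
            genes, _, cis = simulate_annotations(cfg, truth, rng)
            spans = [(g.chrom, g.start, g.end, g.gene_id) for g in genes]
            for gid, ivs in cis.by_gene.items():
                for chrom, s, e in ivs:
                    assert s <= e and e - s + 1 <= 1_000
                    for c2, gs, ge, gid2 in spans:
                        if c2 != chrom or gid2 == gid:
                            continue
                        assert e < gs or s > ge, (gid, gid2)


class TestCodingChange:
    def test_met_to_ile_nonsynonymous(self):
        seq = "NNNATGNNN"
        g = gene(start=1, end=9, cds=[(4, 6, 0)])
        assert classify_coding_change(g, 6, "G", "A", seq) == "nonsynonymous"

    def test_ala_wobble_synonymous(self):
        seq = "NNNGCTNNN"
        g = gene(start=1, end=9, cds=[(4, 6, 0)])
        assert classify_coding_change(g, 6, "T", "C", seq) == "synonymous"

    def test_minus_strand_asp_to_asn(self):
        # genomic ATC on the minus strand reads GAT (Asp); genomic C->T at the
        # codon's first transcript position gives AAT (Asn)
        seq = "NNNATCNNN"
        g = gene(strand="-", start=1, end=9, cds=[(4, 6, 0)])
        assert classify_coding_change(g, 6, "C", "T", seq) == "nonsynonymous"

    def test_stop_gain_counts_as_nonsynonymous(self):
        seq = "NNNTGGNNN"  # Trp codon; G->A at position 3 gives TGA stop
        g = gene(start=1, end=9, cds=[(4, 6, 0)])
        assert classify_coding_change(g, 6, "G", "A", seq) == "nonsynonymous"

    def test_non_codable_gene_classified_other(self):
        seq = "NNNATGCNNN"
        g = gene(start=1, end=10, cds=[(4, 7, 0)])  # length 4, not codable
        assert classify_coding_change(g, 5, "T", "C", seq) == "other"

    def test_split_codon_across_intron(self):
        # CDS [4,5] + [8,8]: the single codon spans the intron (bases 4,5,8)
        seq = "NNNATNNGN"
        g = gene(start=1, end=9, cds=[(4, 5, 0), (8, 8, 1)])
        got = classify_coding_change(g, 8, "G", "A", seq)
        # ATG (Met) -> ATA (Ile)
        assert got == "nonsynonymous"


class TestConservedBlocks:
    def track(self, scores, start=1, chrom="c1"):
        ivs = [
            (start + i, start + i, s) for i, s in enumerate(scores) if s is not None
        ]
        return ConservationTrack({chrom: ivs})

    def test_ten_consecutive_high_bases_is_block(self):
        b = conserved_blocks(self.track([0.9] * 10), 0.8, 10)
        assert b.blocks["c1"] == [(1, 10)]

    def test_nine_bases_no_block(self):
        b = conserved_blocks(self.track([0.95] * 9), 0.8, 10)
        assert b.blocks["c1"] == []

    def test_low_middle_base_splits_run(self):
        scores = [0.9] * 5 + [0.7] + [0.9] * 6
        b = conserved_blocks(self.track(scores), 0.8, 10)
        assert b.blocks["c1"] == []

    def test_unscored_base_breaks_run(self):
        scores = [0.9] * 5 + [None] + [0.9] * 6
        b = conserved_blocks(self.track(scores), 0.8, 10)
        assert b.blocks["c1"] == []

    def test_block_maximality(self):
        scores = [0.7] + [0.9] * 12 + [0.7]
        b = conserved_blocks(self.track(scores), 0.8, 10)
        assert b.blocks["c1"] == [(2, 13)]

    def test_matches_per_base_scan_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            scores = [
                None if rng.random() < 0.2 else float(rng.choice([0.5, 0.85, 0.95]))
                for _ in range(120)
            ]
            got = conserved_blocks(self.track(scores), 0.8, 10).blocks["c1"]
            # oracle: literal per-base run scan
            expected, run = [], None
            for i, s in enumerate(scores, start=1):
                if s is not None and s >= 0.8:
                    run = (run[0], i) if run else (i, i)
                else:
                    if run and run[1] - run[0] + 1 >= 10:
                        expected.append(run)
                    run = None
            if run and run[1] - run[0] + 1 >= 10:
                expected.append(run)
            assert got == expected


class TestClassifySites:
    def setup_method(self):
        #          1        10        20        30
        self.seq = "N" * 9 + "ATGGCTTGA" + "N" * 82
        self.genes = [gene(start=10, end=18, cds=[(10, 18, 0)])]
        self.cis = build_cis_intervals(self.genes)
        self.blocks = conserved_blocks(
            ConservationTrack({"c1": [(i, i, 0.9) for i in range(10, 25)]}), 0.8, 10
        )

    def table(self, pos, ref, alt):
        return pd.DataFrame(
            {"chrom": ["c1"] * len(pos), "pos": pos, "ref": ref, "alt": alt}
        )

    def test_coding_snp_constrained(self):
        t = classify_sites(
            self.table([15], ["T"], ["C"]), self.genes, self.cis, self.blocks,
            {"c1": self.seq},
        )
        assert t["site_class"].iloc[0] == "synonymous"
        assert bool(t["constrained"].iloc[0])

    def test_upstream_snp_cis_regulatory(self):
        t = classify_sites(
            self.table([5], ["A"], ["T"]), self.genes, self.cis, self.blocks,
            {"c1": self.seq},
        )
        assert t["site_class"].iloc[0] == "cis_regulatory"
        assert not bool(t["constrained"].iloc[0])

    def test_distant_intergenic_snp_other(self):
        t = classify_sites(
            self.table([90], ["A"], ["T"]), self.genes, self.cis, self.blocks,
            {"c1": self.seq},
        )
        assert t["site_class"].iloc[0] == "other"

    def test_coding_takes_precedence_over_cis(self):
        # a second gene whose cis interval would cover the first gene's CDS
        # never claims it: genic bases were already excluded from cis
        g2 = gene("g2", start=20, end=40, cds=[(20, 28, 0)])
        genes = self.genes + [g2]
        cis = build_cis_intervals(genes)
        t = classify_sites(
            self.table([15], ["T"], ["C"]), genes, cis, self.blocks,
            {"c1": self.seq},
        )
        assert t["site_class"].iloc[0] == "synonymous"


class TestGeneSnpAssignment:
    def test_cis_and_cds_membership(self):
        genes = [gene(start=5_001, end=6_000, cds=[(5_001, 5_300, 0)])]
        cis = build_cis_intervals(genes)
        t = pd.DataFrame(
            {"chrom": ["c1"] * 3, "pos": [4_500, 5_100, 9_000],
             "ref": ["A"] * 3, "alt": ["T"] * 3}
        )
        assign = gene_snp_assignment(t, genes, cis)
        assert assign["g1"].tolist() == [0, 1]

    def test_shared_cis_interval_assigns_to_both_genes(self):
        g1 = gene("g1", start=5_001, end=5_200)
        g2 = gene("g2", strand="-", start=3_500, end=4_000)
        cis = build_cis_intervals([g1, g2])
        t = pd.DataFrame(
            {"chrom": ["c1"], "pos": [4_500], "ref": ["A"], "alt": ["T"]}
        )
        assign = gene_snp_assignment(t, [g1, g2], cis)
        assert assign["g1"].tolist() == [0] and assign["g2"].tolist() == [0]
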