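from collections import Counter

import numpy as np
import pytest

from platepipe.counting import (
    AMBIGUOUS,
    ASSIGNED,
    NO_FEATURE,
    StrandMode,
    UmiTagError,
    assign_read_to_gene,
    cigar_blocks,
    count_cell,
    count_experiment,
    dedup_umis,
    directional_clusters,
)
from platepipe.core import CellRecord
from platepipe.demux import hamming
from platepipe.features import exon_union
from tests.conftest import make_models, simple_gene, write_sam


class TestCigarBlocks:
    def test_plain_match(self):
        assert cigar_blocks(100, [(0, 50)]) == [(100, 150)]

    def test_soft_clip_and_insertion_ignored(self):
        # 5S 20M 2I 10M -> one block of 30 reference bases
        assert cigar_blocks(10, [(4, 5), (0, 20), (1, 2), (0, 10)]) == [(10, 40)]

    def test_deletion_stays_in_block(self):
        assert cigar_blocks(10, [(0, 10), (2, 5), (0, 10)]) == [(10, 35)]

    def test_intron_splits(self):
        assert cigar_blocks(10, [(0, 10), (3, 500), (0, 20)]) == [
            (10, 20),
            (520, 540),
        ]


SENSE = StrandMode("sense")
ANTI = StrandMode("antisense")
UNSTRANDED = StrandMode("unstranded")


class TestAssignReadToGene:
    def setup_method(self):
        self.models = make_models(
            [
                simple_gene("A", exons=[(99, 300)], strand="+"),
                simple_gene("B", exons=[(250, 600)], strand="+"),
                simple_gene("C", chrom="chr2", exons=[(490, 530)], strand="+"),
            ]
        )

    def test_single_gene_sense(self):
        r = assign_read_to_gene([(120, 170)], "chr1", "+", self.models, SENSE)
        assert r.outcome == ASSIGNED and r.gene_id == "A"

    def test_two_gene_overlap_ambiguous(self):
        r = assign_read_to_gene([(260, 290)], "chr1", "+", self.models, SENSE)
        assert r.outcome == AMBIGUOUS

    def test_spliced_read_second_block_hits(self):
        r = assign_read_to_gene(
            [(10, 20), (500, 520)], "chr2", "+", self.models, SENSE
        )
        assert r.outcome == ASSIGNED and r.gene_id == "C"

    def test_strand_flip(self):
        models = make_models([simple_gene("D", exons=[(0, 100)], strand="-")])
        assert (
            assign_read_to_gene([(10, 50)], "chr1", "+", models, SENSE).outcome
            == NO_FEATURE
        )
        assert (
            assign_read_to_gene([(10, 50)], "chr1", "+", models, ANTI).outcome
            == ASSIGNED
        )

    def test_unknown_chrom_no_feature(self):
        r = assign_read_to_gene([(0, 50)], "chrZ", "+", self.models, SENSE)
        assert r.outcome == NO_FEATURE

    def test_intergenic_no_feature(self):
        r = assign_read_to_gene([(700, 750)], "chr1", "+", self.models, SENSE)
        assert r.outcome == NO_FEATURE

    def test_randomized_nested_loop_oracle(self):
        rng = np.random.default_rng(29)
        genes = []
        for i in range(60):
            ivs = []
            for _ in range(int(rng.integers(1, 4))):
                s = int(rng.integers(0, 3000))
                ivs.append((s, s + int(rng.integers(10, 300))))
            genes.append(
                simple_gene(
                    f"G{i}",
                    chrom=f"chr{int(rng.integers(1, 3))}",
                    strand="+" if rng.integers(0, 2) else "-",
                    exons=exon_union(ivs),
                )
            )
        models = make_models(genes)
        modes = [SENSE, ANTI, UNSTRANDED]
        for trial in range(1200):
            chrom = f"chr{int(rng.integers(1, 3))}"
            strand = "+" if rng.integers(0, 2) else "-"
            n_blocks = int(rng.integers(1, 3))
            blocks = []
            pos = int(rng.integers(0, 3000))
            for _ in range(n_blocks):
                length = int(rng.integers(1, 120))
                blocks.append((pos, pos + length))
                pos += length + int(rng.integers(1, 400))
            mode = modes[trial % 3]
            got = assign_read_to_gene(blocks, chrom, strand, models, mode)
            # independent nested-loop oracle
            candidates = set()
            for g in genes:
                if g.chrom != chrom:
                    continue
                if not mode.compatible(g.strand, strand):
                    continue
                hit = any(
                    bs < ge and be > gs
                    for bs, be in blocks
                    for gs, ge in g.exon_union
                )
                if hit:
                    candidates.add(g.gene_id)
            if len(candidates) == 0:
                assert got.outcome == NO_FEATURE
            elif len(candidates) == 1:
                assert got.outcome == ASSIGNED and got.gene_id in candidates
            else:
                assert got.outcome == AMBIGUOUS


def oracle_directional(counts):
    """Independent directional collapse via an exhaustive pairwise-Hamming
    adjacency table followed by ordered absorption."""
    umis = sorted(counts, key=lambda u: (-counts[u], u))
    adjacent = {
        (a, b)
        for a in umis
        for b in umis
        if a != b and len(a) == len(b) and hamming(a, b) == 1
    }
    kept = []
    for u in umis:
        for k in kept:
            if (k, u) in adjacent and counts[k] >= 2 * counts[u]:
                break
        else:
            kept.append(u)
    return len(kept)


class TestDedupUmis:
    def test_distinct_set(self):
        assert dedup_umis(["AAAA", "AAAA", "CCCC"])[0] == 2

    def test_empty(self):
        assert dedup_umis([]) == (0, 0)

    def test_corrected_le_raw(self):
        raw, corrected = dedup_umis(["AAAA"] * 10 + ["AAAT"])
        assert (raw, corrected) == (2, 1)

    def test_no_absorb_without_support(self):
        # equal support: 2x rule not met, both kept
        raw, corrected = dedup_umis(["AAAA", "AAAT"])
        assert (raw, corrected) == (2, 2)

    def test_idempotent_on_distinct_set(self):
        umis = ["AAAA", "CCCC", "GGGG", "TTTT"]
        raw1, _ = dedup_umis(umis)
        raw2, _ = dedup_umis(set(umis))
        assert raw1 == raw2 == 4

    def test_duplicate_never_changes_counts(self):
        base = ["ACGT", "ACGA", "TTTT"]
        raw0, _ = dedup_umis(base)
        raw1, _ = dedup_umis(base + ["ACGT"])
        assert raw0 == raw1

    def test_novel_umi_adds_one(self):
        base = ["ACGT", "TTTT"]
        raw0, _ = dedup_umis(base)
        raw1, _ = dedup_umis(base + ["GGGG"])
        assert raw1 == raw0 + 1

    def test_directional_oracle_seeded_errors(self):
        rng = np.random.default_rng(41)
        bases = "ACGT"
        for _ in range(30):
            true_umis = [
                "".join(bases[i] for i in rng.integers(0, 4, size=5))
                for _ in range(int(rng.integers(3, 15)))
            ]
            pool = []
            for u in true_umis:
                pool.extend([u] * int(rng.integers(2, 12)))
            # seeded 1-edit errors at low multiplicity
            for u in true_umis:
                if rng.random() < 0.6:
                    p = int(rng.integers(0, 5))
                    err = u[:p] + bases[(bases.index(u[p]) + 1) % 4] + u[p + 1 :]
                    pool.append(err)
            counts = Counter(pool)
            assert len(counts) <= 200
            _, corrected = dedup_umis(pool)
            assert corrected == oracle_directional(counts)

    def test_directional_clusters_partition(self):
        counts = {"AAAA": 10, "AAAT": 2, "CCCC": 3}
        clusters = directional_clusters(counts)
        members = sorted(m for ms in clusters.values() for m in ms)
        assert members == sorted(counts)


CHROMS = {"chr1": 1000, "chr2": 1000, "chrM": 1000}


def _models_abm():
    return make_models(
        [
            simple_gene("A", exons=[(99, 300)], strand="+"),
            simple_gene("B", chrom="chr2", exons=[(0, 400)], strand="+"),
            simple_gene("M", chrom="chrM", exons=[(0, 500)], strand="+",
                        gene_name="mt-x"),
            simple_gene("ERCC-1", chrom="chr1", exons=[(600, 900)], strand="+",
                        biotype="spike_in", is_spike_in=True),
        ]
    )


class TestCountCell:
    def test_hand_computed_fixture(self, tmp_path):
        models = _models_abm()
        sam = write_sam(
            tmp_path / "cell.sam",
            CHROMS,
            [
                ("r1:UMI:AAAA", 0, "chr1", 120, "30M", "A" * 30),
                ("r2:UMI:AAAA", 0, "chr1", 130, "30M", "A" * 30),
                ("r3:UMI:CCCC", 0, "chr1", 140, "30M", "A" * 30),
                ("r4:UMI:AAAA", 0, "chr2", 10, "30M", "A" * 30),
            ],
        )
        result = count_cell(sam, models)
        assert result.per_gene_umi_count == {"A": 2, "B": 1}
        assert result.per_gene_read_count == {"A": 3, "B": 1}
        m = result.metrics
        assert m["total_umis"] == 3
        assert m["reads_mapped_to_genes"] == 4
        assert m["reads_per_umi_mean"] == pytest.approx(4 / 3)
        assert m["reads_per_umi_median"] == 1
        assert m["genes_detected"] == 2

    def test_all_unmapped(self, tmp_path):
        sam = write_sam(
            tmp_path / "cell.sam",
            CHROMS,
            [("r1:UMI:AAAA", 4, "*", 0, "*", "ACGT")],
        )
        result = count_cell(sam, _models_abm())
        assert result.per_gene_umi_count == {}
        m = result.metrics
        assert m["genes_detected"] == 0
        assert m["reads_per_umi_median"] == 0
        assert m["reads_per_umi_mean"] == 0
        assert "no_umis" in result.flags

    def test_spike_in_counted_but_excluded_from_metrics(self, tmp_path):
        sam = write_sam(
            tmp_path / "cell.sam",
            CHROMS,
            [
                ("r1:UMI:AAAA", 0, "chr1", 120, "30M", "A" * 30),
                ("r2:UMI:GGGG", 0, "chr1", 650, "30M", "A" * 30),
            ],
        )
        result = count_cell(sam, _models_abm())
        assert result.per_gene_umi_count == {"A": 1, "ERCC-1": 1}
        assert result.metrics["total_umis"] == 1
        assert result.metrics["genes_detected"] == 1

    def test_mito_umis(self, tmp_path):
        sam = write_sam(
            tmp_path / "cell.sam",
            CHROMS,
            [
                ("r1:UMI:AAAA", 0, "chrM", 10, "30M", "A" * 30),
                ("r2:UMI:CCCC", 0, "chr1", 120, "30M", "A" * 30),
            ],
        )
        m = count_cell(sam, _models_abm()).metrics
        assert m["mito_umis"] == 1 and m["total_umis"] == 2

    def test_secondary_skipped(self, tmp_path):
        sam = write_sam(
            tmp_path / "cell.sam",
            CHROMS,
            [
                ("r1:UMI:AAAA", 0, "chr1", 120, "30M", "A" * 30),
                ("r1:UMI:AAAA", 256, "chr2", 10, "30M", "A" * 30),  # secondary
            ],
        )
        result = count_cell(sam, _models_abm())
        assert result.per_gene_umi_count == {"A": 1}
        assert result.metrics["total_reads"] == 1

    def test_missing_umi_tag_fatal(self, tmp_path):
        sam = write_sam(
            tmp_path / "cell.sam", CHROMS, [("r1", 0, "chr1", 120, "30M", "A" * 30)]
        )
        with pytest.raises(UmiTagError, match="r1"):
            count_cell(sam, _models_abm())

    def test_genes_per_million(self, tmp_path):
        sam = write_sam(
            tmp_path / "cell.sam",
            CHROMS,
            [("r1:UMI:AAAA", 0, "chr1", 120, "30M", "A" * 30)],
        )
        m = count_cell(sam, _models_abm()).metrics
        assert m["genes_per_million_reads"] == pytest.approx(1 / (1 / 1e6))

    def test_same_umi_two_genes_counts_twice(self, tmp_path):
        sam = write_sam(
            tmp_path / "cell.sam",
            CHROMS,
            [
                ("r1:UMI:AAAA", 0, "chr1", 120, "30M", "A" * 30),
                ("r2:UMI:AAAA", 0, "chr2", 10, "30M", "A" * 30),
            ],
        )
        result = count_cell(sam, _models_abm())
        assert result.per_gene_umi_count == {"A": 1, "B": 1}
        assert result.metrics["total_umis"] == 2


class TestCountExperiment:
    def _cells(self, tmp_path, n=3):
        cells = []
        for i in range(n):
            sam = write_sam(
                tmp_path / f"c{i}.sam",
                CHROMS,
                [
                    (f"r{i}:UMI:{'ACGT'[i] * 4}", 0, "chr1", 120, "30M", "A" * 30)
                    for _ in range(1)
                ],
            )
            cells.append(
                CellRecord(f"c{i}", "e", f"BC{i}", alignment_path=sam)
            )
        return cells

    def test_columns_match_single_cell_counts(self, tmp_path):
        models = _models_abm()
        cells = self._cells(tmp_path)
        exp = count_experiment(cells, models)
        for j, cell in enumerate(cells):
            single = count_cell(cell.alignment_path, models)
            col = exp.matrix.counts[:, j]
            for i, gid in enumerate(exp.matrix.gene_ids):
                assert col[i] == single.per_gene_umi_count.get(gid, 0)

    def test_permutation_invariance(self, tmp_path):
        models = _models_abm()
        cells = self._cells(tmp_path)
        exp1 = count_experiment(list(cells), models)
        exp2 = count_experiment(list(reversed(cells)), models)
        assert exp2.matrix.reorder_cells(exp1.matrix.cell_ids) == exp1.matrix

    def test_failed_cell_zeroed_and_flagged(self, tmp_path):
        models = _models_abm()
        cells = self._cells(tmp_path, n=2)
        cells[1].alignment_path = tmp_path / "missing.sam"
        exp = count_experiment(cells, models)
        assert exp.matrix.counts[:, 1].sum() == 0
        assert any(f.startswith("count_failed") for f in cells[1].flags)
        assert exp.matrix.counts[:, 0].sum() > 0
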