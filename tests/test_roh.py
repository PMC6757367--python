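"""Genotype I/O, QC, L_auto, ROH detection (strict + windowed) and summaries."""

import numpy as np
import pandas as pd
import pytest

from gsdiv import (
    GenotypePanel,
    RohParams,
    compute_L_auto,
    detect_roh,
    qc_filter,
    read_plink,
    roh_length_histogram,
    summarize_roh,
    write_plink,
)
from gsdiv.roh import RohSegment

from conftest import make_panel
from oracles import exhaustive_roh, partition_L_auto, random_panel_arrays


class TestPlinkIO:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(5)
        geno = rng.integers(-1, 3, size=(3, 5)).astype(np.int8)
        panel = make_panel(geno, np.arange(1, 6) * 1000)
        write_plink(panel, tmp_path / "fix")
        back = read_plink(tmp_path / "fix")
        assert back.ids == panel.ids
        assert np.array_equal(back.genotypes, panel.genotypes)
        assert np.array_equal(back.snp_map["bp"], panel.snp_map["bp"])

    def test_truncated_bed_payload_errors(self, tmp_path):
        rng = np.random.default_rng(5)
        panel = make_panel(
            rng.integers(0, 3, size=(5, 8)).astype(np.int8), np.arange(1, 9) * 1000
        )
        write_plink(panel, tmp_path / "fix")
        bed = tmp_path / "fix.bed"
        bed.write_bytes(bed.read_bytes()[:-1])
        with pytest.raises(ValueError, match="payload"):
            read_plink(tmp_path / "fix")

    def test_bad_magic_errors(self, tmp_path):
        panel = make_panel(np.zeros((1, 2), dtype=np.int8), [100, 200])
        write_plink(panel, tmp_path / "fix")
        bed = tmp_path / "fix.bed"
        bed.write_bytes(b"\x00\x00\x00" + bed.read_bytes()[3:])
        with pytest.raises(ValueError, match="magic"):
            read_plink(tmp_path / "fix")

    def test_duplicate_fam_id_errors(self, tmp_path):
        panel = make_panel(np.zeros((2, 2), dtype=np.int8), [100, 200], ids=["a", "b"])
        write_plink(panel, tmp_path / "fix")
        fam = tmp_path / "fix.fam"
        lines = fam.read_text().splitlines()
        fam.write_text("\n".join([lines[0], lines[0]]) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_plink(tmp_path / "fix")


class TestQc:
    def _panel_100(self, snp_cols):
        """100 individuals; snp_cols is a list of per-SNP genotype vectors."""
        geno = np.stack(snp_cols, axis=1).astype(np.int8)
        return make_panel(geno, (np.arange(len(snp_cols)) + 1) * 1000)

    def test_call_rate_boundary(self):
        ok = np.ones(100, dtype=np.int8)
        low = ok.copy()
        low[:6] = -1  # 94% called: below the 95% threshold
        edge = ok.copy()
        edge[:5] = -1  # exactly 95%: kept
        panel = self._panel_100([ok, low, edge])
        out, report = qc_filter(panel)
        assert report.n_removed_call_rate == 1
        assert out.n_snps == 2

    def test_maf_boundary_is_strictly_below(self):
        # MAF exactly 0.01 (2 alt alleles in 200) is retained
        exact = np.zeros(100, dtype=np.int8)
        exact[0] = 2
        mono = np.zeros(100, dtype=np.int8)
        common = np.ones(100, dtype=np.int8)
        panel = self._panel_100([exact, mono, common])
        out, report = qc_filter(panel)
        assert report.n_removed_maf == 1  # only the monomorphic SNP
        assert out.n_snps == 2

    def test_individual_call_rate_filter(self):
        geno = np.ones((40, 40), dtype=np.int8)
        geno[0, :3] = -1  # individual 0 at 92.5% < 95%; SNPs stay at 97.5%
        panel = make_panel(geno, (np.arange(40) + 1) * 1000)
        out, report = qc_filter(panel)
        assert report.n_removed_individuals == 1
        assert out.n_individuals == 39

    def test_all_removed_errors(self):
        geno = np.zeros((10, 2), dtype=np.int8)  # both monomorphic
        panel = make_panel(geno, [1000, 2000])
        with pytest.raises(ValueError, match="every SNP"):
            qc_filter(panel)


class TestLAuto:
    def test_no_gap_withheld(self):
        m = pd.DataFrame(
            {"chrom": "1", "snp_id": list("abc"), "bp": [1, 100_001, 200_001],
             "cM": 0.0}
        )
        assert compute_L_auto(m)[1] == 200_000

    def test_one_gap_withheld(self):
        m = pd.DataFrame(
            {"chrom": "1", "snp_id": list("abc"), "bp": [1, 100_001, 400_001],
             "cM": 0.0}
        )
        assert compute_L_auto(m)[1] == 100_000

    def test_single_snp_chromosome_contributes_zero(self):
        m = pd.DataFrame(
            {"chrom": ["1", "1", "2"], "snp_id": list("abc"),
             "bp": [1, 50_001, 10_000], "cM": 0.0}
        )
        per_chrom, total = compute_L_auto(m)
        assert per_chrom["2"] == 0 and total == 50_000

    def test_non_autosomes_excluded(self):
        m = pd.DataFrame(
            {"chrom": ["1", "1", "X", "X"], "snp_id": list("abcd"),
             "bp": [1, 60_001, 1, 60_001], "cM": 0.0}
        )
        assert compute_L_auto(m)[1] == 60_000

    def test_matches_partition_oracle_on_random_maps(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            gaps = rng.integers(10_000, 400_000, size=60)
            bp = np.cumsum(gaps).astype(np.int64)
            m = pd.DataFrame(
                {"chrom": "1", "snp_id": [f"s{i}" for i in range(60)],
                 "bp": bp, "cM": 0.0}
            )
            assert compute_L_auto(m)[1] == partition_L_auto(bp, 150_000)


class TestDetectStrict:
    def test_constructed_positive(self):
        # 20 homozygous SNPs over 1.33 Mb flanked by heterozygotes
        bp = np.concatenate([[1], np.arange(20) * 70_000 + 100_000, [1_600_000]])
        geno = np.full(22, 1, dtype=np.int8)
        geno[1:21] = 0
        segs = detect_roh(make_panel(geno, bp), RohParams(mode="strict"))
        assert len(segs) == 1
        assert segs[0].n_snps == 20
        assert (segs[0].start_bp, segs[0].end_bp) == (100_000, 19 * 70_000 + 100_000)

    def test_too_short_span_rejected(self):
        # 20 homozygous SNPs spanning only ~800 kb
        bp = np.arange(20) * 42_000 + 1
        geno = np.zeros(20, dtype=np.int8)
        segs = detect_roh(make_panel(geno, bp), RohParams(mode="strict"))
        assert segs == []

    def test_gap_splits_run(self):
        # 30 homozygous SNPs with a 200 kb gap after the 15th
        bp = np.concatenate(
            [np.arange(15) * 70_000, np.arange(15) * 70_000 + 15 * 70_000 + 200_000]
        ) + 1
        geno = np.full(30, 2, dtype=np.int8)
        segs = detect_roh(make_panel(geno, bp), RohParams(mode="strict"))
        # each half: 15 SNPs spanning 14*70 kb = 980 kb < 1000 kb -> rejected
        assert segs == []
        relaxed = RohParams(mode="strict", min_length_kb=900)
        segs2 = detect_roh(make_panel(geno, bp), relaxed)
        assert len(segs2) == 2 and all(s.n_snps == 15 for s in segs2)

    def test_missing_breaks_a_run(self):
        bp = np.arange(40) * 70_000 + 1
        geno = np.zeros(40, dtype=np.int8)
        geno[20] = -1
        segs = detect_roh(make_panel(geno, bp), RohParams(mode="strict"))
        assert len(segs) == 2
        assert {s.n_snps for s in segs} == {20, 19}

    @pytest.mark.parametrize(
        "params",
        [
            RohParams(mode="strict"),
            RohParams(mode="strict", min_snps=5, min_length_kb=300,
                      density_kb_per_snp=120),
        ],
        ids=["default-thresholds", "relaxed-thresholds"],
    )
    def test_matches_exhaustive_oracle_on_random_panels(self, params):
        """Strict detector equals pairwise exhaustive enumeration."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n_ind = int(rng.integers(1, 11))
            n_snp = int(rng.integers(30, 201))
            geno, bp = random_panel_arrays(rng, n_ind, n_snp)
            panel = make_panel(geno, bp)
            segs = detect_roh(panel, params)
            got = {
                (s.individual, s.start_bp, s.end_bp, s.n_snps) for s in segs
            }
            expected = set()
            for i, iid in enumerate(panel.ids):
                for (s_idx, e_idx) in exhaustive_roh(geno[i], bp, params):
                    expected.add(
                        (iid, int(bp[s_idx]), int(bp[e_idx]), e_idx - s_idx + 1)
                    )
            assert got == expected

    def test_emitted_segments_satisfy_all_constraints(self):
        rng = np.random.default_rng(4)
        params = RohParams(mode="strict", min_snps=5, min_length_kb=300,
                           density_kb_per_snp=120)
        geno, bp = random_panel_arrays(rng, 8, 150)
        panel = make_panel(geno, bp)
        for seg in detect_roh(panel, params):
            assert seg.n_snps >= params.min_snps
            assert seg.length_bp >= params.min_length_bp
            assert seg.length_bp / seg.n_snps <= params.density_bp_per_snp
            idx = np.flatnonzero((bp >= seg.start_bp) & (bp <= seg.end_bp))
            assert np.all(np.diff(bp[idx]) <= params.max_gap_bp)


class TestDetectWindowed:
    def test_tolerates_one_heterozygote(self):
        bp = np.arange(40) * 70_000 + 1
        geno = np.zeros(40, dtype=np.int8)
        geno[20] = 1  # one het inside an otherwise long homozygous stretch
        strict = detect_roh(make_panel(geno, bp), RohParams(mode="strict"))
        windowed = detect_roh(make_panel(geno, bp), RohParams(mode="windowed"))
        assert len(windowed) == 1  # het absorbed
        assert len(strict) == 2
        assert windowed[0].n_snps == 40

    def test_converges_to_strict_without_missing(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            geno, bp = random_panel_arrays(rng, 4, 120, missing_prob=0.0)
            panel = make_panel(geno, bp)
            base = dict(min_snps=5, min_length_kb=300, density_kb_per_snp=120)
            strict = detect_roh(panel, RohParams(mode="strict", **base))
            tight = RohParams(
                mode="windowed", window_max_het=0, window_max_missing=0,
                window_hit_threshold=1e-9, window_snps=1, **base
            )
            assert detect_roh(panel, tight) == strict

    def test_short_chromosome_is_skipped(self, caplog):
        bp = np.arange(5) * 50_000 + 1
        geno = np.zeros(5, dtype=np.int8)
        with caplog.at_level("WARNING", logger="gsdiv.roh"):
            segs = detect_roh(make_panel(geno, bp), RohParams(mode="windowed"))
        assert segs == []
        assert any("window" in r.message for r in caplog.records)


class TestSummaries:
    def test_f_roh_fraction(self, small_snp_map):
        segs = [RohSegment("i1", "1", 1, 2_000_000, 20)]
        # L_auto of the 30-SNP 70 kb map = 29*70 kb
        summary = summarize_roh(segs, small_snp_map, ids=["i1", "i2"])
        assert summary.L_auto_bp == 29 * 70_000
        assert summary.per_individual.loc["i1", "F_ROH"] == pytest.approx(
            2_000_000 / (29 * 70_000)
        )
        assert summary.per_individual.loc["i2", "F_ROH"] == 0.0
        assert summary.per_individual.loc["i2", "n_roh"] == 0

    def test_mean_length(self, small_snp_map):
        segs = [
            RohSegment("i1", "1", 1, 1_200_000, 16),
            RohSegment("i1", "1", 1, 1_800_000, 20),
        ]
        summary = summarize_roh(segs, small_snp_map)
        assert summary.per_individual.loc["i1", "L_ROH_mean_kb"] == pytest.approx(
            1500.0, rel=1e-3
        )

    def test_f_roh_monotone_under_disjoint_addition(self, small_snp_map):
        seg1 = [RohSegment("i1", "1", 1, 1_000_000, 15)]
        seg2 = seg1 + [RohSegment("i1", "1", 1_200_001, 1_900_000, 12)]
        f1 = summarize_roh(seg1, small_snp_map).per_individual.loc["i1", "F_ROH"]
        f2 = summarize_roh(seg2, small_snp_map).per_individual.loc["i1", "F_ROH"]
        assert 0 <= f1 <= f2 <= 1

    def test_histogram_half_open_classes(self):
        mk = lambda kb: RohSegment("i1", "1", 1, int(kb * 1000), 10)
        counts = roh_length_histogram(
            [mk(1100), mk(2500), mk(9000)], (1000, 2000, 4000, 8000, 16000)
        )
        assert counts.loc["i1"].tolist() == [1, 1, 0, 1]

    def test_histogram_edge_goes_to_upper_class(self):
        seg = RohSegment("i1", "1", 1, 2_000_000, 10)  # exactly 2000 kb
        counts = roh_length_histogram([seg], (1000, 2000, 4000))
        assert counts.loc["i1"].tolist() == [0, 1]

    def test_histogram_empty(self):
        counts = roh_length_histogram([], (1000, 2000))
        assert counts.empty
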