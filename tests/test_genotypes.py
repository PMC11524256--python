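"""Genotype container, VCF/TSV I/O, masking and filtering rules."""

import numpy as np
import pandas as pd
import pytest

from orchardkin.genotypes import (
    MISSING,
    FilterConfig,
    GenotypeMatrix,
    allele_frequencies,
    apply_filters,
    breadth_of_coverage,
    concat_samples,
    filter_loci,
    filter_samples,
    mask_low_confidence,
    read_dosage_tsv,
    read_manifest,
    read_vcf,
    select_high_breadth,
    write_dosage_tsv,
    write_vcf,
)

from conftest import make_gm


class TestGenotypeMatrix:
    def test_rejects_bad_dosage_values(self):
        with pytest.raises(ValueError, match="dosage"):
            make_gm([[0, 3]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(
                sample_ids=["a", "a"],
                roles=["parent"] * 2,
                crop_labels=[""] * 2,
                locus_ids=["l0"],
                dosage=np.zeros((2, 1), dtype=np.int8),
            )

    def test_rejects_negative_depth(self):
        with pytest.raises(ValueError, match="negative"):
            make_gm([[0, 1]], depth=np.array([[-1.0, 5.0]]))


class TestVcfIo:
    def _write_vcf(self, path, lines):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
        )
        path.write_text(header + "".join(lines))

    def test_gt_to_dosage_and_missing(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_vcf(
            vcf,
            [
                "1\t1\tlocA\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
                "1\t2\tlocB\tA\tC\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n",
            ],
        )
        gm = read_vcf(vcf)
        assert gm.locus_ids == ["locA", "locB"]
        np.testing.assert_array_equal(gm.dosage[:, 0], [0, 1, 2])
        assert gm.dosage[0, 1] == MISSING

    def test_multiallelic_flagged_and_removed(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_vcf(
            vcf,
            [
                "1\t1\tbi\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
                "1\t2\ttri\tA\tC,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
            ],
        )
        gm = read_vcf(vcf)
        assert list(gm.n_alleles) == [2, 3]
        filtered, report = filter_loci(gm, FilterConfig(maf_min=0.0))
        assert filtered.locus_ids == ["bi"]
        assert report["removed_multiallelic"] == 1

    def test_manifest_roles_and_missing_sample_error(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_vcf(vcf, ["1\t1\tx\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"])
        mf = pd.DataFrame(
            {"sample_id": ["A", "B"], "role": ["parent", "seedling"], "crop_label": ["", "c1"]}
        )
        with pytest.warns(UserWarning, match="absent from manifest"):
            gm = read_vcf(vcf, mf)
        assert gm.roles == ["parent", "seedling", "reference"]
        bad = pd.DataFrame({"sample_id": ["Z"], "role": ["parent"], "crop_label": [""]})
        with pytest.raises(ValueError, match="Z"):
            read_vcf(vcf, bad)

    def test_vcf_round_trip_bit_exact(self, tmp_path, rng):
        dosage = rng.integers(-1, 3, size=(5, 40)).astype(np.int8)
        gm = make_gm(dosage)
        write_vcf(gm, tmp_path / "rt.vcf")
        back = read_vcf(tmp_path / "rt.vcf")
        np.testing.assert_array_equal(back.dosage, gm.dosage)
        assert back.locus_ids == gm.locus_ids

    def test_dosage_tsv_round_trip(self, tmp_path, rng):
        dosage = rng.integers(-1, 3, size=(4, 10)).astype(np.int8)
        gm = make_gm(dosage)
        write_dosage_tsv(gm, tmp_path / "d.tsv")
        back = read_dosage_tsv(tmp_path / "d.tsv")
        np.testing.assert_array_equal(back.dosage, gm.dosage)


class TestMasking:
    def test_depth_and_gq_boundaries(self):
        # depth 4 masked even at high GQ; depth 5 & GQ 20 retained (strict <)
        gm = make_gm(
            [[1, 1, 1]],
            depth=np.array([[4.0, 5.0, 10.0]]),
            gq=np.array([[99.0, 20.0, 19.0]]),
        )
        out = mask_low_confidence(gm, FilterConfig())
        np.testing.assert_array_equal(out.dosage[0], [MISSING, 1, MISSING])
        # original untouched
        assert gm.dosage[0, 0] == 1

    def test_no_depth_gq_noop_with_warning(self):
        gm = make_gm([[0, 1, 2]])
        with pytest.warns(UserWarning, match="masking skipped"):
            out = mask_low_confidence(gm, FilterConfig())
        np.testing.assert_array_equal(out.dosage, gm.dosage)


class TestSampleFilter:
    def test_strictly_more_than_threshold_dropped(self):
        d = np.zeros((2, 100), dtype=np.int8)
        d[0, :41] = MISSING  # 41% -> dropped
        d[1, :40] = MISSING  # exactly 40% -> kept
        d[:, 50] = 1  # keep loci polymorphic, irrelevant here
        gm = make_gm(d)
        out, report = filter_samples(gm, FilterConfig())
        assert out.sample_ids == ["s1"]
        assert report.sample_id.tolist() == ["s0"]
        assert report.missing_fraction.iloc[0] == pytest.approx(0.41)

    def test_complete_matrix_identity(self):
        gm = make_gm([[0, 1], [2, 1]])
        out, report = filter_samples(gm, FilterConfig())
        assert out.sample_ids == gm.sample_ids
        assert report.empty


class TestLocusFilter:
    def test_each_rule_and_survivor_counts(self):
        # 6 samples x 10 loci; loci 0-3 each violate exactly one rule
        n = 6
        d = np.ones((n, 10), dtype=np.int8)  # het everywhere as baseline
        d[:, 0] = [0, 0, 0, 0, 0, 1]  # MAF = 1/12 = 0.083 ok; make rarer:
        d[:, 0] = 0  # monomorphic -> MAF 0 < 0.05
        d[:, 1] = [MISSING, MISSING, MISSING, 0, 1, 1]  # 50% missing > 40%
        d[:, 2] = [1, 1, 1, 1, 1, 0]  # 5/6 = 83% het > 70%
        # locus 3 multi-allelic via n_alleles
        d[:, 4:] = np.array([0, 0, 1, 1, 2, 2])[:, None]  # clean loci, MAF 0.5, het 1/3
        d[:, 3] = d[:, 4]
        nall = np.full(10, 2)
        nall[3] = 3
        gm = make_gm(d, n_alleles=nall)
        out, report = filter_loci(gm, FilterConfig())
        assert out.n_loci == 6
        assert report["removed_maf"] == 1
        assert report["removed_missing"] == 1
        assert report["removed_het"] == 1
        assert report["removed_multiallelic"] == 1

    def test_maf_below_threshold_dropped(self):
        # alt frequency 0.04 at 25 diploid samples: one het among 25
        d = np.zeros((25, 2), dtype=np.int8)
        d[0, 0] = 2  # p = 2/50 = 0.04 -> dropped
        d[:12, 1] = 1  # p = 12/50 = 0.24 -> kept
        gm = make_gm(d)
        out, report = filter_loci(gm, FilterConfig())
        assert out.locus_ids == ["l1"]
        assert report["removed_maf"] == 1

    def test_filtering_idempotent(self, rng):
        d = rng.integers(-1, 3, size=(30, 50)).astype(np.int8)
        gm = make_gm(d)
        once, _ = filter_loci(gm, FilterConfig())
        twice, rep = filter_loci(once, FilterConfig())
        assert twice.locus_ids == once.locus_ids
        np.testing.assert_array_equal(twice.dosage, once.dosage)
        out1, _ = filter_samples(gm, FilterConfig())
        out2, _ = filter_samples(out1, FilterConfig())
        assert out2.sample_ids == out1.sample_ids


class TestToyFilterSuite:
    def test_full_qc_on_hand_built_matrix(self):
        """Every rule exercised once on a 6-sample x 10-locus toy with exact survivors."""
        n = 6
        d = np.array([[0, 0, 1, 1, 2, 2]]).T.repeat(10, axis=1).astype(np.int8)
        depth = np.full((n, 10), 30.0)
        gq = np.full((n, 10), 99.0)
        depth[0, 0] = 4  # masked by depth
        gq[1, 1] = 19  # masked by GQ
        # locus 2: monomorphic -> MAF < 0.05 among remaining samples
        d[:, 2] = [0, 0, 0, 0, 0, 0]
        # locus 3: > 40% missing
        d[:, 3] = [MISSING, MISSING, MISSING, 0, 1, 1]
        # locus 4: > 70% het
        d[:, 4] = [1, 1, 1, 1, 1, 0]
        # sample s5: 50% missing > 40%
        d[5, [0, 1, 6, 7, 8]] = MISSING
        nall = np.full(10, 2)
        nall[5] = 3  # locus 5 multi-allelic
        gm = make_gm(d, depth=depth, gq=gq, n_alleles=nall)
        out, report = apply_filters(gm, FilterConfig())
        assert [r["sample_id"] for r in report["samples_removed"]] == ["s5"]
        assert out.sample_ids == ["s0", "s1", "s2", "s3", "s4"]
        assert out.locus_ids == ["l0", "l1", "l6", "l7", "l8", "l9"]
        # masked cells became missing before locus stats
        assert out.dosage[0, 0] == MISSING
        assert out.dosage[1, 1] == MISSING


class TestAlleleFrequencies:
    def test_basic_and_missing_handling(self):
        gm = make_gm([[0], [1], [2]])
        af = allele_frequencies(gm)
        assert af.freq[0] == pytest.approx(0.5)
        gm2 = make_gm([[2], [2], [MISSING]])
        af2 = allele_frequencies(gm2)
        assert af2.freq[0] == pytest.approx(1.0)
        assert not af2.informative[0]  # fixed in subset

    def test_zero_call_locus_flagged_not_zero(self):
        gm = make_gm([[MISSING], [MISSING]])
        af = allele_frequencies(gm)
        assert np.isnan(af.freq[0])
        assert not af.informative[0]

    def test_binomial_sampling_consistency(self, rng):
        # HWE draw at p = 0.3: estimate within 3 SE
        n, p = 2000, 0.3
        dosage = rng.binomial(2, p, size=(n, 1)).astype(np.int8)
        af = allele_frequencies(make_gm(dosage))
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(af.freq[0] - p) < 3 * se

    def test_union_frequency_between_subsets(self, rng):
        d = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        gm = make_gm(d)
        a = allele_frequencies(gm.take_samples(range(0, 15)))
        b = allele_frequencies(gm.take_samples(range(15, 40)))
        u = allele_frequencies(gm)
        lo = np.minimum(a.freq, b.freq)
        hi = np.maximum(a.freq, b.freq)
        assert ((u.freq >= lo - 1e-12) & (u.freq <= hi + 1e-12)).all()


class TestBreadth:
    def test_inclusive_threshold(self):
        d = np.zeros((3, 100), dtype=np.int8)
        d[0, :20] = MISSING  # breadth exactly 0.8
        d[1, :] = MISSING  # breadth 0
        gm = make_gm(d)
        assert breadth_of_coverage(gm, "s0") == pytest.approx(0.8)
        assert breadth_of_coverage(gm, "s1") == 0.0
        assert breadth_of_coverage(gm, "s2") == 1.0
        kept = select_high_breadth(gm, 0.8)
        assert kept.sample_ids == ["s0", "s2"]

    def test_unknown_sample_errors(self):
        with pytest.raises(KeyError):
            breadth_of_coverage(make_gm([[0]]), "nope")


def test_concat_samples_requires_matching_loci():
    a = make_gm([[0, 1]])
    b = GenotypeMatrix(
        sample_ids=["x"], roles=["parent"], crop_labels=[""], locus_ids=["other", "l1"],
        dosage=np.zeros((1, 2), dtype=np.int8),
    )
    with pytest.raises(ValueError, match="locus"):
        concat_samples(a, b)


def test_read_manifest_validates(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("sample_id\trole\ncrop1\tparent\n")
    mf = read_manifest(p)
    assert mf.crop_label.tolist() == [""]
    p.write_text("sample_id\trole\nx\twizard\n")
    with pytest.raises(ValueError, match="unknown roles"):
        read_manifest(p)
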