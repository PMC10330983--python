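"""Variant loading, hard/MAF filtering, ts/tv, and annotation."""

import numpy as np
import pandas as pd
import pytest

from sweepscan import vario
from sweepscan.vario import CODON_TABLE, GeneModel, NonsynSynSummary

from conftest import make_table


def write_toy_vcf(path, records, samples=("s1", "s2")):
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="x">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="x">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="x">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">',
        "##contig=<ID=chr1,length=100000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines += records
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadVcf:
    def test_empty_vcf_yields_empty_table(self, tmp_path):
        p = write_toy_vcf(tmp_path / "e.vcf", [])
        t = vario.read_vcf(p)
        assert t.n_sites == 0 and t.n_samples == 2

    def test_three_records_two_samples(self, tmp_path):
        recs = [
            f"chr1\t{pos}\t.\tA\tG\t50\tPASS\tQD=20;FS=1;MQ=50\tGT:GQ\t0/1:99\t1/1:99"
            for pos in (100, 200, 300)]
        t = vario.read_vcf(write_toy_vcf(tmp_path / "t.vcf", recs))
        assert t.genotypes.shape == (3, 2, 2)
        assert t.alt_dosage().tolist() == [[1, 2]] * 3

    def test_multiallelic_excluded_and_counted(self, tmp_path):
        recs = [
            "chr1\t100\t.\tA\tG,T\t50\tPASS\tQD=20;FS=1;MQ=50\tGT:GQ\t0/1:99\t1/1:99",
            "chr1\t200\t.\tA\tG\t50\tPASS\tQD=20;FS=1;MQ=50\tGT:GQ\t0/0:99\t0/1:99"]
        t = vario.read_vcf(write_toy_vcf(tmp_path / "m.vcf", recs))
        assert t.n_sites == 1
        assert t.n_skipped_multiallelic == 1

    def test_pop_map_sample_missing_raises(self, tmp_path):
        p = write_toy_vcf(tmp_path / "p.vcf", [])
        with pytest.raises(KeyError):
            vario.read_vcf(p, {"absent": "popX"})


class TestHardFilters:
    def test_low_qd_site_removed(self):
        t = make_table([[(0, 1)]], qd=1.5, fs=10.0, mq=60.0)
        out, rep = vario.apply_hard_filters(t)
        assert out.n_sites == 0 and rep.n_failed_sites == 1

    def test_boundary_values_retained(self):
        # thresholds are strict inequalities: QD=2.0, FS=60.0, MQ=40.0 pass
        t = make_table([[(0, 1)]], qd=2.0, fs=60.0, mq=40.0)
        out, rep = vario.apply_hard_filters(t)
        assert out.n_sites == 1 and rep.n_failed_sites == 0

    def test_gq_masking_boundary(self):
        gq = np.array([[19.0, 20.0]])
        t = make_table([[(0, 1), (0, 1)]], gq=gq)
        out, rep = vario.apply_hard_filters(t)
        assert out.genotypes[0, 0].tolist() == [-1, -1]
        assert out.genotypes[0, 1].tolist() == [0, 1]
        assert rep.n_genotypes_masked == 1

    def test_missing_info_fails_closed(self):
        t = make_table([[(0, 1)]], qd=np.nan)
        out, _ = vario.apply_hard_filters(t)
        assert out.n_sites == 0

    def test_idempotent(self, sweep_cohort):
        _, table, _ = sweep_cohort
        once, _ = vario.apply_hard_filters(table)
        twice, rep = vario.apply_hard_filters(once)
        assert rep.n_failed_sites == 0 and rep.n_genotypes_masked == 0
        assert np.array_equal(once.genotypes, twice.genotypes)


class TestMafFilter:
    @pytest.mark.parametrize("alt_count,kept", [(1, True), (0, False), (10, True)])
    def test_boundaries_10_diploids(self, alt_count, kept):
        # ALT count 1 of 20 alleles is MAF = 0.05 exactly: retained (strict <)
        pairs = []
        remaining = alt_count
        for _ in range(10):
            a = 1 if remaining >= 1 else 0
            b = 1 if remaining >= 2 else 0
            remaining -= a + b
            pairs.append((a, b))
        t = make_table([pairs])
        assert vario.maf_filter(t, 0.05).n_sites == (1 if kept else 0)

    def test_all_missing_site_removed(self):
        t = make_table([[(-1, -1), (-1, -1)]])
        assert vario.maf_filter(t, 0.05).n_sites == 0


class TestTsTv:
    @pytest.mark.parametrize("refs,alts,expected", [
        (list("ACA"), list("GTC"), 2.0),          # A>G, C>T transitions; A>C tv
        (list("AGCTAG"), list("GATCCT"), 2.0),    # 4 ts, 2 tv
    ])
    def test_ratio(self, refs, alts, expected):
        t = make_table([[(0, 1)]] * len(refs), ref=refs, alt=alts)
        assert vario.tstv_ratio(t) == pytest.approx(expected)

    def test_no_transitions(self):
        t = make_table([[(0, 1)]], ref=["A"], alt=["T"])
        assert vario.tstv_ratio(t) == 0.0

    def test_no_transversions_signalled(self):
        t = make_table([[(0, 1)]], ref=["A"], alt=["G"])
        with pytest.raises(ZeroDivisionError):
            vario.tstv_ratio(t)


@pytest.fixture
def toy_genes():
    genes = pd.DataFrame(
        [("g1", "chr1", 10_000, 20_000, "+")],
        columns=["gene_id", "chrom", "start", "end", "strand"])
    cds = {"g1": [(12_000, 12_300, 0), (15_000, 15_600, 0)]}
    return GeneModel(genes=genes, cds=cds, flank=1000)


class TestClassifySites:
    @pytest.mark.parametrize("pos1,expected", [
        (12_100, "exonic"),       # inside CDS segment
        (11_000, "UTR"),          # transcribed, 5' of first CDS base
        (13_000, "intronic"),     # between CDS segments
        (9_501, "upstream"),      # 500 bp 5' of gene start, flank 1000
        (20_500, "downstream"),
        (25_000, "intergenic"),   # 5 kb from the gene
    ])
    def test_precedence_classes(self, toy_genes, pos1, expected):
        t = make_table([[(0, 1)]], positions=[pos1])
        labels, _ = vario.classify_sites(t, toy_genes)
        assert labels.iloc[0] == expected

    def test_unknown_chromosome_is_intergenic(self, toy_genes):
        t = make_table([[(0, 1)]], chrom="chrZ")
        labels, _ = vario.classify_sites(t, toy_genes)
        assert labels.iloc[0] == "intergenic"

    def test_partition_sums_to_total(self, sweep_cohort, fixture_dir):
        _, table, _ = sweep_cohort
        *_, paths = fixture_dir
        genes = vario.read_gff(paths["gff"])
        sub = table.take_sites(np.arange(0, table.n_sites, 10))
        # wrong chromosome lengths don't matter: classes must still partition
        labels, props = vario.classify_sites(sub, genes)
        assert len(labels) == sub.n_sites
        assert props.sum() == pytest.approx(1.0)


class TestConsequence:
    def _setup(self, tmp_path, codon, pos_in_codon, alt):
        """One gene with a single 3-bp CDS holding `codon` on chr1:1000."""
        seq = "T" * 1000 + codon + "T" * 1000
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\n" + seq + "\n")
        genes = pd.DataFrame([("g1", "chr1", 900, 1100, "+")],
                             columns=["gene_id", "chrom", "start", "end", "strand"])
        model = GeneModel(genes=genes, cds={"g1": [(1000, 1003, 0)]}, flank=100)
        t = make_table([[(0, 1)]], positions=[1001 + pos_in_codon],
                       ref=[codon[pos_in_codon]], alt=[alt])
        return t, model, fa

    def test_third_position_synonymous(self, tmp_path):
        t, model, fa = self._setup(tmp_path, "GCT", 2, "C")  # GCT->GCC: Ala->Ala
        calls, s = vario.consequence(t, model, fa)
        assert calls.iloc[0] == "synonymous"

    def test_first_position_nonsynonymous(self, tmp_path):
        t, model, fa = self._setup(tmp_path, "GCT", 0, "A")  # GCT->ACT: Ala->Thr
        calls, _ = vario.consequence(t, model, fa)
        assert calls.iloc[0] == "nonsynonymous"

    def test_ref_mismatch_raises(self, tmp_path):
        t, model, fa = self._setup(tmp_path, "GCT", 0, "A")
        t.sites.loc[0, "ref"] = "T"
        with pytest.raises(vario.RefMismatchError):
            vario.consequence(t, model, fa)

    def test_ratio_from_counts(self):
        summary = NonsynSynSummary(95_484, 131_946, 0)
        assert round(summary.ratio, 3) == 0.724

    def test_agrees_with_full_cds_translation_oracle(self, fixture_dir):
        """Rebuild and translate the whole CDS with Biopython per site."""
        from Bio.Seq import Seq
        from pyfaidx import Fasta

        cfg, table, _, paths = fixture_dir
        genes = vario.read_gff(paths["gff"])
        fa = Fasta(str(paths["fasta"]))
        calls, _ = vario.consequence(table, genes, paths["fasta"])
        rng = np.random.default_rng(0)
        coding_rows = [i for i in range(table.n_sites) if calls.iloc[i] != "noncoding"]
        assert coding_rows, "fixture produced no coding sites"
        for i in rng.choice(len(table.sites), size=100, replace=False).tolist() + coding_rows:
            row = table.sites.iloc[i]
            pos0 = row.pos - 1
            expected = "noncoding"
            for g in genes.genes.itertuples():
                segs = sorted(genes.cds[g.gene_id])
                if g.chrom != row.chrom or not any(s <= pos0 < e for s, e, _ in segs):
                    continue
                ref_cds, alt_cds = [], []
                for s, e, _ in segs:
                    chunk = str(fa[row.chrom][s:e])
                    if s <= pos0 < e:
                        k = pos0 - s
                        alt_chunk = chunk[:k] + row.alt + chunk[k + 1:]
                    else:
                        alt_chunk = chunk
                    ref_cds.append(chunk)
                    alt_cds.append(alt_chunk)
                ref_seq, alt_seq = Seq("".join(ref_cds)), Seq("".join(alt_cds))
                if g.strand == "-":
                    ref_seq, alt_seq = (ref_seq.reverse_complement(),
                                        alt_seq.reverse_complement())
                expected = ("synonymous" if ref_seq.translate() == alt_seq.translate()
                            else "nonsynonymous")
                break
            assert calls.iloc[i] == expected, f"site {row.chrom}:{row.pos}"


def test_codon_table_matches_biopython():
    from Bio.Seq import Seq

    for codon, aa in CODON_TABLE.items():
        assert str(Seq(codon).translate()) == aa
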