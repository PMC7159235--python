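"""Format readers/writers and the coordinate-convention boundary."""

import pytest

from enloft import genomic_io as gio
from enloft.genomic_io import GenomicInterval
from enloft.synthetic_fixtures import write_vcf


def test_interval_invariants():
    iv = GenomicInterval("chr1", 100, 200)
    assert iv.length == 100
    assert iv.id == "chr1:100-200"
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 100)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (("chr1", 0, 100), ("chr1", 40, 140), 60),
        (("chr1", 0, 100), ("chr2", 40, 140), 0),
        (("chr1", 0, 100), ("chr1", 100, 200), 0),
        (("chr1", 100, 200), ("chr1", 50, 300), 100),
    ],
)
def test_interval_overlap(a, b, expected):
    assert GenomicInterval(*a).overlap(GenomicInterval(*b)) == expected


def test_parse_jeme_compound_key():
    iv, gene = gio.parse_jeme_key("chr1:100-200$GENE1")
    assert iv == GenomicInterval("chr1", 100, 200)
    assert gene == "GENE1"
    with pytest.raises(ValueError):
        gio.parse_interval_id("not-a-coordinate")


def test_read_enhancer_network_merges_tissues(tmp_path):
    """Repeated (enhancer, gene) rows merge into one edge with union tissues."""
    p = tmp_path / "net.tsv"
    p.write_text(
        "chr1:0-100\tG1\ttissueA\n"
        "chr1:0-100\tG1\ttissueB\n"
        "chr1:0-100\tG2\ttissueC\n"
    )
    table = gio.read_enhancer_network(
        p, {"tissueA": "A", "tissueB": "B", "tissueC": "C"}
    )
    by_gene = {e.gene_id: e for e in table.edges}
    assert set(by_gene) == {"G1", "G2"}
    assert by_gene["G1"].tissues == {"A", "B"}
    assert by_gene["G2"].tissues == {"C"}
    assert len(table.enhancers) == 1


def test_read_enhancer_network_discards_unmapped(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("chr1:0-100$G1\tweird_cell\n")
    table = gio.read_enhancer_network(p, {"known": "known"})
    assert table.edges == []
    assert table.n_discarded == 1


def test_read_enhancer_network_errors(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    with pytest.raises(ValueError, match="empty"):
        gio.read_enhancer_network(empty, {})
    bad = tmp_path / "bad.tsv"
    bad.write_text("chr1:zz-100\tG1\tt\n")
    with pytest.raises(ValueError, match="line 1"):
        gio.read_enhancer_network(bad, {"t": "t"})


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=100000>\n"
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
    '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def test_read_deletions_symbolic_coordinates(tmp_path):
    """Symbolic <DEL> POS=101 END=200 becomes the 0-based span [100, 200)."""
    p = tmp_path / "d.vcf"
    p.write_text(
        VCF_HEADER + "chr1\t101\tD1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\tGT\t1|1\t0|1\n"
    )
    calls = gio.read_deletions(p).calls
    assert len(calls) == 1
    assert calls[0].interval == GenomicInterval("chr1", 100, 200)
    assert calls[0].interval.length == 100
    assert calls[0].genotypes == {"S1": "1/1", "S2": "0/1"}
    assert calls[0].hom_samples() == ["S1"]


def test_read_deletions_explicit_allele(tmp_path):
    """REF=ACGT, ALT=A at POS=10 deletes the 3 bp span [10, 13)."""
    p = tmp_path / "d.vcf"
    p.write_text(
        VCF_HEADER + "chr1\t10\tD1\tACGT\tA\t.\tPASS\t.\tGT\t0|0\t1|1\n"
    )
    calls = gio.read_deletions(p).calls
    assert calls[0].interval == GenomicInterval("chr1", 10, 13)


def test_read_deletions_skips_and_filters(tmp_path):
    p = tmp_path / "d.vcf"
    p.write_text(
        VCF_HEADER
        + "chr1\t101\tNOEND\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL\tGT\t1|1\t1|1\n"
        + "chr1\t201\tINS\tN\t<INS>\t.\tPASS\tSVTYPE=INS;END=300\tGT\t1|1\t1|1\n"
        + "chr1\t301\tFAIL\tN\t<DEL>\t.\tq10\tSVTYPE=DEL;END=400\tGT\t1|1\t1|1\n"
    )
    result = gio.read_deletions(p, pass_only=True)
    assert result.calls == []
    assert result.n_skipped_unresolvable == 1
    assert result.n_ignored_non_deletion == 1
    # permissive FILTER policy keeps the non-PASS record
    assert len(gio.read_deletions(p, pass_only=False).calls) == 1


def test_read_deletions_multiallelic_split(tmp_path):
    p = tmp_path / "d.vcf"
    p.write_text(
        VCF_HEADER + "chr1\t10\tM\tACGTACG\tA,ACGT\t.\tPASS\t.\tGT\t1|2\t2|2\n"
    )
    calls = gio.read_deletions(p).calls
    assert len(calls) == 2
    # allele 1 deletes 6 bp, allele 2 deletes 3 bp
    assert calls[0].interval == GenomicInterval("chr1", 10, 16)
    assert calls[1].interval == GenomicInterval("chr1", 13, 16)
    # genotypes referencing the other allele count as non-carrier
    assert calls[0].genotypes == {"S1": "0/1", "S2": "0/0"}
    assert calls[1].genotypes == {"S1": "0/1", "S2": "1/1"}


def test_read_bed(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("chr1\t100\t200\nchr1\t300\t400\tnamed\n")
    records = gio.read_bed(p)
    assert records[0].interval == GenomicInterval("chr1", 100, 200)
    assert records[0].name is None
    assert records[1].name == "named"
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t100\t200\nchr1\t200\t100\n")
    with pytest.raises(ValueError, match="line 2"):
        gio.read_bed(bad)


def test_bed_round_trip(tmp_path):
    records = [
        gio.BedRecord(GenomicInterval("chr1", 0, 10), "a"),
        gio.BedRecord(GenomicInterval("chr2", 5, 500), None),
    ]
    p = tmp_path / "rt.bed"
    gio.write_bed(p, records, header=["meta"])
    assert gio.read_bed(p) == records


def test_read_scalar_table(tmp_path):
    p = tmp_path / "gis.tsv"
    p.write_text("G1\t0.62\n")
    assert gio.read_scalar_table(p) == {"G1": 0.62}
    empty = tmp_path / "e.tsv"
    empty.write_text("")
    assert gio.read_scalar_table(empty) == {}
    dup = tmp_path / "dup.tsv"
    dup.write_text("G1\t0.5\nG1\t0.6\n")
    with pytest.raises(ValueError, match="duplicate"):
        gio.read_scalar_table(dup)
    bad = tmp_path / "bad.tsv"
    bad.write_text("G1\tnot_a_number\n")
    with pytest.raises(ValueError, match="G1"):
        gio.read_scalar_table(bad)


def test_scalar_table_round_trip(tmp_path):
    table = {"a": 0.125, "b": 3.0, "c": 1e-4}
    p = tmp_path / "rt.tsv"
    gio.write_scalar_table(p, table, header=["provenance"])
    assert gio.read_scalar_table(p) == table


def test_vcf_write_read_inverse(tmp_path):
    """The 1-based write / 0-based read conversion is its own inverse."""
    calls = [
        gio.DeletionCall(
            GenomicInterval("chr1", 1234, 5678),
            {"S1": "1/1", "S2": "0/1", "S3": "0/0"},
            None,
            "DELX",
        )
    ]
    calls[0].allele_frequency = calls[0].carrier_frequency()
    p = tmp_path / "rt.vcf"
    write_vcf(p, calls, ["S1", "S2", "S3"], {"chr1": 100000})
    back = gio.read_deletions(p).calls
    assert back[0].interval == calls[0].interval
    assert back[0].genotypes == calls[0].genotypes
    assert back[0].allele_frequency == pytest.approx(0.5, abs=1e-6)


def test_read_gene_interactions_whitelist(tmp_path):
    p = tmp_path / "i.tsv"
    p.write_text(
        "G1\tG2\tprotein-protein\nG2\tG3\tgenetic\nG3\tG4\tsignaling\n"
    )
    rows, excluded = gio.read_gene_interactions(p)
    assert rows == [("G1", "G2", "protein-protein"), ("G3", "G4", "signaling")]
    assert excluded == 1
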