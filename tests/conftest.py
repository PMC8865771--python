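import numpy as np
import pytest

from modepairs.datamodel import Genotype, SpeciesEntry, StudyDesign, SVRecord, VariantRecord
from modepairs.simulate import make_design


@pytest.fixture
def design5():
    """Five pairs, one individual per species."""
    return make_design(5, 1)


@pytest.fixture
def design5x5():
    return make_design(5, 5)


def make_variant(pos=100, qual=350.0, genotypes=None, depths=None, chrom="chr1"):
    genotypes = genotypes or {"s1": Genotype.HET}
    depths = depths or {s: 20 for s in genotypes}
    return VariantRecord(
        chrom=chrom, pos=pos, ref="A", alt="T", qual=qual,
        genotypes=genotypes, depths=depths,
    )


def make_sv(start=1000, end=5000, sv_type="DEL", length=None, strand="+/+",
            sr=5, pe=5, sample="s1", genotype="het", coverage=40.0, chrom="chr1"):
    if length is None:
        length = end - start
    return SVRecord(
        chrom=chrom, start=start, end=end, sv_type=sv_type, length=length,
        strand_pair=strand, support_sr=sr, support_pe=pe, sample=sample,
        genotype=genotype, sample_coverage=coverage,
    )


def write_minimal_vcf(path, data_lines, samples=("s1",), fileformat=True):
    """Write a VCF with given raw data lines (already tab-joined strings)."""
    with open(path, "w") as fh:
        if fileformat:
            fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1,length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for line in data_lines:
            fh.write(line + "\n")
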