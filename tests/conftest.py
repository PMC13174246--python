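import numpy as np
import pytest

from gsimpute.genotype_io import GenotypeMatrix, MarkerRecord


def make_gm(codes, chrom="1", start_pos=1, step=1, sample_prefix="s", ref="A", alt="G"):
    """Build a GenotypeMatrix from a 2-D code array with synthetic markers."""
    codes = np.asarray(codes, dtype=np.int8)
    n, p = codes.shape
    markers = [
        MarkerRecord(chrom, start_pos + j * step, f"m{j}", ref, alt) for j in range(p)
    ]
    return GenotypeMatrix([f"{sample_prefix}{i}" for i in range(n)], markers, codes)


def random_gm(rng, n, p, missing=0.0, chrom="1"):
    codes = rng.integers(1, 4, size=(n, p)).astype(np.int8)
    if missing:
        codes[rng.random((n, p)) < missing] = 0
    return make_gm(codes, chrom=chrom)


@pytest.fixture
def gm_factory():
    return make_gm


@pytest.fixture
def random_gm_factory():
    return random_gm


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={chrom}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, g: GenotypeMatrix, phased=False):
    """Serialize a GenotypeMatrix as a plain-text VCF for round-trip tests."""
    sep = "|" if phased else "/"
    gt_of = {0: f".{sep}.", 1: f"0{sep}0", 2: f"0{sep}1", 3: f"1{sep}1"}
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(chrom=g.markers[0].chrom, samples="\t".join(g.sample_ids)))
        for j, m in enumerate(g.markers):
            calls = "\t".join(gt_of[int(c)] for c in g.codes[:, j])
            fh.write(f"{m.chrom}\t{m.pos}\t{m.id or '.'}\t{m.ref}\t{m.alt}\t.\tPASS\t.\tGT\t{calls}\n")
    return str(path)


@pytest.fixture
def vcf_writer():
    return write_vcf
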