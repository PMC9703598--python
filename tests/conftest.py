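import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from poolevo.io_formats import SampleMeta, SiteTable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_site_table(rows, samples):
    """Build a SiteTable from (chrom, pos, allele_A, allele_B, [(ca, cb), ...]) rows."""
    sites = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], "SNP") for r in rows],
        columns=["chrom", "pos", "allele_A", "allele_B", "variant_class"],
    )
    count_a = np.array([[c[0] for c in r[4]] for r in rows], dtype=np.int64).reshape(
        len(rows), len(samples)
    )
    count_b = np.array([[c[1] for c in r[4]] for r in rows], dtype=np.int64).reshape(
        len(rows), len(samples)
    )
    return SiteTable(sites=sites, samples=list(samples), count_a=count_a, count_b=count_b)


@pytest.fixture
def filter_toy():
    """Six-site toy table with exactly two planted violations.

    Site at pos 300 has depth 20 (< 25) in the evolved sample; site at pos
    500 has founder MAF 0.1 (< 0.3). The other four sites pass every
    criterion: clean parents, heterozygous founder, depth 28-30 everywhere.
    """
    samples = ["pA", "pB", "F", "E1"]
    metas = [
        SampleMeta("pA", "parent_A"),
        SampleMeta("pB", "parent_B"),
        SampleMeta("F", "founder", environment="NaCl", replicate="1", generation=0),
        SampleMeta("E1", "evolved", environment="NaCl", replicate="1", generation=100),
    ]
    ok = [(30, 0), (0, 28), (15, 15), (20, 10)]
    rows = [
        ("chr1", 100, "A", "C", ok),
        ("chr1", 200, "G", "T", [(29, 0), (0, 30), (14, 16), (22, 8)]),
        ("chr1", 300, "A", "G", [(30, 0), (0, 30), (15, 15), (10, 10)]),  # depth 20
        ("chr1", 400, "C", "T", ok),
        ("chr1", 500, "T", "A", [(28, 0), (0, 29), (3, 27), (25, 5)]),  # founder MAF 0.1
        ("chr1", 600, "G", "A", ok),
    ]
    return make_site_table(rows, samples), metas


def write_vcf(path, records, samples):
    """records: (chrom, pos, ref, alts, [AD tuples per sample])."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]
    for chrom in dict.fromkeys(r[0] for r in records):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for chrom, pos, ref, alts, ads in records:
        cells = "\t".join(",".join(str(x) for x in ad) for ad in ads)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tAD\t{cells}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_sheet(path, rows):
    """rows: (sample_id, role, environment, replicate, generation)."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "role", "environment", "replicate", "generation"]
    )
    df.to_csv(path, sep="\t", index=False)
    return path
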