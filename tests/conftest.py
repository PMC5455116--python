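import numpy as np
import pytest

from domesticscan.synthetic_cohort import SimulationConfig, simulate_cohort, write_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down synthetic cohort shared across the unit tests."""
    return simulate_cohort(SimulationConfig.small(seed=7))


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory, small_cohort):
    outdir = tmp_path_factory.mktemp("cohort")
    return write_cohort(small_cohort, outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_vcf(path, body_rows, sample="ACC1", contigs=(("ch01", 100000),)):
    """Write a minimal single-sample VCF for parser tests."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    lines += body_rows
    path.write_text("\n".join(lines) + "\n")
    return path
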