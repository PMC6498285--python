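import numpy as np
import pandas as pd
import pytest

from snpsom.genotype_io import AlleleMatrix, GenotypePanel


def make_panel(calls, snp_ids=None, sample_ids=None, populations=None, regions=None):
    """Build a GenotypePanel from an N x M x 2 call array (0/1 alleles, -1 missing)."""
    calls = np.asarray(calls, dtype=np.int16)
    n, m, _ = calls.shape
    snp_ids = snp_ids or [f"rs{i + 1}" for i in range(n)]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(m)]
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 10,
            "ref": "A",
            "alt": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": populations or ["POP1"] * m,
            "region": regions or ["REG1"] * m,
        }
    )
    return GenotypePanel(snps=snps, samples=samples, calls=calls)


def panel_from_dosages(dosages, **kw):
    """Panel from an N x M alt-allele dosage matrix (None/-1 = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    calls = np.zeros(dosages.shape + (2,), dtype=np.int16)
    missing = ~np.isfinite(dosages) | (dosages < 0)
    calls[..., 0] = (dosages == 2).astype(np.int16)
    calls[..., 1] = (dosages >= 1).astype(np.int16)
    calls[missing] = -1
    return make_panel(calls, **kw)


def matrix_from_scores(scores, sample_ids=None, populations=None, regions=None):
    """AlleleMatrix directly from a 0/1/2 score matrix."""
    scores = np.asarray(scores, dtype=np.int16)
    n, m = scores.shape
    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 10,
            "ref": "A",
            "alt": "G",
            "minor_allele": "G",
        }
    )
    sample_meta = pd.DataFrame(
        {
            "sample_id": sample_ids or [f"S{j + 1}" for j in range(m)],
            "population": populations or ["POP1"] * m,
            "region": regions or ["REG1"] * m,
        }
    )
    return AlleleMatrix(
        scores=scores,
        snp_meta=snp_meta,
        sample_meta=sample_meta,
        maf=scores.sum(axis=1) / (2 * m),
    )


def write_sample_table(path, sample_ids, populations=None, regions=None):
    pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": populations or ["POP1"] * len(sample_ids),
            "region": regions or ["REG1"] * len(sample_ids),
        }
    ).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def tiny_vcf(tmp_path):
    """Two biallelic SNPs + one tri-allelic site, three samples."""
    vcf = tmp_path / "tiny.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t0/1\t0/0\n"
        "1\t300\trs3\tA\tG,T\t.\t.\t.\tGT\t0/0\t1/2\t0/1\n"
    )
    meta = write_sample_table(tmp_path / "samples.tsv", ["S1", "S2", "S3"])
    return vcf, meta
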