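"""Genotype input, minor-allele coding, and frequency filtering.

Genotype panels come in either as VCF (biallelic SNPs, GT field) or as a
plain-text dosage matrix, together with a sample metadata table.  Genotypes
are coded as integer allele scores counting copies of the *globally* minor
allele: 0 = homozygous major, 1 = heterozygous, 2 = homozygous minor.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "AlleleMatrix",
    "read_genotypes",
    "read_sample_table",
    "drop_missing",
    "code_alleles",
    "filter_by_maf",
    "restrict_to_catalog",
    "write_score_matrix",
    "read_score_matrix",
]

log = logging.getLogger(__name__)

SAMPLE_META_COLUMNS = ("sample_id", "population", "region")
SNP_META_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt")

#: allele index used for a missing call in :attr:`GenotypePanel.calls`
MISSING = -1


@dataclasses.dataclass
class GenotypePanel:
    """Raw diploid calls for N SNPs x M samples.

    ``calls[i, j]`` holds the two allele indices (0 = ref, 1 = alt) of
    sample ``j`` at SNP ``i``; ``MISSING`` marks a missing allele.
    """

    snps: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.calls.shape != (len(self.snps), len(self.samples), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.samples)} samples"
            )
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate SNP identifier: {dup}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample identifier: {dup}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def missing_mask(self) -> np.ndarray:
        """Boolean N x M mask of missing calls."""
        return (self.calls == MISSING).any(axis=2)


@dataclasses.dataclass
class AlleleMatrix:
    """Complete-case allele score matrix with per-SNP minor allele and MAF.

    Invariants: all scores in {0, 1, 2}; ``maf[i] == scores[i].sum() / (2 M)``
    and ``maf`` never exceeds 0.5.
    """

    scores: np.ndarray
    snp_meta: pd.DataFrame  # SNP_META_COLUMNS + "minor_allele"
    sample_meta: pd.DataFrame
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)
        n, m = self.scores.shape
        if len(self.snp_meta) != n or len(self.sample_meta) != m:
            raise ValueError("metadata length does not match score matrix shape")
        if self.scores.size and not np.isin(self.scores, (0, 1, 2)).all():
            raise ValueError("allele scores must be 0, 1 or 2")
        # NB: maf can exceed 0.5 on sample subsets (orientation stays global);
        # code_alleles guarantees maf <= 0.5 on the full panel.
        expected = self.scores.sum(axis=1) / (2 * max(m, 1))
        if self.maf.shape != (n,) or (n and not np.allclose(self.maf, expected)):
            raise ValueError("maf is inconsistent with the score matrix")

    @property
    def n_snps(self) -> int:
        return self.scores.shape[0]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp_id"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.sample_meta["sample_id"].to_numpy()

    def take_snps(self, rows: np.ndarray) -> "AlleleMatrix":
        return AlleleMatrix(
            scores=self.scores[rows],
            snp_meta=self.snp_meta.iloc[rows],
            sample_meta=self.sample_meta,
            maf=self.maf[rows],
        )

    def take_samples(self, cols: np.ndarray) -> "AlleleMatrix":
        """Column subset; MAF is recomputed on the subset."""
        scores = self.scores[:, cols]
        maf = scores.sum(axis=1) / (2 * scores.shape[1])
        return AlleleMatrix(
            scores=scores,
            snp_meta=self.snp_meta,
            sample_meta=self.sample_meta.iloc[cols],
            maf=maf,
        )


def read_sample_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the tab-separated sample metadata (sample_id, population, region)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sample table {path} lacks required column(s): {missing}")
    return table[list(SAMPLE_META_COLUMNS)]


def read_genotypes(source: str | os.PathLike, sample_table: str | os.PathLike) -> GenotypePanel:
    """Read a genotype panel from VCF or the plain-text matrix dialect.

    Multi-allelic and non-SNP sites are skipped (counted in
    :attr:`GenotypePanel.n_skipped`).  Every sample in the genotype source
    must appear in the metadata table.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(f"genotype source not found: {source}")
    meta = read_sample_table(sample_table)
    if source.suffix in {".vcf", ".gz", ".bcf"} or source.name.endswith(".vcf.gz"):
        return _read_vcf(source, meta)
    return _read_matrix(source, meta)


def _align_meta(sample_ids: Sequence[str], meta: pd.DataFrame) -> pd.DataFrame:
    known = set(meta["sample_id"])
    for sid in sample_ids:
        if sid not in known:
            raise ValueError(f"sample '{sid}' in genotype source is absent from the metadata table")
    return meta.set_index("sample_id").loc[list(sample_ids)].reset_index()


def _read_vcf(path: Path, meta: pd.DataFrame) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = _align_meta(vcf.samples, meta)
    snp_rows: list[tuple] = []
    calls: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        gts = np.array([g[:2] for g in variant.genotypes], dtype=np.int16)
        gts[gts < 0] = MISSING
        snp_rows.append(
            (
                variant.ID or f"{variant.CHROM}:{variant.POS}",
                str(variant.CHROM),
                int(variant.POS),
                variant.REF,
                variant.ALT[0],
            )
        )
        calls.append(gts)
    vcf.close()
    if n_skipped:
        log.warning("skipped %d multi-allelic or non-SNP site(s) in %s", n_skipped, path)
    snps = pd.DataFrame(snp_rows, columns=list(SNP_META_COLUMNS))
    arr = (
        np.stack(calls)
        if calls
        else np.empty((0, len(samples), 2), dtype=np.int16)
    )
    return GenotypePanel(snps=snps, samples=samples, calls=arr, n_skipped=n_skipped)


# dosage entry -> pseudo allele pair; matrix input has no real REF/ALT bases
_DOSAGE_CALLS = {"0": (0, 0), "1": (0, 1), "2": (1, 1), ".": (MISSING, MISSING)}


def _read_matrix(path: Path, meta: pd.DataFrame) -> GenotypePanel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}:1: matrix header must list sample IDs")
        sample_ids = header[1:]
        samples = _align_meta(sample_ids, meta)
        snp_rows = []
        calls = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
                )
            try:
                row = [_DOSAGE_CALLS[v] for v in fields[1:]]
            except KeyError as exc:
                raise ValueError(
                    f"{path}:{lineno}: invalid genotype entry {exc.args[0]!r} "
                    "(expected 0, 1, 2 or '.')"
                ) from None
            snp_rows.append((fields[0], ".", 0, "A", "B"))
            calls.append(row)
    snps = pd.DataFrame(snp_rows, columns=list(SNP_META_COLUMNS))
    arr = (
        np.array(calls, dtype=np.int16)
        if calls
        else np.empty((0, len(samples), 2), dtype=np.int16)
    )
    return GenotypePanel(snps=snps, samples=samples, calls=arr)


def drop_missing(panel: GenotypePanel, max_missing_rate: float = 0.0) -> GenotypePanel:
    """Remove SNPs whose fraction of missing calls exceeds ``max_missing_rate``.

    The default 0 yields a complete-case matrix: any missing call removes
    the SNP.
    """
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    if panel.n_snps == 0:
        return panel
    rate = panel.missing_mask().mean(axis=1)
    keep = rate <= max_missing_rate
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("drop_missing: removed %d of %d SNPs", n_dropped, panel.n_snps)
    return GenotypePanel(
        snps=panel.snps.loc[keep],
        samples=panel.samples,
        calls=panel.calls[keep],
        n_skipped=panel.n_skipped,
    )


def code_alleles(panel: GenotypePanel) -> AlleleMatrix:
    """Code genotypes as minor-allele copy counts (0/1/2).

    The minor allele is determined globally over all samples; a frequency
    tie at exactly 0.5 designates the alternate allele as minor.
    """
    if panel.n_snps and panel.missing_mask().any():
        raise ValueError("panel contains missing calls; run drop_missing first")
    m = panel.n_samples
    alt_copies = (panel.calls == 1).sum(axis=2)
    alt_freq = alt_copies.sum(axis=1) / (2 * m) if panel.n_snps else np.empty(0)
    minor_is_alt = alt_freq <= 0.5
    scores = np.where(minor_is_alt[:, None], alt_copies, 2 - alt_copies).astype(np.int16)
    snp_meta = panel.snps.copy()
    snp_meta["minor_allele"] = np.where(
        minor_is_alt, panel.snps["alt"], panel.snps["ref"]
    )
    maf = scores.sum(axis=1) / (2 * m) if panel.n_snps else np.empty(0)
    return AlleleMatrix(scores=scores, snp_meta=snp_meta, sample_meta=panel.samples, maf=maf)


def filter_by_maf(matrix: AlleleMatrix, threshold: float = 0.05) -> AlleleMatrix:
    """Keep SNPs with MAF *strictly* greater than ``threshold``."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    keep = np.flatnonzero(matrix.maf > threshold)
    log.info("filter_by_maf: kept %d of %d SNPs at MAF > %g", len(keep), matrix.n_snps, threshold)
    return matrix.take_snps(keep)


def restrict_to_catalog(matrix: AlleleMatrix, catalog) -> AlleleMatrix:
    """Keep only SNPs present in the association catalog (row order preserved)."""
    wanted = set(catalog.snp_ids())
    keep = np.flatnonzero(np.fromiter((s in wanted for s in matrix.snp_ids), bool, matrix.n_snps))
    if matrix.n_snps and len(keep) == 0:
        raise ValueError(
            "no overlap between matrix SNPs and catalog SNPs; "
            "check for an identifier scheme mismatch (e.g. rsID vs chrom:pos)"
        )
    log.info("restrict_to_catalog: kept %d of %d SNPs", len(keep), matrix.n_snps)
    return matrix.take_snps(keep)


def write_score_matrix(matrix: AlleleMatrix, path: str | os.PathLike) -> None:
    """Write the scores in the plain-text dialect (SNP rows, sample columns)."""
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for sid, row in zip(matrix.snp_ids, matrix.scores):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_score_matrix(path: str | os.PathLike, sample_table: str | os.PathLike) -> AlleleMatrix:
    """Read a score matrix written by :func:`write_score_matrix`.

    Scores are re-interpreted through the standard coding path, which is the
    identity on any valid score matrix (MAF never exceeds 0.5, so the coded
    orientation is stable under a round trip).
    """
    panel = read_genotypes(path, sample_table)
    return code_alleles(drop_missing(panel))
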