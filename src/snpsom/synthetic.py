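"""Seeded synthetic multi-population genotype panels with planted structure.

Background SNPs follow the Balding-Nichols model: an ancestral frequency p
drawn uniformly from a configurable range, then per-population frequencies
from a Beta distribution with mean p and variance p(1-p)*Fst.  "Block" SNPs
are planted with an elevated alternate-allele frequency in target
populations (low baseline elsewhere) and annotated with a disease term, so
every downstream stage has a known ground truth.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AssociationCatalog, OntologyGraph, compute_depths, write_obo
from .genotype_io import GenotypePanel, MISSING

__all__ = [
    "BlockSpec",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_panel",
    "make_ontology_fixture",
    "leaf_terms",
    "default_spec",
    "write_fixture",
    "write_vcf",
]


@dataclasses.dataclass
class BlockSpec:
    """A planted cluster of SNPs with elevated frequency in target pops."""

    size: int
    pops: tuple[str, ...]
    freq: float
    term: str
    genes: tuple[str, ...] = ()
    baseline: float = 0.05

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("block size must be >= 1")
        if not 0.0 < self.freq < 1.0 or not 0.0 < self.baseline < 1.0:
            raise ValueError("block frequencies must be in (0, 1)")


@dataclasses.dataclass
class SyntheticSpec:
    n_pops: int = 4
    samples_per_pop: int = 50
    n_background_snps: int = 1800
    fst: float = 0.1
    blocks: list[BlockSpec] = dataclasses.field(default_factory=list)
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    background_term_pool: tuple[str, ...] = ()
    background_annotation_rate: float = 1.0
    ld_copy_pairs: int = 0
    ld_flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        if self.n_pops < 1 or self.samples_per_pop < 1:
            raise ValueError("need at least one population and one sample per population")
        for b in self.blocks:
            if b.size > self.n_background_snps:
                raise ValueError(
                    "block larger than the background panel requested; "
                    "increase n_background_snps or shrink the block"
                )

    @property
    def pop_labels(self) -> list[str]:
        return [f"POP{k + 1}" for k in range(self.n_pops)]


@dataclasses.dataclass
class SyntheticTruth:
    sample_truth: pd.DataFrame  # sample_id, population, region
    snp_truth: pd.DataFrame  # snp_id, block, term, ld_source
    pop_freqs: pd.DataFrame  # snp_id x population alternate-allele frequency
    block_members: dict[int, list[str]]  # block index -> snp ids


def make_ontology_fixture(
    depth: int = 5, branching: int = 2, diamond: bool = False
) -> OntologyGraph:
    """Deterministic rooted tree ontology with ``branching ** L`` terms per level.

    ``depth`` is the leaf level (>= 4 so level-3 mapping is exercised).
    With ``diamond=True`` one extra leaf with two distinct level-3 parents is
    appended, for multi-ancestor tests.
    """
    if depth < 4:
        raise ValueError("depth must be >= 4 to exercise level-3 mapping")
    counter = 0

    def new_id() -> str:
        nonlocal counter
        tid = f"DO:{counter:07d}"
        counter += 1
        return tid

    terms: dict[str, str] = {}
    parents: dict[str, tuple[str, ...]] = {}
    root = new_id()
    terms[root] = "disease root"
    parents[root] = ()
    level = [root]
    by_level = {0: [root]}
    for lvl in range(1, depth + 1):
        nxt = []
        for parent in level:
            for i in range(branching):
                tid = new_id()
                terms[tid] = f"term level{lvl} under {parent}"
                parents[tid] = (parent,)
                nxt.append(tid)
        level = nxt
        by_level[lvl] = nxt
    if diamond:
        tid = new_id()
        terms[tid] = "diamond leaf with two level-3 parents"
        parents[tid] = (by_level[3][0], by_level[3][-1])
    return compute_depths(OntologyGraph(terms=terms, parents=parents, root=root))


def leaf_terms(graph: OntologyGraph) -> list[str]:
    """Terms with no children, sorted by identifier."""
    has_child: set[str] = set()
    for ps in graph.parents.values():
        has_child.update(ps)
    return sorted(t for t in graph.terms if t not in has_child)


def default_spec(seed: int = 0, graph: OntologyGraph | None = None) -> tuple[SyntheticSpec, OntologyGraph]:
    """The reference spec: 4 pops x 50 samples, 1800 background SNPs at
    Fst 0.1, and 4 blocks of 50 SNPs at elevated frequency 0.6, each
    annotated with a distinct deep disease term."""
    graph = graph or make_ontology_fixture(depth=5, branching=2)
    leaves = leaf_terms(graph)
    # pick leaves under distinct level-3 ancestors
    chosen: list[str] = []
    used_ancestors: set[str] = set()
    for leaf in leaves:
        anc = graph.ancestors_at_depth(leaf, 3)
        if not anc & used_ancestors:
            chosen.append(leaf)
            used_ancestors |= anc
        if len(chosen) == 4:
            break
    blocks = [
        BlockSpec(
            size=50,
            pops=(f"POP{k + 1}",),
            freq=0.6,
            term=chosen[k],
            genes=(f"GENE{k + 1}",),
            baseline=0.02,
        )
        for k in range(4)
    ]
    # the narrow background range keeps drift-elevated background SNPs from
    # blending into the planted blocks, so ground truth stays recoverable
    spec = SyntheticSpec(
        blocks=blocks,
        background_term_pool=tuple(leaves),
        ancestral_maf_range=(0.05, 0.12),
        seed=seed,
    )
    return spec, graph


def generate_panel(
    spec: SyntheticSpec,
) -> tuple[GenotypePanel, AssociationCatalog, SyntheticTruth]:
    """Draw a seeded panel + association catalog + ground truth."""
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_freq = np.random.default_rng(streams[0])
    rng_geno = np.random.default_rng(streams[1])
    rng_annot = np.random.default_rng(streams[2])
    rng_ld = np.random.default_rng(streams[3])

    pops = spec.pop_labels
    n_bg = spec.n_background_snps
    n_block = sum(b.size for b in spec.blocks)
    n_snps = n_bg + n_block

    # per-population alternate allele frequencies, Balding-Nichols background
    lo, hi = spec.ancestral_maf_range
    ancestral = rng_freq.uniform(lo, hi, size=n_bg)
    shape = (1.0 - spec.fst) / spec.fst
    alpha = np.clip(ancestral * shape, 1e-9, None)
    beta = np.clip((1.0 - ancestral) * shape, 1e-9, None)
    freqs = rng_freq.beta(alpha[:, None], beta[:, None], size=(n_bg, spec.n_pops))

    block_freqs = np.empty((n_block, spec.n_pops))
    block_index = np.full(n_snps, -1, dtype=int)
    row = 0
    for bi, block in enumerate(spec.blocks):
        target = np.isin(pops, block.pops)
        if not target.any():
            raise ValueError(f"block {bi} targets unknown population(s) {block.pops}")
        block_freqs[row : row + block.size] = np.where(target, block.freq, block.baseline)
        block_index[n_bg + row : n_bg + row + block.size] = bi
        row += block.size
    freqs = np.vstack([freqs, block_freqs]) if n_block else freqs

    # genotypes: two independent allele draws per sample
    sample_pop = np.repeat(np.arange(spec.n_pops), spec.samples_per_pop)
    p_matrix = freqs[:, sample_pop]  # N x M
    alt_counts = rng_geno.binomial(2, p_matrix).astype(np.int16)

    snp_ids = [f"rs{i + 1:06d}" for i in range(n_snps)]
    ld_source = [""] * n_snps
    # optional LD knob: duplicated genotype columns with per-allele flips
    if spec.ld_copy_pairs:
        sources = rng_ld.choice(n_snps, size=spec.ld_copy_pairs, replace=False)
        copies = []
        for src in sources:
            copy = alt_counts[src].copy()
            if spec.ld_flip_prob > 0:
                down = rng_ld.binomial(copy, spec.ld_flip_prob)
                up = rng_ld.binomial(2 - copy, spec.ld_flip_prob)
                copy = copy - down + up
            copies.append(copy)
            snp_ids.append(f"rs{src + 1:06d}LD")
            ld_source.append(f"rs{src + 1:06d}")
        alt_counts = np.vstack([alt_counts, np.array(copies, dtype=np.int16)])
        freqs = np.vstack([freqs, freqs[sources]])
        block_index = np.concatenate([block_index, block_index[sources]])
        n_snps = len(snp_ids)

    # assemble the panel
    ref_alt = [("A", "G"), ("C", "T")]
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 100,
            "ref": [ref_alt[i % 2][0] for i in range(n_snps)],
            "alt": [ref_alt[i % 2][1] for i in range(n_snps)],
        }
    )
    m = spec.n_pops * spec.samples_per_pop
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{j + 1:04d}" for j in range(m)],
            "population": [pops[k] for k in sample_pop],
            "region": [f"REG{k // 2 + 1}" for k in sample_pop],
        }
    )
    # genotype 0 -> (0,0), 1 -> (0,1), 2 -> (1,1)
    calls = np.zeros((n_snps, m, 2), dtype=np.int16)
    calls[:, :, 0] = (alt_counts == 2).astype(np.int16)
    calls[:, :, 1] = (alt_counts >= 1).astype(np.int16)
    panel = GenotypePanel(snps=snps, samples=samples, calls=calls)

    # association catalog: planted block terms + random background annotation
    records = []
    for bi, block in enumerate(spec.blocks):
        ids = [snp_ids[i] for i in np.flatnonzero(block_index[: len(snp_ids)] == bi)]
        for k, sid in enumerate(ids):
            gene = block.genes[k % len(block.genes)] if block.genes else pd.NA
            records.append((sid, block.term, gene, "planted"))
    if spec.background_term_pool and spec.background_annotation_rate > 0:
        pool = list(spec.background_term_pool)
        for i in range(n_snps):
            if block_index[i] >= 0:
                continue
            if rng_annot.random() < spec.background_annotation_rate:
                term = pool[rng_annot.integers(len(pool))]
                records.append((snp_ids[i], term, pd.NA, "background"))
    catalog = AssociationCatalog(
        records=pd.DataFrame(records, columns=["snp_id", "term_id", "gene", "source"])
    )

    block_terms = {bi: b.term for bi, b in enumerate(spec.blocks)}
    snp_truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "block": block_index,
            "term": [block_terms.get(b, "") for b in block_index],
            "ld_source": ld_source,
        }
    )
    pop_freqs = pd.DataFrame(freqs, columns=pops, index=snp_ids)
    block_members = {
        bi: [snp_ids[i] for i in np.flatnonzero(block_index == bi)]
        for bi in range(len(spec.blocks))
    }
    truth = SyntheticTruth(
        sample_truth=samples.copy(),
        snp_truth=snp_truth,
        pop_freqs=pop_freqs,
        block_members=block_members,
    )
    return panel, catalog, truth


def write_vcf(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Write a minimal uncompressed VCF 4.2 with GT calls."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    alt = (panel.calls == 1).sum(axis=2)
    missing = panel.missing_mask()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["sample_id"])
            + "\n"
        )
        for i, row in panel.snps.iterrows():
            gts = [
                "./." if missing[i, j] else gt_codes[int(alt[i, j])]
                for j in range(panel.n_samples)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_fixture(
    outdir: str | os.PathLike,
    panel: GenotypePanel,
    catalog: AssociationCatalog,
    truth: SyntheticTruth,
    graph: OntologyGraph,
) -> dict[str, Path]:
    """Emit VCF + metadata + associations + OBO + truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "samples": outdir / "samples.tsv",
        "associations": outdir / "associations.tsv",
        "ontology": outdir / "ontology.obo",
        "truth_snps": outdir / "truth_snps.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
        "truth_freqs": outdir / "truth_pop_freqs.tsv",
    }
    write_vcf(panel, paths["vcf"])
    panel.samples.to_csv(paths["samples"], sep="\t", index=False)
    catalog.records.rename(columns={"term_id": "disease_term_id"}).to_csv(
        paths["associations"], sep="\t", index=False
    )
    write_obo(graph, paths["ontology"])
    truth.snp_truth.to_csv(paths["truth_snps"], sep="\t", index=False)
    truth.sample_truth.to_csv(paths["truth_samples"], sep="\t", index=False)
    truth.pop_freqs.to_csv(paths["truth_freqs"], sep="\t", index_label="snp_id")
    return paths
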