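"""Batch self-organizing map over centered SNP profiles.

Each SNP is a point in R^M (its allele scores across the M individuals,
mean-centered).  Training distributes the N SNPs over K = rows x cols grid
units by minimizing Euclidean distance to prototype ("meta-SNP") profiles.
Batch updates with a Gaussian neighborhood kernel and a linearly decaying
radius keep the procedure fully deterministic for a given config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SomConfig", "SomModel", "centralize", "train_som", "assign_bmu"]


@dataclasses.dataclass
class SomConfig:
    rows: int = 55
    cols: int = 55
    epochs: int = 100
    radius_start: float | None = None  # defaults to max(rows, cols) / 2
    radius_end: float = 1.0
    init: str = "linear"  # "linear" (deterministic PCA span) or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.radius_start is None:
            self.radius_start = max(self.rows, self.cols) / 2
        if not self.radius_start >= self.radius_end > 0:
            raise ValueError("need radius_start >= radius_end > 0")
        if self.init not in ("linear", "random"):
            raise ValueError("init must be 'linear' or 'random'")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SomConfig":
        return cls(**d)


@dataclasses.dataclass
class SomModel:
    """Trained map: K prototype profiles plus the SNP -> unit assignment."""

    config: SomConfig
    prototypes: np.ndarray  # K x M
    assignment: np.ndarray  # length N, unit indices in [0, K)
    row_means: np.ndarray  # length N per-SNP means removed by centralize
    history: np.ndarray  # per-epoch mean quantization error

    @property
    def n_units(self) -> int:
        return self.prototypes.shape[0]

    def grid_coords(self) -> np.ndarray:
        """K x 2 array of (row, col) grid coordinates, row-major unit order."""
        r, c = np.unravel_index(np.arange(self.n_units), (self.config.rows, self.config.cols))
        return np.column_stack([r, c])

    def unit_members(self) -> dict[int, np.ndarray]:
        """Unit index -> array of member SNP row indices."""
        order = np.argsort(self.assignment, kind="stable")
        units, starts = np.unique(self.assignment[order], return_index=True)
        bounds = np.append(starts, len(order))
        return {int(u): order[a:b] for u, a, b in zip(units, bounds[:-1], bounds[1:])}

    def save(self, outdir: str | os.PathLike) -> None:
        """Portable text container: config JSON + TSV matrices."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))
        np.savetxt(outdir / "prototypes.tsv", self.prototypes, delimiter="\t", fmt="%.17g")
        np.savetxt(outdir / "assignment.tsv", self.assignment[:, None], delimiter="\t", fmt="%d")
        np.savetxt(outdir / "row_means.tsv", self.row_means[:, None], delimiter="\t", fmt="%.17g")
        np.savetxt(outdir / "history.tsv", self.history[:, None], delimiter="\t", fmt="%.17g")

    @classmethod
    def load(cls, outdir: str | os.PathLike) -> "SomModel":
        outdir = Path(outdir)
        config = SomConfig.from_dict(json.loads((outdir / "config.json").read_text()))
        return cls(
            config=config,
            prototypes=np.loadtxt(outdir / "prototypes.tsv", delimiter="\t", ndmin=2),
            assignment=np.loadtxt(outdir / "assignment.tsv", dtype=int).reshape(-1),
            row_means=np.loadtxt(outdir / "row_means.tsv").reshape(-1),
            history=np.loadtxt(outdir / "history.tsv").reshape(-1),
        )

    def export_membership(self, snp_ids, path: str | os.PathLike) -> None:
        """Tab-separated unit_id <-> snp_id table."""
        with open(path, "w") as fh:
            fh.write("unit_id\tsnp_id\n")
            for unit, sid in zip(self.assignment, snp_ids):
                fh.write(f"{unit}\t{sid}\n")


def centralize(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each SNP row's mean across individuals.

    Accepts an AlleleMatrix or a raw 2-D array; returns (centered, means).
    """
    scores = np.asarray(getattr(matrix, "scores", matrix), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot centralize an empty matrix")
    means = scores.mean(axis=1)
    return scores - means[:, None], means


def _init_prototypes(centered: np.ndarray, config: SomConfig) -> np.ndarray:
    n, m = centered.shape
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        idx = rng.integers(0, n, size=config.n_units)
        return centered[idx].copy()
    # linear: span the grid along the two leading principal directions
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt[:2].copy()
    if axes.shape[0] < 2:  # M == 1 degenerate case
        axes = np.vstack([axes, np.zeros_like(axes)])
        svals = np.append(svals, 0.0)
    for k in range(2):  # deterministic sign convention
        pivot = np.argmax(np.abs(axes[k]))
        if axes[k, pivot] < 0:
            axes[k] *= -1
    scale = svals[:2] / np.sqrt(n)
    rr = np.linspace(-1.0, 1.0, config.rows)
    cc = np.linspace(-1.0, 1.0, config.cols)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    protos = (
        grid_r.ravel()[:, None] * scale[0] * axes[0][None, :]
        + grid_c.ravel()[:, None] * scale[1] * axes[1][None, :]
    )
    return protos


def _grid_sq_distances(config: SomConfig) -> np.ndarray:
    r, c = np.unravel_index(np.arange(config.n_units), (config.rows, config.cols))
    coords = np.column_stack([r, c]).astype(float)
    diff = coords[:, None, :] - coords[None, :, :]
    return (diff**2).sum(axis=2)


def train_som(centered: np.ndarray, config: SomConfig, row_means: np.ndarray | None = None) -> SomModel:
    """Train a batch SOM on centered SNP profiles.

    Each epoch assigns every SNP to its best-matching unit and replaces each
    prototype by the neighborhood-kernel-weighted mean of the assigned
    profiles.  A final assignment pass guarantees nearest-prototype
    membership at convergence.
    """
    centered = np.asarray(centered, dtype=float)
    if centered.ndim != 2 or centered.shape[0] < 1:
        raise ValueError("need a non-empty 2-D profile matrix")
    if centered.shape[1] < 2:
        raise ValueError("need at least 2 individuals")
    if not np.isfinite(centered).all():
        raise ValueError("profile matrix contains non-finite values")
    n, m = centered.shape
    prototypes = _init_prototypes(centered, config)
    grid_d2 = _grid_sq_distances(config)
    history = np.empty(config.epochs)
    assignment = np.zeros(n, dtype=int)
    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        radius = config.radius_start + (config.radius_end - config.radius_start) * frac
        d2 = cdist(centered, prototypes, "sqeuclidean")
        assignment = np.argmin(d2, axis=1)
        history[epoch] = np.sqrt(d2[np.arange(n), assignment]).mean()
        # per-unit sums of assigned profiles, then kernel smoothing
        unit_sums = np.zeros((config.n_units, m))
        np.add.at(unit_sums, assignment, centered)
        unit_counts = np.bincount(assignment, minlength=config.n_units).astype(float)
        kernel = np.exp(-grid_d2 / (2.0 * radius**2))
        denom = kernel @ unit_counts
        numer = kernel @ unit_sums
        nonzero = denom > 0
        prototypes[nonzero] = numer[nonzero] / denom[nonzero, None]
    d2 = cdist(centered, prototypes, "sqeuclidean")
    assignment = np.argmin(d2, axis=1)
    if row_means is None:
        row_means = np.zeros(n)
    return SomModel(
        config=config,
        prototypes=prototypes,
        assignment=assignment,
        row_means=np.asarray(row_means, dtype=float),
        history=history,
    )


def assign_bmu(profile: np.ndarray, model: SomModel) -> int:
    """Index of the nearest prototype (ties -> lowest unit index)."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (model.prototypes.shape[1],):
        raise ValueError(
            f"profile length {profile.shape} does not match prototype length "
            f"{model.prototypes.shape[1]}"
        )
    d2 = ((model.prototypes - profile[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2))
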