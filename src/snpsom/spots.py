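"""Minor-allele summary map, spot segmentation and enrichment testing.

The summary map is the pointwise maximum over group mean portraits.  Units
above a quantile threshold are segmented into 8-connected components
("spots", lettered by decreasing peak value), whose member SNPs are tested
for disease-term over-representation with one-sided Fisher's exact tests
against the full set of clustered SNPs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import string
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import AssociationCatalog
from .genotype_io import AlleleMatrix
from .portrayal import Portrait
from .som import SomModel

__all__ = [
    "SummaryMap",
    "Spot",
    "SpotSet",
    "summary_map",
    "segment_spots",
    "spot_profile",
    "fisher_greater",
    "enrich_terms",
    "background_distribution",
]

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)


@dataclasses.dataclass
class SummaryMap:
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)


@dataclasses.dataclass
class Spot:
    label: str
    units: set[tuple[int, int]]
    member_snps: list[str]
    peak: float
    group_profile: pd.Series | None = None
    sample_profile: pd.Series | None = None


@dataclasses.dataclass
class SpotSet:
    spots: list[Spot]
    threshold: float
    quantile: float

    def __iter__(self):
        return iter(self.spots)

    def __len__(self) -> int:
        return len(self.spots)

    def __getitem__(self, label: str) -> Spot:
        for spot in self.spots:
            if spot.label == label:
                return spot
        raise KeyError(label)


def summary_map(mean_portraits: Sequence[Portrait]) -> SummaryMap:
    """Element-wise maximum over group mean portraits."""
    if not mean_portraits:
        raise ValueError("need at least one portrait")
    shape = mean_portraits[0].grid.shape
    for p in mean_portraits:
        if p.grid.shape != shape:
            raise ValueError("portrait grid shapes differ")
    return SummaryMap(grid=np.max([p.grid for p in mean_portraits], axis=0))


def _letters() -> Iterable[str]:
    for ch in string.ascii_uppercase:
        yield ch
    for a in string.ascii_uppercase:
        for b in string.ascii_uppercase:
            yield a + b


def segment_spots(
    smap: SummaryMap,
    model: SomModel,
    snp_ids: Sequence[str],
    threshold_quantile: float = 0.90,
    min_units: int = 5,
) -> SpotSet:
    """Threshold the summary map and label 8-connected foreground spots.

    Foreground = units whose value is strictly above the
    ``threshold_quantile`` quantile of the map (so a uniform map yields no
    spots).  Components smaller than ``min_units`` are discarded, as are
    components whose units carry no member SNPs (pure fill-in artifacts).
    Spots are lettered A, B, ... by decreasing peak value.
    """
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in (0, 1)")
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    grid = smap.grid
    threshold = float(np.quantile(grid, threshold_quantile))
    foreground = grid > threshold
    if not foreground.any():
        log.warning("segment_spots: no unit above the %g quantile", threshold_quantile)
        return SpotSet(spots=[], threshold=threshold, quantile=threshold_quantile)
    labels, n_components = ndimage.label(foreground, structure=_EIGHT)
    snp_ids = np.asarray(snp_ids)
    unit_of_snp = model.assignment
    cols = model.config.cols
    candidates = []
    for comp in range(1, n_components + 1):
        coords = np.argwhere(labels == comp)
        if len(coords) < min_units:
            continue
        units = {(int(r), int(c)) for r, c in coords}
        unit_idx = {r * cols + c for r, c in units}
        member_mask = np.isin(unit_of_snp, list(unit_idx))
        members = snp_ids[member_mask].tolist()
        if not members:
            continue
        peak = float(grid[coords[:, 0], coords[:, 1]].max())
        anchor = min(units)
        candidates.append((peak, len(units), anchor, units, members))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    spots = [
        Spot(label=letter, units=units, member_snps=members, peak=peak)
        for letter, (peak, _, _, units, members) in zip(_letters(), candidates)
    ]
    return SpotSet(spots=spots, threshold=threshold, quantile=threshold_quantile)


def spot_profile(
    spot: Spot, matrix: AlleleMatrix, grouping: Mapping[str, str] | str = "population"
) -> tuple[pd.Series, pd.Series]:
    """Mean allele score of the spot's SNPs per sample and per group.

    ``grouping`` is either a sample -> group mapping or the name of a
    sample metadata column.  The results are stored on the spot and
    returned as (group_profile, sample_profile).
    """
    idx = pd.Index(matrix.snp_ids).get_indexer(spot.member_snps)
    if (idx < 0).any():
        missing = [s for s, i in zip(spot.member_snps, idx) if i < 0]
        raise KeyError(f"spot member SNP(s) absent from matrix: {missing[:5]}")
    sample_ids = matrix.sample_ids
    sample_profile = pd.Series(
        matrix.scores[idx].mean(axis=0), index=sample_ids, name=spot.label
    )
    if isinstance(grouping, str):
        groups = pd.Series(
            matrix.sample_meta[grouping].to_numpy(), index=sample_ids
        )
    else:
        groups = pd.Series({s: grouping[s] for s in sample_ids})
    group_profile = sample_profile.groupby(groups).mean()
    spot.sample_profile = sample_profile
    spot.group_profile = group_profile
    return group_profile, sample_profile


def fisher_greater(a, b, c, d):
    """One-sided (alternative: greater) Fisher's exact p for 2x2 table(s).

    Table layout: [[a, b], [c, d]] with a = in-spot & annotated.  Equals the
    hypergeometric upper-tail sum P(X >= a) with population a+b+c+d,
    a+c annotated and a+b drawn.  Vectorized over array inputs.
    """
    a = np.asarray(a)
    return hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)


def enrich_terms(
    spots: SpotSet,
    catalog: AssociationCatalog,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per (spot, level-3 term) one-sided Fisher enrichment.

    The universe is the full set of clustered SNPs; a SNP counts once per
    term regardless of source multiplicity.  Benjamini-Hochberg adjusted
    p-values are computed within each spot.
    """
    universe = list(dict.fromkeys(universe))
    universe_set = set(universe)
    n_total = len(universe_set)
    term_snps = catalog.term_to_snps(universe_set)
    skipped = [t for t, s in term_snps.items() if not s]
    for t in skipped:
        log.info("enrich_terms: term %s has no annotated SNP in the universe; skipped", t)
    term_snps = {t: s for t, s in term_snps.items() if s}
    rows = []
    for spot in spots:
        members = set(spot.member_snps) & universe_set
        n_spot = len(members)
        for term in sorted(term_snps):
            annotated = term_snps[term]
            a = len(members & annotated)
            b = n_spot - a
            c = len(annotated) - a
            d = n_total - a - b - c
            p = float(fisher_greater(a, b, c, d))
            rows.append((spot.label, term, a, b, c, d, p))
    result = pd.DataFrame(
        rows,
        columns=["spot", "term", "in_annot", "in_other", "out_annot", "out_other", "p_value"],
    )
    if len(result):
        result["p_bh"] = np.nan
        for label, idx in result.groupby("spot").groups.items():
            result.loc[idx, "p_bh"] = multipletests(
                result.loc[idx, "p_value"], method="fdr_bh"
            )[1]
        result = result.sort_values(["spot", "p_value", "term"]).reset_index(drop=True)
    else:
        result["p_bh"] = pd.Series(dtype=float)
    return result


def background_distribution(
    catalog: AssociationCatalog, universe: Iterable[str]
) -> pd.Series:
    """Number of universe SNPs annotated with each level-3 term."""
    counts = {t: len(s) for t, s in catalog.term_to_snps(set(universe)).items()}
    return pd.Series(counts, dtype=int).sort_index()


def write_spot_report(spots: SpotSet, enrichment: pd.DataFrame, path: str | os.PathLike, top: int = 3) -> None:
    """Tab-separated per-spot summary with top enriched terms."""
    with open(path, "w") as fh:
        fh.write("spot\tn_units\tn_snps\tpeak\ttop_terms\n")
        for spot in spots:
            sub = enrichment[enrichment["spot"] == spot.label].nsmallest(top, "p_value")
            terms = ";".join(
                f"{t}(p={p:.3g},bh={q:.3g})"
                for t, p, q in zip(sub["term"], sub["p_value"], sub["p_bh"])
            )
            fh.write(
                f"{spot.label}\t{len(spot.units)}\t{len(spot.member_snps)}\t"
                f"{spot.peak:.6g}\t{terms}\n"
            )
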