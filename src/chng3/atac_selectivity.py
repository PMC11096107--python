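"""Cell-type selectivity of chromatin accessibility over a genomic region.

Works on per-cell-type coverage tracks binned at fixed width (100 bp by
default, matching precomputed snATAC-seq depth workflows). For a query
region the score is

    selectivity(target) = median depth of target / sum of median depths,

where the median is over the fixed bins overlapping the region (partial
bins included whole — bins are anchored at the track's declared interval
start, not re-cut per query). Scores over all cell types sum to 1 whenever
any cell type has signal, and are invariant to rescaling every track by a
common constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import CoverageTrack, GenomicInterval, ValidationError


class CoverageError(ValueError):
    """Query region falls outside a track's declared interval."""


@dataclass
class SelectivityResult:
    region: GenomicInterval
    median_depth: dict[str, float]
    selectivity: dict[str, float]   # empty when undefined
    target_cell_type: str
    undefined: bool = False

    @property
    def target_selectivity(self) -> float | None:
        return None if self.undefined else self.selectivity[self.target_cell_type]


def region_median_depth(track: CoverageTrack, region: GenomicInterval) -> float:
    """Median of the fixed-width bin depths overlapping ``region``.

    Bins partially overlapping the region contribute whole (no re-weighting).
    """
    iv = track.interval
    if region.chrom != iv.chrom or not region.overlaps(iv):
        raise CoverageError(f"region {region} outside track interval {iv}")
    if region.start < iv.start or region.end > iv.end:
        raise CoverageError(f"region {region} not fully covered by {iv}")
    first = (region.start - iv.start) // track.bin_width
    last = (region.end - iv.start) // track.bin_width
    return float(np.median(track.depths[first: last + 1]))


def selectivity_score(
    tracks: Sequence[CoverageTrack],
    region: GenomicInterval,
    target_cell_type: str,
) -> SelectivityResult:
    """Target cell type's share of total regional accessibility.

    When every cell type's median is 0 the ratio is undefined; the result is
    flagged rather than raising.
    """
    if len(tracks) < 2:
        raise ValidationError("need >= 2 cell-type tracks")
    names = [t.cell_type for t in tracks]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate cell-type names")
    if target_cell_type not in names:
        raise ValidationError(f"target {target_cell_type!r} not among tracks")
    medians = {t.cell_type: region_median_depth(t, region) for t in tracks}
    total = sum(medians.values())
    if total == 0:
        return SelectivityResult(region, medians, {}, target_cell_type, undefined=True)
    return SelectivityResult(
        region,
        medians,
        {ct: m / total for ct, m in medians.items()},
        target_cell_type,
    )


def rank_regions(
    tracks: Sequence[CoverageTrack],
    regions: Sequence[GenomicInterval],
    target_cell_type: str,
) -> list[tuple[GenomicInterval, SelectivityResult]]:
    """Regions in descending order of target selectivity.

    Ties break by genomic position; regions with undefined selectivity sort
    last.
    """
    if not regions:
        raise ValidationError("no regions")
    scored = [
        (r, selectivity_score(tracks, r, target_cell_type)) for r in regions
    ]
    return sorted(
        scored,
        key=lambda rs: (
            rs[1].undefined,
            -(rs[1].target_selectivity or 0.0),
            rs[0].chrom,
            rs[0].start,
        ),
    )


def write_selectivity_tsv(result: SelectivityResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# region {result.region}, target {result.target_cell_type}\n")
        fh.write("cell_type\tmedian_depth\tselectivity\n")
        for ct in sorted(result.median_depth):
            sel = result.selectivity.get(ct)
            fh.write(
                f"{ct}\t{result.median_depth[ct]:.6g}\t"
                f"{'NA' if sel is None else f'{sel:.6g}'}\n"
            )
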