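"""Binned coverage analysis of the SDR: calling male-specific regions.

A Y-hemizygous interval is present on one haplotype only, so in whole-genome
sequencing it shows ~half-depth coverage in an XY male and zero coverage in
an XX female.  Depth is binned (200-bp bins over the SDR by default),
normalized per sample so a diploid single-copy bin has expected depth 1,
and male-specific intervals are called as runs of bins with male depth above
and female depth below thresholds.  RNA coverage on the same grid flags
whether a called region is transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval


@dataclass(frozen=True)
class CoverageTrack:
    """Per-bin depth for one sample on a fixed bin grid.

    ``normalizer`` is None for raw tracks and holds the scalar divisor
    (median autosomal-equivalent bin depth) after normalization.
    """

    sample_id: str
    bins: tuple[GenomicInterval, ...]
    depth: np.ndarray
    normalizer: float | None = None

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "bins", tuple(self.bins))
        if depth.shape != (len(self.bins),):
            raise ValueError(
                f"depth length {depth.shape} does not match {len(self.bins)} bins"
            )
        if np.any(depth < 0):
            raise ValueError("negative bin depth")


def normalize_track(
    raw: CoverageTrack, reference_depth: float | None = None
) -> CoverageTrack:
    """Scale a raw track so a diploid single-copy bin has expected depth 1.

    ``reference_depth`` defaults to the sample's median bin depth, which is
    robust as long as candidate (hemizygous or deleted) bins are a minority
    of the grid.
    """
    if reference_depth is None:
        reference_depth = float(np.median(raw.depth))
    if reference_depth <= 0:
        raise ValueError(
            f"reference depth must be positive, got {reference_depth} "
            f"(sample {raw.sample_id})"
        )
    return replace(raw, depth=raw.depth / reference_depth, normalizer=reference_depth)


def call_male_specific(
    male_track: CoverageTrack,
    female_track: CoverageTrack,
    male_min: float = 0.3,
    female_max: float = 0.1,
    min_run: int = 2,
) -> list[GenomicInterval]:
    """Call male-specific (Y-hemizygous) intervals from normalized tracks.

    A bin qualifies when male normalized depth >= ``male_min`` (a single
    haplotype contributes ~0.5) and female depth <= ``female_max`` (absent
    from the X).  Maximal runs of >= ``min_run`` consecutive qualifying bins
    are merged into intervals; shorter runs are treated as noise.
    """
    if male_track.bins != female_track.bins:
        raise ValueError("male and female tracks are on different bin grids")
    qualifying = (male_track.depth >= male_min) & (female_track.depth <= female_max)
    intervals: list[GenomicInterval] = []
    run_start: int | None = None
    bins = male_track.bins
    for i, q in enumerate(list(qualifying) + [False]):
        if q and run_start is None:
            run_start = i
        elif not q and run_start is not None:
            if i - run_start >= min_run:
                intervals.append(
                    GenomicInterval(
                        bins[run_start].chrom, bins[run_start].start, bins[i - 1].end
                    )
                )
            run_start = None
    return intervals


def overlay_expression(
    regions: Sequence[GenomicInterval],
    rna_tracks: Mapping[str, CoverageTrack],
    expressed_min: float = 0.1,
) -> pd.DataFrame:
    """Flag transcription over candidate regions, per tissue.

    A region counts as expressed in a tissue when the mean normalized RNA
    depth over its overlapping bins is >= ``expressed_min``.  Returns one
    row per region x tissue with columns chrom, start, end, tissue,
    mean_rna_depth, expressed.
    """
    rows = []
    for region in regions:
        for tissue, track in rna_tracks.items():
            mask = np.array([b.overlaps(region) for b in track.bins])
            mean_depth = float(track.depth[mask].mean()) if mask.any() else 0.0
            rows.append(
                {
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "tissue": tissue,
                    "mean_rna_depth": mean_depth,
                    "expressed": mean_depth >= expressed_min,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "tissue", "mean_rna_depth", "expressed"],
    )


def write_regions_bed(regions: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tmale_specific_{i}\n")


def read_track_tsv(path: str | Path) -> dict[str, CoverageTrack]:
    """Read per-bin depth TSV (chrom, start, end, then one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    bins = tuple(
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    )
    return {
        col: CoverageTrack(col, bins, df[col].to_numpy(dtype=float))
        for col in df.columns[3:]
    }


def write_track_tsv(tracks: Mapping[str, CoverageTrack], path: str | Path) -> None:
    tracks = dict(tracks)
    first = next(iter(tracks.values()))
    for t in tracks.values():
        if t.bins != first.bins:
            raise ValueError("tracks on different bin grids cannot share a file")
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in first.bins],
            "start": [b.start for b in first.bins],
            "end": [b.end for b in first.bins],
            **{name: t.depth for name, t in tracks.items()},
        }
    )
    df.to_csv(path, sep="\t", index=False)
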