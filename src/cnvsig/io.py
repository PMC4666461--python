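"""Readers and writers for the package's tab-delimited and JSON artifacts."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .association import GenomicRegion, region_table
from .cna import Segment
from .cohort import CloneMap


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    """TSV with a sample-id header row; NaN written empty."""
    matrix.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clone_map(clone_map: CloneMap, path: str | Path) -> None:
    """BED-like TSV: chrom, start (bp), end (bp), clone_id, position_mb."""
    frame = clone_map.frame
    bed = pd.DataFrame({
        "chrom": "chr" + frame["chromosome"].astype(str),
        "start": (frame["position_mb"] * 1_000_000).round().astype(int),
        "end": (frame["position_mb"] * 1_000_000).round().astype(int) + 1,
        "clone_id": frame["clone_id"],
        "position_mb": frame["position_mb"],
    })
    bed.to_csv(path, sep="\t", index=False)


def read_clone_map(path: str | Path) -> CloneMap:
    bed = pd.read_csv(path, sep="\t")
    return CloneMap(pd.DataFrame({
        "clone_id": bed["clone_id"],
        "chromosome": bed["chrom"].astype(str).str.removeprefix("chr").astype(int),
        "position_mb": bed["position_mb"].astype(float),
    }))


def write_seg(segments_by_sample: dict[str, Sequence[Segment]],
              clone_map: CloneMap, path: str | Path) -> None:
    """SEG format: sample, chrom, loc.start, loc.end, num.mark, seg.mean.

    Starts/ends are the genomic positions (Mb) of the first/last clone of the
    segment, per sample, using the non-missing clone order of the map.
    """
    rows = []
    for sample, segments in segments_by_sample.items():
        by_chrom: dict[int, list[Segment]] = {}
        for seg in segments:
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in by_chrom.items():
            pos = clone_map.chromosome_frame(chrom)["position_mb"].to_numpy()
            for seg in sorted(segs, key=lambda s: s.start):
                rows.append({
                    "sample": sample, "chrom": chrom,
                    "loc.start": pos[min(seg.start, len(pos) - 1)],
                    "loc.end": pos[min(seg.end - 1, len(pos) - 1)],
                    "num.mark": seg.n_clones,
                    "seg.mean": round(seg.mean, 4),
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    write_matrix(calls, path, index_name="clone_id")


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_regions(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    region_table(regions).to_csv(path, sep="\t", index=False)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, default=str))


def read_labels(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0]
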