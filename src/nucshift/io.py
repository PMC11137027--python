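"""Reading and writing the pipeline's file formats.

Inputs are plain or gzipped BED3/BEDPE fragment files and BED6 anchor
files; outputs are TSVs with headers and bedGraph tracks.  Coordinates are
0-based half-open throughout.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

_STRANDS = {"+", "-", "."}


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read fragments from BED3 (chrom, start, end) or BEDPE.

    BEDPE mates must share a chromosome; the fragment spans the outer
    coordinates of the pair.  Malformed lines raise with their line
    number.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if len(f) >= 6 and not f[3].isdigit():
                    # BEDPE: chrom1 start1 end1 chrom2 start2 end2 ...
                    c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
                    if c1 != c2:
                        raise ValueError("mates on different chromosomes")
                    start, end = min(s1, s2), max(e1, e2)
                    chrom = c1
                else:
                    chrom, start, end = f[0], int(f[1]), int(f[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    logger.info("read %d fragments from %s", len(df), path)
    return df


def read_anchors(path: str | Path) -> pd.DataFrame:
    """Read point anchors from BED6 (strand in column 6, '.' allowed).

    Intervals wider than one base are reduced to their midpoint (logged);
    '.' strands are treated as '+'.
    """
    rows = []
    n_intervals = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = f[3] if len(f) > 3 and f[3] not in {"", "."} else f"anchor_{lineno}"
            strand = f[5] if len(f) > 5 else "."
            if strand not in _STRANDS:
                raise ValueError(f"{path}:{lineno}: bad strand token {strand!r}")
            if end - start > 1:
                n_intervals += 1
            position = (start + end - 1) // 2
            rows.append((name, chrom, position, "+" if strand == "." else strand))
    if n_intervals:
        logger.info("%d interval anchors reduced to midpoints", n_intervals)
    df = pd.DataFrame(rows, columns=["anchor_id", "chrom", "position", "strand"])
    if df["anchor_id"].duplicated().any():
        dup = df.loc[df["anchor_id"].duplicated(), "anchor_id"].iloc[0]
        raise ValueError(f"{path}: duplicate anchor id {dup!r}")
    logger.info("read %d anchors from %s", len(df), path)
    return df


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_anchors_bed6(anchors: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": anchors["chrom"],
            "start": anchors["position"],
            "end": anchors["position"] + 1,
            "name": anchors["anchor_id"],
            "score": 0,
            "strand": anchors["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(
    profile: pd.DataFrame, path: str | Path, chrom: str, anchor_pos: int,
    column: str = "smoothed",
) -> None:
    """Write an aggregate or per-anchor profile as bedGraph around a locus."""
    with open(path, "w") as fh:
        for _, row in profile.iterrows():
            pos = anchor_pos + int(row["offset"])
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{row[column]:.6g}\n")
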