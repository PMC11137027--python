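"""Per-base nucleosome occupancy scoring around anchors.

The raw signal is the nucleosome center positioning (NCP) score ``S_k``:
the normalized count of canonical-nucleosome fragment midpoints at base
``k``.  Profiles are smoothed with a Gaussian center weight

    w_j = exp(-(j / sigma)^2 / 2),   j in [-halfwidth, +halfwidth]

with ``sigma = 20`` bp and ``halfwidth = 73`` bp by default, so that the
center-weighted occupancy at ``k`` is ``sum_j S_{k+j} w_j``.  All
coordinates are 0-based half-open (BED convention); anchor-relative offsets
are strand-oriented so that negative offsets are always upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end"]

#: inclusive fragment-length bounds for canonical mono-nucleosomes (bp)
CANONICAL_MIN_LEN = 140
CANONICAL_MAX_LEN = 180


@dataclass(frozen=True)
class GaussianKernel:
    """Gaussian center weight w_j = exp(-(j/sigma)^2 / 2) over |j| <= halfwidth."""

    sigma: float = 20.0
    halfwidth: int = 73

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.halfwidth < 0:
            raise ValueError(f"halfwidth must be >= 0, got {self.halfwidth}")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.halfwidth, self.halfwidth + 1)

    @property
    def weights(self) -> np.ndarray:
        j = self.offsets
        return np.exp(-((j / self.sigma) ** 2) / 2.0)


@dataclass
class OccupancyProfile:
    """Strand-oriented per-base profile around one anchor.

    ``offsets`` are anchor-relative (negative = upstream after strand
    orientation); ``raw`` holds the NCP score S_k and ``smoothed`` the
    center-weighted occupancy on the same offset axis.
    """

    anchor_id: str
    offsets: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    library_factor: float = 1.0
    n_fragments: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.raw = np.asarray(self.raw, dtype=float)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        if not (len(self.offsets) == len(self.raw) == len(self.smoothed)):
            raise ValueError("offsets, raw and smoothed must share one axis")


def _validate_fragments(fragments: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FRAGMENT_COLUMNS if c not in fragments.columns]
    if missing:
        raise ValueError(f"fragment table lacks columns {missing}")
    bad = fragments.index[fragments["start"] >= fragments["end"]]
    if len(bad):
        raise ValueError(
            f"{len(bad)} fragments with start >= end (first at row {bad[0]})"
        )
    return fragments


def filter_canonical_fragments(
    fragments: pd.DataFrame,
    min_len: int = CANONICAL_MIN_LEN,
    max_len: int = CANONICAL_MAX_LEN,
) -> pd.DataFrame:
    """Retain fragments whose length lies in [min_len, max_len], inclusive.

    The canonical mono-nucleosome window is 140-180 bp; sub-nucleosomal and
    di-nucleosomal fragments are discarded.  Input order is preserved.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    _validate_fragments(fragments)
    lengths = fragments["end"] - fragments["start"]
    return fragments.loc[(lengths >= min_len) & (lengths <= max_len)]


def fragment_midpoints(fragments: pd.DataFrame) -> pd.DataFrame:
    """Count fragment midpoints per base.

    The midpoint of the half-open interval [start, end) is
    ``(start + end - 1) // 2`` — even-length fragments round down.  Returns
    a table (chrom, pos, count) with counts summing to the number of
    fragments.
    """
    _validate_fragments(fragments)
    if len(fragments) == 0:
        return pd.DataFrame({"chrom": [], "pos": [], "count": []}).astype(
            {"chrom": str, "pos": int, "count": int}
        )
    mids = (fragments["start"] + fragments["end"] - 1) // 2
    out = (
        pd.DataFrame({"chrom": fragments["chrom"].to_numpy(), "pos": mids.to_numpy()})
        .groupby(["chrom", "pos"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def ncp_score(
    midpoint_counts: np.ndarray | pd.Series,
    library_factor: float,
    scale: float = 1e6,
) -> np.ndarray:
    """NCP score S_k = count_k / library_factor * scale.

    With ``library_factor`` equal to the total fragment count this is CPM
    semantics: the genome-wide scores sum to ``scale``.
    """
    if library_factor <= 0:
        raise ValueError(f"library_factor must be > 0, got {library_factor}")
    counts = np.asarray(midpoint_counts, dtype=float)
    return counts / library_factor * scale


def center_weighted_occupancy(
    scores: np.ndarray, kernel: GaussianKernel | None = None
) -> np.ndarray:
    """Gaussian center-weighted occupancy: out_k = sum_j S_{k+j} w_j.

    Out-of-range scores are treated as zero.  The operator is linear and,
    because the kernel is symmetric, identical to a same-mode convolution.
    """
    if kernel is None:
        kernel = GaussianKernel()
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return scores.copy()
    # symmetric kernel: correlation equals convolution; zero padding at ends
    return convolve1d(scores, kernel.weights, mode="constant", cval=0.0)


def _window_counts(
    midpoints: pd.DataFrame, chrom: str, lo: int, hi: int
) -> np.ndarray:
    """Dense midpoint counts for positions [lo, hi] (inclusive) on chrom."""
    sub = midpoints[midpoints["chrom"] == chrom]
    counts = np.zeros(hi - lo + 1, dtype=float)
    if len(sub):
        pos = sub["pos"].to_numpy()
        sel = (pos >= lo) & (pos <= hi)
        counts[pos[sel] - lo] = sub.loc[sel, "count"].to_numpy()
    return counts


def anchor_profile(
    midpoints: pd.DataFrame,
    anchor: pd.Series | dict,
    window_halfwidth: int = 1000,
    kernel: GaussianKernel | None = None,
    library_factor: float = 1.0,
    chrom_sizes: dict[str, int] | None = None,
) -> OccupancyProfile | None:
    """Strand-oriented occupancy profile for one anchor.

    The raw NCP score is extracted over ``anchor.position +/-
    (window_halfwidth + kernel.halfwidth)`` and smoothed before cropping to
    ``+/- window_halfwidth``, so smoothed values inside the window are
    unaffected by edge padding.  For "-"-strand anchors the offset axis is
    reversed (negative offsets are 5' of the gene).  Strandless anchors
    (".") are treated as "+".  Anchors falling entirely off the chromosome
    are skipped with a warning (returns None); partially clipped windows
    are zero-filled outside the chromosome.
    """
    if kernel is None:
        kernel = GaussianKernel()
    if window_halfwidth <= 0:
        raise ValueError("window_halfwidth must be positive")
    chrom = anchor["chrom"]
    position = int(anchor["position"])
    strand = anchor.get("strand", "+") if isinstance(anchor, dict) else anchor.get("strand", "+")
    if strand not in {"+", "-", "."}:
        raise ValueError(f"bad strand {strand!r} for anchor {anchor['anchor_id']}")
    if chrom_sizes is not None:
        size = chrom_sizes.get(chrom)
        if size is not None and (position < 0 or position >= size):
            logger.warning(
                "anchor %s at %s:%d outside chromosome; skipped",
                anchor["anchor_id"], chrom, position,
            )
            return None
    pad = kernel.halfwidth
    lo = position - window_halfwidth - pad
    hi = position + window_halfwidth + pad
    counts = _window_counts(midpoints, chrom, lo, hi)
    raw = ncp_score(counts, library_factor)
    smoothed = center_weighted_occupancy(raw, kernel)
    sl = slice(pad, len(raw) - pad)
    raw, smoothed = raw[sl], smoothed[sl]
    offsets = np.arange(-window_halfwidth, window_halfwidth + 1)
    if strand == "-":
        raw = raw[::-1].copy()
        smoothed = smoothed[::-1].copy()
    n_frag = int(counts.sum())
    return OccupancyProfile(
        anchor_id=str(anchor["anchor_id"]),
        offsets=offsets,
        raw=raw,
        smoothed=smoothed,
        library_factor=library_factor,
        n_fragments=n_frag,
    )


def aggregate_profile(profiles: list[OccupancyProfile]) -> pd.DataFrame:
    """Per-offset mean over anchors, with the contributing-anchor count.

    Profiles may cover different offset ranges (clipped anchors); missing
    offsets are excluded from the mean and the ``n`` column tracks how many
    anchors contributed at each offset.
    """
    if not profiles:
        raise ValueError("aggregate_profile requires at least one profile")
    frames = [
        pd.DataFrame(
            {"offset": p.offsets, "raw": p.raw, "smoothed": p.smoothed}
        )
        for p in profiles
    ]
    long = pd.concat(frames, ignore_index=True)
    agg = (
        long.groupby("offset", sort=True)
        .agg(raw=("raw", "mean"), smoothed=("smoothed", "mean"), n=("raw", "size"))
        .reset_index()
    )
    return agg
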