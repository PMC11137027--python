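"""Library normalization schemes, background correction, and region logic.

Three normalization schemes are provided:

* library size — CPM: count / library_size * 1e6;
* spike-in chromatin — factor_i = mean(mouse_reads) * spike_i / spike_ref,
  so that genuine global signal changes survive normalization while
  technical depth differences cancel;
* conserved genes — factors from robustly expressed (> 500 CPM in every
  library) genes with no BRG1 enrichment near the gene.

Background correction subtracts the outside-peak read density from
per-peak densities.  Region utilities implement the fixed distance
conventions (5'/3' = within 1000 bp of TSS/TTS; TSS-class peaks <= 2 kb
from a TSS; nonTSS > 5 kb) and the differential-summary cutoffs
(P < 0.05 and fold-change > 1.3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LibraryStats:
    """Per-library read totals used by the normalization schemes."""

    library_id: str
    condition: str
    mouse_reads: int
    spike_reads: int = 0
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.mouse_reads <= 0:
            raise ValueError(f"{self.library_id}: mouse_reads must be > 0")
        if self.spike_reads < 0:
            raise ValueError(f"{self.library_id}: spike_reads must be >= 0")


def libsize_normalize(
    counts: np.ndarray | pd.Series, library_size: float, scale: float = 1e6
) -> np.ndarray | pd.Series:
    """CPM: count / library_size * scale."""
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    return counts / library_size * scale


def choose_reference(stats: list[LibraryStats]) -> LibraryStats:
    """Default spike-in reference: the control library with median spike reads."""
    ctrl = [s for s in stats if s.condition == "control"]
    if not ctrl:
        raise ValueError("spike-in normalization needs at least one control library")
    ctrl = sorted(ctrl, key=lambda s: (s.spike_reads, s.library_id))
    return ctrl[(len(ctrl) - 1) // 2]


def spikein_factors(stats: list[LibraryStats]) -> pd.Series:
    """Two-component spike-in normalization factors.

    factor_i = mean over libraries of mouse_reads  *  spike_i / spike_ref.
    Normalized density is then count_i / factor_i * 1e6.  Exactly one
    library may be flagged ``is_reference``; if none is, the control
    library with median spike reads is used.
    """
    if not stats:
        raise ValueError("no libraries given")
    for s in stats:
        if s.spike_reads <= 0:
            raise ValueError(f"{s.library_id}: spike_reads must be > 0 for spike-in")
    refs = [s for s in stats if s.is_reference]
    if len(refs) > 1:
        raise ValueError("more than one reference library designated")
    ref = refs[0] if refs else choose_reference(stats)
    mean_mouse = float(np.mean([s.mouse_reads for s in stats]))
    return pd.Series(
        {s.library_id: mean_mouse * s.spike_reads / ref.spike_reads for s in stats}
    )


def apply_factors(
    counts: pd.DataFrame, factors: pd.Series, scale: float = 1e6
) -> pd.DataFrame:
    """Normalized densities: count / factor * scale, column per library."""
    missing = [c for c in counts.columns if c not in factors.index]
    if missing:
        raise ValueError(f"no factor for libraries {missing}")
    return counts / factors[counts.columns] * scale


def _overlaps(
    chrom: str, start: int, end: int, peaks: pd.DataFrame
) -> bool:
    sub = peaks[peaks["chrom"] == chrom]
    if not len(sub):
        return False
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def conserved_gene_factors(
    genes: pd.DataFrame,
    counts: pd.DataFrame,
    brg1_peaks: pd.DataFrame,
    cpm_threshold: float = 500.0,
    library_sizes: pd.Series | None = None,
    promoter_pad: int = 2000,
) -> tuple[pd.Series, list[str]]:
    """Normalization factors from robustly expressed, BRG1-free genes.

    ``genes`` has columns (gene_id, chrom, start, end, strand); ``counts``
    is genes x libraries.  A gene qualifies when its CPM exceeds
    ``cpm_threshold`` in *every* library and its body extended
    ``promoter_pad`` bp upstream overlaps no BRG1 peak.  The factor for
    library i is its selected-gene count sum divided by the mean of that
    sum across libraries (so factors average to 1).
    """
    counts = counts.loc[genes["gene_id"]]
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    cpm = counts / library_sizes * 1e6
    robust = (cpm > cpm_threshold).all(axis=1)
    selected = []
    for _, g in genes.iterrows():
        if not robust.loc[g["gene_id"]]:
            continue
        start, end = int(g["start"]), int(g["end"])
        if g["strand"] == "-":
            end = end + promoter_pad
        else:
            start = max(0, start - promoter_pad)
        if not _overlaps(g["chrom"], start, end, brg1_peaks):
            selected.append(g["gene_id"])
    if not selected:
        near = cpm.min(axis=1).nlargest(5)
        raise ValueError(
            "no conserved genes selected; closest by min-library CPM: "
            + ", ".join(f"{g}={v:.0f}" for g, v in near.items())
        )
    sums = counts.loc[selected].sum(axis=0)
    factors = sums / sums.mean()
    return factors, selected


def background_correct(
    reads_in_peaks: np.ndarray | pd.Series,
    peak_sizes: np.ndarray | pd.Series,
    reads_outside: float,
    effective_genome_size: float,
) -> np.ndarray:
    """Per-peak read density minus the outside-peak background density.

    corrected_p = reads_p / size_p - reads_outside / (G - total peak
    length), floored at 0.  Library-factor scaling is applied separately.
    """
    reads_in_peaks = np.asarray(reads_in_peaks, dtype=float)
    peak_sizes = np.asarray(peak_sizes, dtype=float)
    if np.any(peak_sizes <= 0):
        raise ValueError("peak sizes must be positive")
    total_peak = peak_sizes.sum()
    if effective_genome_size <= total_peak:
        raise ValueError("effective genome size must exceed total peak length")
    background = reads_outside / (effective_genome_size - total_peak)
    return np.maximum(reads_in_peaks / peak_sizes - background, 0.0)


def make_regions(
    tss: pd.DataFrame,
    tts: pd.DataFrame | None = None,
    peaks: pd.DataFrame | None = None,
    flank: int = 1000,
    tss_max_dist: int = 2000,
    nontss_min_dist: int = 5000,
) -> pd.DataFrame:
    """Region scaffold with the fixed distance conventions.

    Emits 5' regions (TSS +/- ``flank``) and 3' regions (TTS +/- ``flank``)
    and classifies each peak by the distance of its midpoint to the nearest
    TSS: ``TSS`` when <= ``tss_max_dist``, ``nonTSS`` when >
    ``nontss_min_dist``, excluded otherwise.  TSS entries must carry a
    strand.
    """
    if "strand" not in tss.columns or tss["strand"].isin([None, ""]).any():
        raise ValueError("TSS set must be strand-annotated")
    rows = []
    for _, t in tss.iterrows():
        p = int(t["position"])
        rows.append(
            {"region_id": f"fivePrime:{t['anchor_id']}", "chrom": t["chrom"],
             "start": max(0, p - flank), "end": p + flank, "kind": "fivePrime"}
        )
    if tts is not None:
        for _, t in tts.iterrows():
            p = int(t["position"])
            rows.append(
                {"region_id": f"threePrime:{t['anchor_id']}", "chrom": t["chrom"],
                 "start": max(0, p - flank), "end": p + flank, "kind": "threePrime"}
            )
    if peaks is not None:
        tss_by_chrom = {
            c: np.sort(g["position"].to_numpy()) for c, g in tss.groupby("chrom")
        }
        for i, pk in peaks.reset_index(drop=True).iterrows():
            mid = (int(pk["start"]) + int(pk["end"]) - 1) // 2
            pos = tss_by_chrom.get(pk["chrom"])
            if pos is None or len(pos) == 0:
                dist = np.inf
            else:
                j = np.searchsorted(pos, mid)
                cands = pos[max(0, j - 1): j + 1]
                dist = np.abs(cands - mid).min()
            if dist <= tss_max_dist:
                kind = "TSS"
            elif dist > nontss_min_dist:
                kind = "nonTSS"
            else:
                continue  # intermediate distances belong to neither class
            rid = pk.get("region_id", f"peak{i}")
            rows.append(
                {"region_id": rid, "chrom": pk["chrom"], "start": int(pk["start"]),
                 "end": int(pk["end"]), "kind": kind}
            )
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "kind"])


def differential_summary(
    results: pd.DataFrame,
    alpha: float = 0.05,
    fc_cut: float = 1.3,
) -> dict:
    """Counts and fractions of changed regions under the joint cutoff.

    A region is significant when p_value < ``alpha`` and its fold change
    (depleted/control) lies outside [1/fc_cut, fc_cut].  Fractions of
    down/up are computed over the changed regions; ``frac_changed`` over
    all regions.  Percentages are on the 0-100 scale.
    """
    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1")
    if (results["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive")
    sig = (results["p_value"] < alpha) & (
        (results["fold_change"] > fc_cut) | (results["fold_change"] < 1 / fc_cut)
    )
    changed = results[sig]
    n_changed = len(changed)
    n_down = int((changed["fold_change"] < 1).sum())
    n_up = n_changed - n_down
    return {
        "n_total": len(results),
        "n_changed": n_changed,
        "n_down": n_down,
        "n_up": n_up,
        "pct_down_of_changed": 100.0 * n_down / n_changed if n_changed else float("nan"),
        "pct_up_of_changed": 100.0 * n_up / n_changed if n_changed else float("nan"),
        "frac_changed": n_changed / len(results) if len(results) else float("nan"),
    }


def tertile_groups(values: np.ndarray | pd.Series) -> np.ndarray:
    """Equal-count low/medium/high groups by rank, ties by input order."""
    values = np.asarray(values)
    n = len(values)
    if n < 3:
        raise ValueError("tertile grouping needs at least 3 values")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=object)
    for name, chunk in zip(("low", "medium", "high"), np.array_split(order, 3)):
        labels[chunk] = name
    return labels
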