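"""Synthetic MNase-fragment and count-matrix generator.

The generator emulates the statistical structure the downstream analysis
assumes: each anchor has a -1 and a +1 nucleosome whose fragment dyads are
Gaussian around the true centers (fuzziness), a uniform linker/background
fragment rate, and a fragment-length distribution that straddles the
140-180 bp canonical window so the length filter is exercised.  In the
depleted condition, group-specific dyad displacements are injected at the
-1 and/or +1 centers; all randomness flows from a single master seed via
deterministic sub-seeds per condition and replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import LibraryStats

#: injected dyad displacements (delta_minus1, delta_plus1) in bp, matching
#: the reported TSS shift magnitudes (downstream positive for -1, upstream
#: negative for +1)
DEFAULT_GROUPS: dict[str, tuple[float, float]] = {
    "non-shift": (0.0, 0.0),
    "Shift1": (0.0, -36.0),
    "Shift2": (49.0, 0.0),
    "Shift3": (40.0, -27.0),
}

DEFAULT_LENGTH_LAW: dict = {
    "kind": "normal", "mean": 160.0, "sd": 20.0, "min": 100, "max": 240,
}


@dataclass
class NucleosomeArchitecture:
    """True -1/+1 architecture of one anchor, in anchor-oriented bp.

    ``minus1_center`` is upstream (negative) and ``plus1_center``
    downstream (positive) of the anchor; ``fuzziness_sd`` is the Gaussian
    dyad jitter; occupancies are expected fragment counts per nucleosome
    and ``background_rate`` expected background fragments per bp.
    """

    anchor_id: str
    minus1_center: float = -95.0
    plus1_center: float = 55.0
    fuzziness_sd: float = 20.0
    occupancy_minus1: float = 900.0
    occupancy_plus1: float = 900.0
    background_rate: float = 0.2
    group: str = "non-shift"
    chrom: str = "chrSim"
    position: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.minus1_center < 0 < self.plus1_center:
            raise ValueError(
                f"{self.anchor_id}: need minus1_center < 0 < plus1_center, "
                f"got ({self.minus1_center}, {self.plus1_center})"
            )
        if self.fuzziness_sd < 0:
            raise ValueError(f"{self.anchor_id}: fuzziness_sd must be >= 0")
        if self.occupancy_minus1 < 0 or self.occupancy_plus1 < 0:
            raise ValueError(f"{self.anchor_id}: occupancies must be >= 0")
        if self.background_rate < 0:
            raise ValueError(f"{self.anchor_id}: background_rate must be >= 0")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort."""

    n_anchors: int = 200
    groups: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    fragment_length_law: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_LAW)
    )
    window_halfwidth: int = 500
    seed: int = 0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be positive")
        if self.n_anchors <= 0:
            raise ValueError("n_anchors must be positive")


@dataclass
class SpikeInSimSpec:
    """Per-library truth for the spike-in normalization simulation."""

    library_id: str
    condition: str
    mouse_reads: int
    spike_reads: int
    true_global_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mouse_reads <= 0 or self.spike_reads <= 0:
            raise ValueError(f"{self.library_id}: read counts must be > 0")
        if self.true_global_factor <= 0:
            raise ValueError(f"{self.library_id}: true_global_factor must be > 0")


def _condition_rng(config: SimulationConfig, condition: str, replicate: int):
    code = {"control": 0, "depleted": 1}[condition]
    return np.random.default_rng([config.seed, code, replicate])


def sample_lengths(law: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    """Integer fragment lengths from a configured length law."""
    kind = law.get("kind", "normal")
    if size == 0:
        return np.zeros(0, dtype=int)
    if kind == "fixed":
        return np.full(size, int(law["length"]))
    if kind == "uniform":
        return rng.integers(int(law["min"]), int(law["max"]) + 1, size=size)
    if kind == "normal":
        lo, hi = float(law["min"]), float(law["max"])
        mean, sd = float(law["mean"]), float(law["sd"])
        a, b = (lo - mean) / sd, (hi - mean) / sd
        x = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
        return np.rint(x).astype(int)
    raise ValueError(f"unknown fragment_length_law kind {kind!r}")


def default_cohort(
    config: SimulationConfig, spacing: int = 10_000, **arch_kwargs
) -> tuple[list[NucleosomeArchitecture], pd.DataFrame]:
    """Cohort of ``n_anchors`` per group on one synthetic chromosome.

    Returns the architectures and a matching anchor table (anchor_id,
    chrom, position, strand, kind, group).  Extra keyword arguments
    override :class:`NucleosomeArchitecture` defaults (fuzziness,
    occupancies, centers...).
    """
    archs: list[NucleosomeArchitecture] = []
    pos = spacing
    for group in config.groups:
        for i in range(config.n_anchors):
            archs.append(
                NucleosomeArchitecture(
                    anchor_id=f"{group}_{i}",
                    group=group,
                    position=pos,
                    **arch_kwargs,
                )
            )
            pos += spacing
    anchors = pd.DataFrame(
        {
            "anchor_id": [a.anchor_id for a in archs],
            "chrom": [a.chrom for a in archs],
            "position": [a.position for a in archs],
            "strand": [a.strand for a in archs],
            "kind": "TSS",
            "group": [a.group for a in archs],
        }
    )
    return archs, anchors


def _fragments_for_dyads(
    dyads: np.ndarray, lengths: np.ndarray, chrom: str, library_id: str
) -> pd.DataFrame:
    starts = dyads - (lengths - 1) // 2
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + lengths,
         "library_id": library_id}
    )


def simulate_fragments(
    architectures: list[NucleosomeArchitecture],
    config: SimulationConfig,
    condition: str,
    replicate: int = 0,
) -> pd.DataFrame:
    """Draw one fragment library for one condition.

    Per anchor, Poisson(occupancy) fragments per nucleosome with dyads
    Normal(center [+ injected group delta when depleted], fuzziness_sd),
    plus Poisson(background_rate * window) uniform background fragments;
    every fragment takes its length from the configured law and is emitted
    as a 0-based half-open interval whose midpoint is its (rounded) dyad.
    Deterministic for a fixed (config.seed, condition, replicate).
    """
    if not architectures:
        raise ValueError("no architectures given")
    if condition not in {"control", "depleted"}:
        raise ValueError(f"condition must be 'control' or 'depleted', got {condition!r}")
    rng = _condition_rng(config, condition, replicate)
    library_id = f"{condition}_rep{replicate}"
    law = config.fragment_length_law
    W = config.window_halfwidth
    frames = []
    for arch in architectures:
        dm, dp = (0.0, 0.0)
        if condition == "depleted":
            dm, dp = config.groups.get(arch.group, (0.0, 0.0))
        sign = -1 if arch.strand == "-" else 1
        parts = []
        for center, occ in (
            (arch.minus1_center + dm, arch.occupancy_minus1),
            (arch.plus1_center + dp, arch.occupancy_plus1),
        ):
            n = rng.poisson(occ)
            rel = center + rng.normal(0.0, arch.fuzziness_sd, size=n) if n else np.zeros(0)
            parts.append(arch.position + sign * np.rint(rel).astype(int))
        n_bg = rng.poisson(arch.background_rate * (2 * W + 1))
        parts.append(arch.position + rng.integers(-W, W + 1, size=n_bg))
        dyads = np.concatenate(parts)
        lengths = sample_lengths(law, len(dyads), rng)
        frames.append(_fragments_for_dyads(dyads, lengths, arch.chrom, library_id))
    out = pd.concat(frames, ignore_index=True)
    return out


def simulate_signal_counts(
    architectures: list[NucleosomeArchitecture],
    config: SimulationConfig,
    effect: dict[str, float],
    base_mean: float = 500.0,
    dispersion: float = 0.1,
) -> pd.DataFrame:
    """Replicated negative-binomial counts per region and condition.

    Each architecture becomes one region with a lognormal baseline around
    ``base_mean``; depleted-condition means are scaled by the group's fold
    change from ``effect``.  ``dispersion`` is the NB overdispersion
    (variance = mu + dispersion * mu^2); 0 falls back to Poisson.  Returns
    a long table (region_id, library_id, condition, replicate, group,
    count).
    """
    for group in {a.group for a in architectures}:
        if group not in effect:
            raise ValueError(f"no fold-change given for group {group!r}")
    for g, fc in effect.items():
        if fc <= 0:
            raise ValueError(f"fold-change for {g!r} must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng([config.seed, 2])
    base = base_mean * rng.lognormal(0.0, 0.5, size=len(architectures))
    rows = []
    for condition in ("control", "depleted"):
        for rep in range(config.n_replicates):
            lib = f"{condition}_rep{rep}"
            for arch, b in zip(architectures, base):
                mu = b * (effect[arch.group] if condition == "depleted" else 1.0)
                if dispersion == 0:
                    count = rng.poisson(mu)
                else:
                    r = 1.0 / dispersion
                    count = rng.negative_binomial(r, r / (r + mu))
                rows.append(
                    {"region_id": arch.anchor_id, "library_id": lib,
                     "condition": condition, "replicate": rep,
                     "group": arch.group, "count": int(count)}
                )
    return pd.DataFrame(rows)


def simulate_spikein_libraries(
    specs: list[SpikeInSimSpec],
    regions: int | pd.DataFrame = 200,
    seed: int = 0,
    base_mean: float = 200.0,
    noise: bool = True,
) -> tuple[pd.DataFrame, list[LibraryStats]]:
    """Simulate libraries carrying spike-in chromatin.

    ``true_global_factor`` is a technical global scaling (depth): it
    multiplies the expected region counts, mouse reads, *and* spike reads
    of a library, which is exactly what spike-in normalization exists to
    cancel.  Biological signal differences enter through ``mouse_reads``
    relative to the cohort mean.  Returns a regions x libraries count
    matrix and observed :class:`LibraryStats`.  With ``noise=False`` the
    expected (rounded) counts are emitted, which makes the symmetry
    contracts exact.
    """
    if not specs:
        raise ValueError("no library specs given")
    if not any(s.condition == "control" for s in specs):
        raise ValueError("at least one library must be a control")
    rng = np.random.default_rng([seed, 3])
    if isinstance(regions, int):
        region_ids = [f"region_{i}" for i in range(regions)]
        base = base_mean * rng.lognormal(0.0, 0.5, size=regions)
    else:
        region_ids = list(regions["region_id"])
        base = (
            regions["base_rate"].to_numpy(dtype=float)
            if "base_rate" in regions.columns
            else np.full(len(region_ids), base_mean)
        )
    mean_mouse = float(np.mean([s.mouse_reads for s in specs]))
    counts = {}
    stats_out = []
    for s in specs:
        g = s.true_global_factor
        mu = base * (s.mouse_reads / mean_mouse) * g
        if noise:
            col = rng.poisson(mu)
            spike_obs = int(rng.poisson(s.spike_reads * g))
            mouse_obs = int(rng.poisson(s.mouse_reads * g))
        else:
            col = np.rint(mu).astype(int)
            spike_obs = int(round(s.spike_reads * g))
            mouse_obs = int(round(s.mouse_reads * g))
        if spike_obs == 0:
            spike_obs = 1  # guard against a zero Poisson draw at tiny rates
        counts[s.library_id] = col
        stats_out.append(
            LibraryStats(
                library_id=s.library_id,
                condition=s.condition,
                mouse_reads=max(mouse_obs, 1),
                spike_reads=spike_obs,
            )
        )
    matrix = pd.DataFrame(counts, index=pd.Index(region_ids, name="region_id"))
    return matrix, stats_out
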