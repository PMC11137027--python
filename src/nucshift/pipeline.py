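"""Full-pipeline orchestration: fragments -> profiles -> calls -> shifts.

`run_pipeline` chains occupancy profiling, -1/+1 nucleosome calling with
bootstrap SEs, shift testing/classification, Table-style group summaries
and (optionally) hypergeometric association, writing TSVs plus a
machine-readable run manifest.  All defaults match the analysis
parameters: 140-180 bp fragments, sigma 20 / halfwidth 73 kernel, +/-150
bp search, prominence 0.1, 90% confidence, bootstrap B = 200.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_anchors, read_fragments, write_tsv
from .occupancy import GaussianKernel
from .peaks import NucleosomeCaller
from .shift import associate_with_signal, calls_to_frame, shift_call, summarize_groups

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one end-to-end run."""

    fragments_control: list[str] = field(default_factory=list)
    fragments_depleted: list[str] = field(default_factory=list)
    anchors: str = ""
    decreased_sets: dict[str, str] = field(default_factory=dict)
    outdir: str = "nucshift_out"
    min_len: int = 140
    max_len: int = 180
    sigma: float = 20.0
    kernel_halfwidth: int = 73
    window_halfwidth: int = 150
    search_halfwidth: int = 150
    min_prominence: float = 0.1
    confidence: float = 0.90
    alpha: float = 0.05
    fc: float = 1.3
    bootstrap_B: int = 200
    seed: int = 0
    refine: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _caller(config: PipelineConfig) -> NucleosomeCaller:
    return NucleosomeCaller(
        min_len=config.min_len,
        max_len=config.max_len,
        kernel=GaussianKernel(config.sigma, config.kernel_halfwidth),
        window_halfwidth=config.window_halfwidth,
        search_halfwidth=config.search_halfwidth,
        min_prominence=config.min_prominence,
        refine=config.refine,
    )


def pairs_to_frame(pairs: list) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "anchor_id": p.anchor_id,
                "condition": p.condition,
                "minus1_offset": p.minus1.offset,
                "plus1_offset": p.plus1.offset,
                "minus1_position": p.minus1.position,
                "plus1_position": p.plus1.position,
                "minus1_height": p.minus1.height,
                "plus1_height": p.plus1.height,
                "minus1_prominence": p.minus1.prominence,
                "plus1_prominence": p.plus1.prominence,
                "se_minus1": p.se_minus1,
                "se_plus1": p.se_plus1,
                "n_fragments": p.n_fragments,
                "status": p.status,
            }
        )
    return pd.DataFrame(rows)


def call_condition(
    fragments: pd.DataFrame,
    anchors: pd.DataFrame,
    condition: str,
    caller: NucleosomeCaller,
    B: int = 200,
    seed: int = 0,
) -> dict:
    """Per-anchor -1/+1 calls with bootstrap SEs for one condition.

    Returns {anchor_id: NucleosomePair} for callable anchors; bootstrap
    sub-seeds are derived deterministically from ``seed`` per anchor.
    """
    pairs = {}
    ss = np.random.SeedSequence([seed, {"control": 0, "depleted": 1}[condition]])
    children = ss.spawn(len(anchors))
    # index fragments once: per-chromosome midpoint/length arrays sorted by
    # midpoint, so each anchor slices its window in O(log n)
    by_chrom = {}
    for chrom, sub in fragments.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        mids = (starts + ends - 1) // 2
        order = np.argsort(mids, kind="stable")
        by_chrom[chrom] = (mids[order], (ends - starts)[order])
    margin = caller.window_halfwidth + caller.kernel.halfwidth
    for child, (_, anchor) in zip(children, anchors.iterrows()):
        rng = np.random.default_rng(child)
        entry = by_chrom.get(anchor["chrom"])
        if entry is None:
            continue
        mids, lengths = entry
        position = int(anchor["position"])
        lo = np.searchsorted(mids, position - margin, side="left")
        hi = np.searchsorted(mids, position + margin, side="right")
        window = caller.local_window_from_arrays(
            mids[lo:hi], lengths[lo:hi], position, anchor.get("strand", "+")
        )
        pair = caller.call_window(
            window, str(anchor["anchor_id"]), condition, B=B, rng=rng
        )
        if pair is not None and pair.status == "callable":
            pairs[pair.anchor_id] = pair
    return pairs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run occupancy -> calls -> shift -> summary (-> association).

    Returns a dict of the output tables and writes them, the resolved
    config, and a run manifest under ``config.outdir``.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.anchors:
        raise ValueError("no anchor file configured")
    if not config.fragments_control or not config.fragments_depleted:
        raise ValueError("fragment files required for both conditions")
    anchors = read_anchors(config.anchors)
    if len(anchors) == 0:
        raise ValueError(f"anchor file {config.anchors} is empty")

    def load(paths: list[str], which: str) -> pd.DataFrame:
        if not paths:
            raise ValueError(f"no {which} fragment files configured")
        # replicates are pooled at the fragment level before profiling
        return pd.concat([read_fragments(p) for p in paths], ignore_index=True)

    frags = {
        "control": load(config.fragments_control, "control"),
        "depleted": load(config.fragments_depleted, "depleted"),
    }
    caller = _caller(config)
    pairs = {}
    for condition in ("control", "depleted"):
        logger.info("calling nucleosomes: %s", condition)
        pairs[condition] = call_condition(
            frags[condition], anchors, condition, caller,
            B=config.bootstrap_B, seed=config.seed,
        )
    common = sorted(set(pairs["control"]) & set(pairs["depleted"]))
    calls = [
        shift_call(pairs["control"][a], pairs["depleted"][a], config.confidence)
        for a in common
    ]
    calls_df = calls_to_frame(calls)
    summary = summarize_groups(calls)
    outputs = {
        "calls_control": pairs_to_frame(list(pairs["control"].values())),
        "calls_depleted": pairs_to_frame(list(pairs["depleted"].values())),
        "shifts": calls_df,
        "summary": summary,
    }
    if config.decreased_sets:
        universe = set(common)
        sets = {}
        for name, path in config.decreased_sets.items():
            ids = set(pd.read_csv(path, sep="\t", header=None)[0]) & universe
            sets[name] = ids
        groups = {
            label: set(calls_df.loc[calls_df["label"] == label, "anchor_id"])
            for label in calls_df["label"].unique()
        }
        outputs["association"] = associate_with_signal(groups, sets, universe)
    for name, df in outputs.items():
        write_tsv(df, outdir / f"{name}.tsv", index=(name == "association"))
    resolved = config.to_dict()
    with open(outdir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh)
    manifest = {
        "nucshift_version": __version__,
        "seed": config.seed,
        "parameter_hash": hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_anchors": int(len(anchors)),
        "n_callable_both": len(common),
        "n_fragments": {k: int(len(v)) for k, v in frags.items()},
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = manifest
    return outputs
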