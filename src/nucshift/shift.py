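"""Shift testing and classification of -1/+1 nucleosome movement.

Between a control and a depleted condition, each flanking nucleosome is
tested for movement *toward* the anchor with a one-tailed z-score test at a
90% confidence level:

    z = (pos_dep - pos_ctrl) / sqrt(se_ctrl^2 + se_dep^2)

The expected direction is downstream (positive delta) for the -1
nucleosome and upstream (negative delta) for +1, so every significant call
narrows the -1/+1 spacing.  Anchors are classified by which nucleosome(s)
moved: Shift 1 (+1 upstream only), Shift 2 (-1 downstream only), Shift 3
(both), non-shift (neither).  Group-set association with decreased-signal
region sets uses a one-sided hypergeometric test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import NucleosomePair

logger = logging.getLogger(__name__)

LABELS = ("non-shift", "Shift1", "Shift2", "Shift3")

#: default one-tailed confidence level for the per-nucleosome z-test
CONFIDENCE = 0.90


@dataclass
class ShiftCall:
    """Per-anchor shift test results and pattern label."""

    anchor_id: str
    minus1_ctrl: float
    plus1_ctrl: float
    minus1_dep: float
    plus1_dep: float
    delta_minus1: float
    delta_plus1: float
    z_minus1: float
    z_plus1: float
    sig_minus1: bool
    sig_plus1: bool
    label: str
    spacing_control: float
    spacing_depleted: float


def z_shift_test(
    pos_ctrl: float,
    se_ctrl: float,
    pos_dep: float,
    se_dep: float,
    nucleosome: str,
    confidence: float = CONFIDENCE,
) -> tuple[float, bool]:
    """One-tailed z test for movement toward the anchor.

    ``nucleosome`` is ``"minus1"`` (expected downstream, delta > 0) or
    ``"plus1"`` (expected upstream, delta < 0).  Returns ``(z,
    significant)`` with z signed as depleted minus control.  Both SEs zero:
    equal positions give (0, False); unequal positions are significant by
    convention with infinite z in the moved direction (logged).
    """
    if nucleosome not in {"minus1", "plus1"}:
        raise ValueError(f"nucleosome must be 'minus1' or 'plus1', got {nucleosome!r}")
    if se_ctrl < 0 or se_dep < 0:
        raise ValueError("standard errors must be >= 0")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    delta = pos_dep - pos_ctrl
    se = math.hypot(se_ctrl, se_dep)
    if se == 0:
        if delta == 0:
            return 0.0, False
        z = math.copysign(math.inf, delta)
        logger.warning("zero SEs with unequal positions: z set to %s", z)
    else:
        z = delta / se
    zstar = stats.norm.ppf(confidence)
    if nucleosome == "minus1":
        significant = z > zstar
    else:
        significant = -z > zstar
    return z, bool(significant)


def classify_shift(
    call_minus1: tuple[float, bool], call_plus1: tuple[float, bool]
) -> str:
    """Pattern label from the two one-tailed (z, significant) results.

    Shift1: +1 moved upstream, -1 did not; Shift2: -1 moved downstream,
    +1 did not; Shift3: both moved; non-shift: neither.
    """
    _, sig_m = call_minus1
    _, sig_p = call_plus1
    if sig_p and not sig_m:
        return "Shift1"
    if sig_m and not sig_p:
        return "Shift2"
    if sig_m and sig_p:
        return "Shift3"
    return "non-shift"


def spacing(pair: NucleosomePair) -> float:
    """-1/+1 nucleosome spacing in bp: +1 position minus -1 position."""
    return pair.plus1.position - pair.minus1.position


def shift_call(
    ctrl: NucleosomePair,
    dep: NucleosomePair,
    confidence: float = CONFIDENCE,
) -> ShiftCall:
    """Test and classify one anchor from its control/depleted calls."""
    if ctrl.anchor_id != dep.anchor_id:
        raise ValueError(
            f"condition calls refer to different anchors: "
            f"{ctrl.anchor_id!r} vs {dep.anchor_id!r}"
        )
    zm, sm = z_shift_test(
        ctrl.minus1.position, ctrl.se_minus1, dep.minus1.position, dep.se_minus1,
        "minus1", confidence,
    )
    zp, sp = z_shift_test(
        ctrl.plus1.position, ctrl.se_plus1, dep.plus1.position, dep.se_plus1,
        "plus1", confidence,
    )
    return ShiftCall(
        anchor_id=ctrl.anchor_id,
        minus1_ctrl=ctrl.minus1.position,
        plus1_ctrl=ctrl.plus1.position,
        minus1_dep=dep.minus1.position,
        plus1_dep=dep.plus1.position,
        delta_minus1=dep.minus1.position - ctrl.minus1.position,
        delta_plus1=dep.plus1.position - ctrl.plus1.position,
        z_minus1=zm,
        z_plus1=zp,
        sig_minus1=sm,
        sig_plus1=sp,
        label=classify_shift((zm, sm), (zp, sp)),
        spacing_control=spacing(ctrl),
        spacing_depleted=spacing(dep),
    )


def calls_to_frame(calls: list[ShiftCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def summarize_groups(calls: list[ShiftCall] | pd.DataFrame, kind: str = "") -> pd.DataFrame:
    """Per-label group means in the layout of a spacing/shift table.

    One row per pattern label with the group size, the mean -1 and +1
    positions and spacing in each condition, and the mean per-nucleosome
    shifts (depleted minus control).  Empty groups get n = 0 and NaN means.
    """
    df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    rows = []
    for label in LABELS:
        sub = df[df["label"] == label] if len(df) else df
        n = len(sub)
        def m(col):
            return float(sub[col].mean()) if n else float("nan")
        rows.append(
            {
                "kind": kind,
                "label": label,
                "n": n,
                "minus1_ctrl": m("minus1_ctrl"),
                "plus1_ctrl": m("plus1_ctrl"),
                "spacing_ctrl": m("spacing_control"),
                "minus1_dep": m("minus1_dep"),
                "plus1_dep": m("plus1_dep"),
                "spacing_dep": m("spacing_depleted"),
                "shift_minus1": m("delta_minus1"),
                "shift_plus1": m("delta_plus1"),
            }
        )
    return pd.DataFrame(rows)


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """One-sided hypergeometric overlap P-value, P(X >= k).

    ``k`` overlapping items between a set of size ``K`` and a group of size
    ``n`` drawn from a universe of size ``N``.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N:
        raise ValueError("set and group sizes cannot exceed the universe")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    # survival function at k-1 gives P(X >= k); exact and log-stable
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def associate_with_signal(
    groups: dict[str, set] | list[ShiftCall],
    decreased_sets: dict[str, set],
    universe: set,
) -> pd.DataFrame:
    """-log10 one-sided hypergeometric P for each (shift group, region set).

    ``groups`` maps pattern labels to anchor-id sets (or a list of
    ShiftCalls grouped by label); ``decreased_sets`` maps signal names
    (e.g. decreased BRG1 / DNase / PRO-seq) to anchor-id sets.  All ids
    must come from ``universe`` (the callable anchors).
    """
    if not isinstance(groups, dict):
        by_label: dict[str, set] = {}
        for c in groups:
            by_label.setdefault(c.label, set()).add(c.anchor_id)
        groups = by_label
    universe = set(universe)
    N = len(universe)
    for name, s in list(groups.items()) + list(decreased_sets.items()):
        extra = set(s) - universe
        if extra:
            raise ValueError(
                f"{name!r} contains {len(extra)} ids outside the universe "
                f"(e.g. {sorted(extra)[:3]})"
            )
    mat = pd.DataFrame(
        index=list(groups), columns=list(decreased_sets), dtype=float
    )
    for g, gset in groups.items():
        for s, sset in decreased_sets.items():
            k = len(set(gset) & set(sset))
            p = hypergeometric_test(k, len(sset), len(gset), N)
            mat.loc[g, s] = -np.log10(max(p, np.finfo(float).tiny))
    return mat
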