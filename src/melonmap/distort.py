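"""Segregation distortion: per-marker chi-square tests and SDR detection.

Each mapped marker is tested against the 1:1 segregation expected in a
RIL population with a one-degree-of-freedom chi-square on the counts of
the two homozygous classes (heterozygous and missing calls excluded).
A segregation distortion region (SDR) is a maximal run of at least
``min_run`` adjacent mapped loci all significantly skewed toward the
same parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from melonmap.genotypes import A, B
from melonmap.linkmap import SkeletonMap

__all__ = ["SkewCall", "SDR", "chisq_1to1", "find_sdrs", "skew_calls_for_map"]


@dataclass(frozen=True)
class SkewCall:
    marker: str
    a: int
    b: int
    x2: float
    p: float
    skewed: bool
    direction: str  # 'A', 'B' or ''


@dataclass(frozen=True)
class SDR:
    lg: str
    start_index: int  # inclusive, on the ordered marker list of the LG
    end_index: int  # inclusive
    n_markers: int
    direction: str
    markers: tuple[str, ...]


def chisq_1to1(
    a: int, b: int, marker: str = "", alpha: float = 0.05, yates: bool = False
) -> SkewCall:
    """Test counts of the two homozygote classes against 1:1.

    ``X^2 = (a-b)^2/(a+b)`` (optionally with Yates' continuity
    correction), one degree of freedom; flagged skewed iff p < alpha.
    """
    if a < 0 or b < 0 or a + b == 0:
        raise ValueError("need non-negative counts with a + b > 0")
    diff = abs(a - b)
    if yates:
        diff = max(diff - 1.0, 0.0)
    x2 = diff**2 / (a + b)
    p = float(chi2.sf(x2, df=1))
    skewed = p < alpha
    direction = ("A" if a > b else "B") if skewed else ""
    return SkewCall(marker=marker, a=int(a), b=int(b), x2=float(x2), p=p, skewed=skewed, direction=direction)


def skew_calls_from_matrix(
    calls: np.ndarray, marker_ids: list[str], alpha: float = 0.05, yates: bool = False
) -> list[SkewCall]:
    """Chi-square calls for every row of a genotype matrix (A/B counts)."""
    out = []
    for row, mid in zip(calls, marker_ids):
        a = int((row == A).sum())
        b = int((row == B).sum())
        if a + b == 0:
            out.append(SkewCall(marker=mid, a=0, b=0, x2=float("nan"), p=float("nan"), skewed=False, direction=""))
        else:
            out.append(chisq_1to1(a, b, marker=mid, alpha=alpha, yates=yates))
    return out


def find_sdrs(
    ordered_calls: list[SkewCall], lg: str = "", min_run: int = 10, max_gap: int = 0
) -> list[SDR]:
    """Maximal runs of adjacent same-direction skewed markers.

    A run is broken by any non-skewed or opposite-direction marker
    (strict adjacency); ``max_gap`` > 0 tolerates that many intervening
    non-skewed markers within a run (off by default).
    """
    sdrs: list[SDR] = []
    i = 0
    n = len(ordered_calls)
    while i < n:
        if not ordered_calls[i].skewed:
            i += 1
            continue
        direction = ordered_calls[i].direction
        j = i
        last_skewed = i
        gap = 0
        while j + 1 < n:
            nxt = ordered_calls[j + 1]
            if nxt.skewed and nxt.direction == direction:
                j += 1
                last_skewed = j
                gap = 0
            elif not nxt.skewed and gap < max_gap:
                j += 1
                gap += 1
            else:
                break
        members = [c for c in ordered_calls[i : last_skewed + 1] if c.skewed]
        if len(members) >= min_run:
            sdrs.append(
                SDR(
                    lg=lg,
                    start_index=i,
                    end_index=last_skewed,
                    n_markers=len(members),
                    direction=direction,
                    markers=tuple(c.marker for c in members),
                )
            )
        i = last_skewed + 1
    return sdrs


def skew_calls_for_map(
    skeleton: SkeletonMap,
    calls_by_marker: dict[str, np.ndarray],
    alpha: float = 0.05,
    min_run: int = 10,
) -> tuple[pd.DataFrame, list[SDR]]:
    """Test every mapped marker along its LG order and detect SDRs."""
    rows = []
    sdrs: list[SDR] = []
    for g in skeleton.groups:
        ordered = [m for b in g.bins for m in b.members]
        lg_calls = skew_calls_from_matrix(
            np.stack([calls_by_marker[m] for m in ordered]), ordered, alpha=alpha
        )
        sdrs.extend(find_sdrs(lg_calls, lg=g.id, min_run=min_run))
        for c in lg_calls:
            rows.append((g.id, c.marker, c.a, c.b, c.x2, c.p, c.skewed, c.direction))
    table = pd.DataFrame(
        rows, columns=["lg", "marker", "a", "b", "x2", "p", "skewed", "direction"]
    )
    return table, sdrs
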