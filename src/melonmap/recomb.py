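"""Recombination-rate landscape on pseudochromosomes.

Mapped markers give anchor points (physical bp, genetic cM) per
pseudochromosome.  Genetic positions between anchors are linearly
interpolated and clamped to the terminal cM beyond the outermost
markers.  Each pseudochromosome is tiled with non-overlapping windows
(1 Mb by default; the last one may be short and is normalised by its
actual length); the window rate is its genetic span divided by its
physical span in Mb.  Windows below 1.0 cM/Mb are classified as
recombination-suppressed, all others as recombination-hot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneticPositionTrack",
    "WindowRate",
    "interpolate_cm",
    "window_rates",
    "genome_average",
    "plot_tracks",
]


@dataclass(frozen=True)
class GeneticPositionTrack:
    """Monotone (bp, cM) anchor points for one pseudochromosome."""

    chrom: str
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.bp, dtype=float)
        cm = np.asarray(self.cm, dtype=float)
        if bp.size < 2:
            raise ValueError("a track needs at least two anchor points")
        if bp.size != cm.size:
            raise ValueError("bp and cM arrays differ in length")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("bp anchors must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("cM anchors must be non-decreasing")
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)

    @classmethod
    def from_anchors(cls, chrom: str, bp, cm) -> "GeneticPositionTrack":
        """Build from unsorted, possibly conflicting marker anchors.

        Anchors are sorted by bp; exact bp duplicates are averaged and
        small cM inversions (marker noise) are resolved with a running
        maximum so the track is monotone.
        """
        df = pd.DataFrame({"bp": np.asarray(bp, float), "cm": np.asarray(cm, float)})
        df = df.groupby("bp", as_index=False)["cm"].mean().sort_values("bp")
        cmv = np.maximum.accumulate(df["cm"].to_numpy())
        return cls(chrom=chrom, bp=df["bp"].to_numpy(), cm=cmv)


@dataclass(frozen=True)
class WindowRate:
    chrom: str
    start: int
    end: int
    cm_start: float
    cm_end: float
    rate: float  # cM/Mb
    suppressed: bool  # rate < 1.0; otherwise "hot"


def interpolate_cm(track: GeneticPositionTrack, bp) -> np.ndarray | float:
    """Genetic position(s) at bp: linear between anchors, clamped outside."""
    out = np.interp(np.asarray(bp, dtype=float), track.bp, track.cm)
    return out.item() if out.ndim == 0 else out


def window_rates(
    track: GeneticPositionTrack, chrom_length: int, window_bp: int = 1_000_000
) -> list[WindowRate]:
    """Per-window cM/Mb over [0, chrom_length), tiled from 0."""
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    out = []
    for start in range(0, chrom_length, window_bp):
        end = min(start + window_bp, chrom_length)
        c0 = float(interpolate_cm(track, start))
        c1 = float(interpolate_cm(track, end))
        rate = (c1 - c0) / ((end - start) / 1e6)
        out.append(
            WindowRate(
                chrom=track.chrom,
                start=start,
                end=end,
                cm_start=c0,
                cm_end=c1,
                rate=rate,
                suppressed=rate < 1.0,
            )
        )
    return out


def windows_to_bed(windows: list[WindowRate], path) -> None:
    """Write windows as BED with rate and class columns."""
    with open(path, "w") as fh:
        for w in windows:
            cls = "suppressed" if w.suppressed else "hot"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{cls}\t{w.rate:.4f}\n")


def genome_average(tracks: list[GeneticPositionTrack], assembly_mb: float) -> float:
    """Genome-wide genetic-to-physical ratio, cM/Mb, to one decimal."""
    if assembly_mb <= 0:
        raise ValueError("assembly size must be positive")
    total_cm = sum(float(t.cm[-1] - t.cm[0]) for t in tracks)
    return round(total_cm / assembly_mb, 1)


def plot_tracks(tracks: list[GeneticPositionTrack], path) -> None:
    """Per-chromosome genetic vs physical distance panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(tracks)
    ncol = min(4, n)
    nrow = -(-n // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    for ax in axes.flat[n:]:
        ax.axis("off")
    for ax, t in zip(axes.flat, tracks):
        ax.plot(t.bp / 1e6, t.cm, lw=1)
        ax.set_title(t.chrom, fontsize=9)
        ax.set_xlabel("Mb", fontsize=8)
        ax.set_ylabel("cM", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
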