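"""Scaffold anchoring, orientation and pseudochromosome assembly.

Scaffolds are assigned to the linkage group holding the majority of
their mapped markers (ties are conflicts, left unanchored), ordered
along the chromosome by the median cM of their markers, and oriented by
the concordance of within-scaffold bp order with map cM order.  Ordered
placements are assembled into pseudochromosomes emitted as AGP 2.1,
with a fixed N-gap between adjacent scaffolds.  BAC end pairs are
placed on scaffolds with the usual forward/reverse + insert-size
criteria.  Map summary rows mirror the standard per-LG summary table
(loci, scaffolds, Mb, cM, recombination events, filled bins) with the
derived ratios recomputed from the totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from melonmap.linkmap import SkeletonMap

__all__ = [
    "ScaffoldPlacement",
    "AnchorResult",
    "PseudochromosomeBuild",
    "BACPlacement",
    "assign_and_order_scaffolds",
    "orient_scaffolds",
    "build_pseudochromosomes",
    "write_agp",
    "read_agp",
    "place_bac_ends",
    "marker_pseudo_positions",
    "per_lg_rows",
    "summarize_rows",
    "summarize_map",
]


@dataclass
class ScaffoldPlacement:
    scaffold: str
    lg: str
    order_index: int
    orientation: str = "?"  # '+', '-' or '?' (unoriented)
    n_markers: int = 0
    cm_min: float = float("nan")
    cm_max: float = float("nan")
    size_bp: int = 0
    chimeric: bool = False


@dataclass
class AnchorResult:
    placements: list[ScaffoldPlacement]
    unanchored: list[str]
    conflicts: list[str]

    def by_lg(self) -> dict[str, list[ScaffoldPlacement]]:
        out: dict[str, list[ScaffoldPlacement]] = {}
        for p in self.placements:
            out.setdefault(p.lg, []).append(p)
        for lst in out.values():
            lst.sort(key=lambda p: p.order_index)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.scaffold, p.lg, p.order_index, p.orientation, p.n_markers, p.cm_min, p.cm_max, p.size_bp, p.chimeric)
                for p in self.placements
            ],
            columns=["scaffold", "lg", "order_index", "orientation", "n_markers", "cm_min", "cm_max", "size_bp", "chimeric"],
        )


def assign_and_order_scaffolds(
    map_table: pd.DataFrame, scaffold_lengths: dict[str, int]
) -> AnchorResult:
    """Majority-rule LG assignment and median-cM ordering of scaffolds.

    ``map_table`` is the skeleton map's marker table (index marker;
    columns lg, cm, scaffold, bp).  Scaffolds with no mapped marker are
    listed unanchored; an exact LG tie is a conflict (also unanchored).
    A scaffold with at least two markers on each of two or more LGs is
    flagged chimeric but still assigned by majority when one exists.
    """
    placements: list[ScaffoldPlacement] = []
    conflicts: list[str] = []
    seen = set()
    for scaffold, grp in map_table.groupby("scaffold", sort=True):
        seen.add(scaffold)
        counts = grp["lg"].value_counts()
        top = counts.max()
        leaders = sorted(counts[counts == top].index)
        if len(leaders) > 1:
            conflicts.append(scaffold)
            continue
        lg = leaders[0]
        sub = grp[grp["lg"] == lg]
        placements.append(
            ScaffoldPlacement(
                scaffold=scaffold,
                lg=lg,
                order_index=-1,
                n_markers=len(sub),
                cm_min=float(sub["cm"].min()),
                cm_max=float(sub["cm"].max()),
                size_bp=int(scaffold_lengths.get(scaffold, 0)),
                chimeric=int((counts >= 2).sum()) >= 2,
            )
        )
    unanchored = sorted(set(scaffold_lengths) - seen) + conflicts
    # order within each LG by median cM of the scaffold's markers
    med = {
        p.scaffold: float(map_table.loc[(map_table["scaffold"] == p.scaffold) & (map_table["lg"] == p.lg), "cm"].median())
        for p in placements
    }
    for lg in sorted({p.lg for p in placements}):
        group = sorted((p for p in placements if p.lg == lg), key=lambda p: (med[p.scaffold], p.scaffold))
        for i, p in enumerate(group):
            p.order_index = i
    return AnchorResult(placements=placements, unanchored=unanchored, conflicts=conflicts)


def orient_scaffolds(result: AnchorResult, map_table: pd.DataFrame) -> AnchorResult:
    """Set orientation from bp-vs-cM concordance over each scaffold's markers.

    The sign of the Kendall concordance (number of concordant minus
    discordant marker pairs) gives '+' or '-'; a single marker, markers
    at a single cM, or an exact tie leave the scaffold unoriented.
    """
    for p in result.placements:
        sub = map_table[(map_table["scaffold"] == p.scaffold) & (map_table["lg"] == p.lg)]
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        if len(sub) < 2 or len(np.unique(cm)) < 2:
            p.orientation = "?"
            continue
        db = np.sign(bp[:, None] - bp[None, :])
        dc = np.sign(cm[:, None] - cm[None, :])
        score = float(np.sum(db * dc)) / 2.0
        p.orientation = "+" if score > 0 else "-" if score < 0 else "?"
    return result


@dataclass
class PseudochromosomeBuild:
    chrom: str
    #: AGP-style records: (object_beg, object_end, part, type, id/gap_len,
    #: comp_beg/gap_type, comp_end/linkage, orientation/evidence), 1-based inclusive
    records: list[tuple] = field(default_factory=list)
    length: int = 0


def build_pseudochromosomes(
    result: AnchorResult, scaffold_lengths: dict[str, int], gap_bp: int = 100
) -> dict[str, PseudochromosomeBuild]:
    """Concatenate ordered scaffolds with fixed N-gaps into AGP builds."""
    builds: dict[str, PseudochromosomeBuild] = {}
    for lg, group in result.by_lg().items():
        order = [p.order_index for p in group]
        if len(set(order)) != len(order):
            raise ValueError(f"duplicate order index on {lg}")
        b = PseudochromosomeBuild(chrom=lg)
        pos = 0
        part = 0
        for i, p in enumerate(group):
            if i > 0 and gap_bp > 0:
                part += 1
                b.records.append((pos + 1, pos + gap_bp, part, "N", gap_bp, "scaffold", "yes", "map"))
                pos += gap_bp
            ln = scaffold_lengths[p.scaffold]
            part += 1
            b.records.append((pos + 1, pos + ln, part, "W", p.scaffold, 1, ln, p.orientation))
            pos += ln
        b.length = pos
        builds[lg] = b
    return builds


def write_agp(builds: dict[str, PseudochromosomeBuild], path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for chrom in sorted(builds):
            for rec in builds[chrom].records:
                fh.write("\t".join(str(x) for x in (chrom, *rec)) + "\n")


def read_agp(path) -> dict[str, PseudochromosomeBuild]:
    builds: dict[str, PseudochromosomeBuild] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom = f[0]
            b = builds.setdefault(chrom, PseudochromosomeBuild(chrom=chrom))
            if f[4] in ("N", "U"):
                rec = (int(f[1]), int(f[2]), int(f[3]), f[4], int(f[5]), f[6], f[7], f[8])
            else:
                rec = (int(f[1]), int(f[2]), int(f[3]), f[4], f[5], int(f[6]), int(f[7]), f[8])
            b.records.append(rec)
            b.length = max(b.length, int(f[2]))
    return builds


def scaffold_offsets(build: PseudochromosomeBuild) -> dict[str, tuple[int, int, str]]:
    """scaffold -> (0-based start on the pseudochromosome, length, orientation)."""
    out = {}
    for beg, end, _part, typ, comp, *rest in build.records:
        if typ == "W":
            out[comp] = (beg - 1, end - beg + 1, rest[-1])
    return out


def marker_pseudo_positions(
    builds: dict[str, PseudochromosomeBuild], map_table: pd.DataFrame
) -> pd.DataFrame:
    """Add a pseudochromosome coordinate column to the marker table.

    Scaffold-local bp is lifted through each placement; '-' components
    are mirrored, unoriented ('?') components are treated as '+'.
    """
    offsets = {chrom: scaffold_offsets(b) for chrom, b in builds.items()}
    rows = []
    for marker, row in map_table.iterrows():
        off = offsets.get(row["lg"], {}).get(row["scaffold"])
        if off is None:
            continue
        start, ln, orient = off
        local = int(row["bp"])
        pseudo = start + (ln - 1 - local) if orient == "-" else start + local
        rows.append((marker, row["lg"], float(row["cm"]), int(pseudo)))
    return pd.DataFrame(rows, columns=["marker", "chrom", "cm", "pseudo_bp"]).set_index("marker")


# ---------------------------------------------------------------------------
# BAC end placement


@dataclass(frozen=True)
class BACPlacement:
    bac: str
    scaffold: str | None
    span: int | None
    estimate: int
    accepted: bool
    reason: str
    interval: tuple[int, int] | None = None


def place_bac_ends(
    alignments: pd.DataFrame,
    insert_estimates: dict[str, int],
    size_tolerance: float = 0.5,
) -> list[BACPlacement]:
    """Accept BACs whose two end reads bracket a plausible insert.

    ``alignments`` has one row per end: columns bac, scaffold, pos
    (0-based leftmost), strand ('+'/'-').  A BAC is accepted iff it has
    exactly two aligned ends, both on one scaffold, on opposite strands,
    and the spanned distance is within ``size_tolerance`` of the
    estimated insert size.  The predicted BAC interval is returned for
    accepted pairs.
    """
    out = []
    for bac, grp in alignments.groupby("bac", sort=True):
        est = int(insert_estimates.get(bac, 0))
        if len(grp) != 2:
            out.append(BACPlacement(bac, None, None, est, False, f"{len(grp)} end alignments"))
            continue
        (s1, p1, st1), (s2, p2, st2) = grp[["scaffold", "pos", "strand"]].itertuples(index=False)
        if s1 != s2:
            out.append(BACPlacement(bac, None, None, est, False, "ends on different scaffolds"))
            continue
        if st1 == st2:
            out.append(BACPlacement(bac, s1, None, est, False, "ends on the same strand"))
            continue
        lo, hi = int(min(p1, p2)), int(max(p1, p2))
        span = hi - lo
        if not (1 - size_tolerance) * est <= span <= (1 + size_tolerance) * est:
            out.append(BACPlacement(bac, s1, span, est, False, "span outside insert-size tolerance"))
            continue
        out.append(BACPlacement(bac, s1, span, est, True, "", interval=(lo, hi)))
    return out


# ---------------------------------------------------------------------------
# map summary


def per_lg_rows(skeleton: SkeletonMap, result: AnchorResult) -> pd.DataFrame:
    """Per-LG summary rows: loci, scaffolds, Mb, cM, events, filled bins.

    Every observed bin carries at least one marker, so recombination
    events are bin count - 1 and filled bins equal the bin count.
    """
    by_lg = result.by_lg()
    rows = []
    for g in skeleton.groups:
        scs = by_lg.get(g.id, [])
        rows.append(
            (
                g.id,
                g.n_markers,
                len(scs),
                sum(p.size_bp for p in scs) / 1e6,
                g.length_cm,
                max(len(g.bins) - 1, 0),
                len(g.bins),
            )
        )
    return pd.DataFrame(rows, columns=["lg", "loci", "scaffolds", "mb", "cm", "events", "filled_bins"])


def summarize_rows(rows: pd.DataFrame, assembly_mb: float) -> dict:
    """Totals and derived ratios from per-LG rows.

    Ratios are recomputed from the totals, never stored: mean marker
    interval (cM, 1 decimal), mean scaffold size (Mb, 2 decimals),
    markers per scaffold (nearest integer), genome-wide cM/Mb against
    the full assembly size (1 decimal).
    """
    total = {
        "loci": int(rows["loci"].sum()),
        "scaffolds": int(rows["scaffolds"].sum()),
        "mb": float(rows["mb"].sum()),
        "cm": float(rows["cm"].sum()),
        "events": int(rows["events"].sum()),
        "filled_bins": int(rows["filled_bins"].sum()),
    }
    total["mean_marker_interval_cm"] = round(total["cm"] / total["loci"], 1)
    total["mean_scaffold_mb"] = round(total["mb"] / total["scaffolds"], 2)
    total["markers_per_scaffold"] = round(total["loci"] / total["scaffolds"])
    total["cm_per_mb"] = round(total["cm"] / assembly_mb, 1)
    total["anchored_pct"] = round(100.0 * total["mb"] / assembly_mb, 1)
    return total


def summarize_map(skeleton: SkeletonMap, result: AnchorResult, assembly_mb: float) -> dict:
    """Per-LG rows plus totals/ratios for a built map and its placements."""
    rows = per_lg_rows(skeleton, result)
    summary = summarize_rows(rows, assembly_mb)
    summary["rows"] = rows
    return summary
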