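"""Bin-based genetic map construction for selfed RIL populations.

Pipeline: pairwise two-point statistics -> linkage grouping at a LOD
threshold -> singleton (isolated double-crossover) cleaning -> merging
of co-segregating markers into bin signatures -> bin ordering -> Haldane
map distances -> placement of residual markers at a relaxed LOD.

Two-point statistics for fully inbred lines: with ``n`` individuals
scored as opposite homozygotes at both markers and ``k`` of them
discordant, the observed discordance is ``R = k/n``, the meiotic
recombination fraction is recovered through the Haldane–Waddington
relation ``r = R/(2 - 2R)``, and the LOD score is the base-10 binomial
likelihood ratio against independence,
``LOD = k log10(2R) + (n-k) log10(2(1-R))``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from melonmap.genotypes import A, B, HET, MISSING, GenotypeMatrix
from melonmap.theory import haldane_cm, ril_r_from_discordance

__all__ = [
    "TwoPointEstimate",
    "Bin",
    "LinkageGroup",
    "SkeletonMap",
    "estimate_two_point",
    "two_point_tables",
    "group_markers",
    "clean_singletons",
    "build_bins",
    "order_bins",
    "compute_distances",
    "place_residual_markers",
    "build_map",
]


@dataclass(frozen=True)
class TwoPointEstimate:
    n: int
    k: int
    R_hat: float
    r_hat: float
    lod: float


def _lod(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binomial LOD against r=0.5, with 0*log10(0) := 0."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n > 0, k / np.maximum(n, 1), np.nan)
        t1 = np.where(k > 0, k * np.log10(2.0 * R), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log10(2.0 * (1.0 - R)), 0.0)
    return t1 + t2


def estimate_two_point(calls_i: np.ndarray, calls_j: np.ndarray) -> TwoPointEstimate | None:
    """Two-point estimate for one marker pair; None if no informative pair."""
    ci = np.asarray(calls_i)
    cj = np.asarray(calls_j)
    ok = np.isin(ci, (A, B)) & np.isin(cj, (A, B))
    n = int(ok.sum())
    if n == 0:
        return None
    k = int((ci[ok] != cj[ok]).sum())
    R = k / n
    return TwoPointEstimate(n=n, k=k, R_hat=R, r_hat=float(ril_r_from_discordance(R)), lod=float(_lod(k, n)))


def two_point_tables(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (n, R_hat, r_hat, LOD) matrices for a call matrix.

    Entries with no informative individuals have ``n = 0`` and NaN
    statistics.  Vectorised: with markers scored +1 (A) / -1 (B) / 0
    (other), the Gram matrix of the sign coding gives agreements minus
    disagreements, and the Gram matrix of its absolute value gives the
    informative count.
    """
    x = np.zeros(calls.shape, dtype=np.float64)
    x[calls == A] = 1.0
    x[calls == B] = -1.0
    v = np.abs(x)
    n = v @ v.T
    s = x @ x.T
    k = (n - s) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    r = ril_r_from_discordance(np.where(np.isnan(R), 0.5, R))
    r = np.where(np.isnan(R), np.nan, r)
    lod = np.where(n > 0, _lod(k, n), np.nan)
    return n.astype(np.int64), R, r, lod


def group_markers(
    lod: np.ndarray,
    r_hat: np.ndarray,
    lod_threshold: float = 10.0,
    r_max: float = 0.45,
) -> list[np.ndarray]:
    """Single-linkage partition: join markers with LOD >= threshold and r <= r_max.

    Returns marker-index arrays sorted by decreasing group size (ties by
    smallest member index).
    """
    with np.errstate(invalid="ignore"):
        adj = (lod >= lod_threshold) & (r_hat <= r_max)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == c) for c in range(n_comp)]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def clean_singletons(ordered_calls: np.ndarray) -> tuple[np.ndarray, int]:
    """Mask isolated double-crossover calls along an ordered marker set.

    For each individual, an interior non-missing homozygous call whose
    two immediate neighbours are homozygous, agree with each other and
    differ from it is set to missing.  Terminal markers are never
    flagged and the pass runs once (flags are computed on the input,
    then applied), so true crossovers are not eroded in cascade.
    """
    calls = np.asarray(ordered_calls)
    out = calls.copy()
    if calls.shape[0] < 3:
        return out, 0
    mid, prv, nxt = calls[1:-1], calls[:-2], calls[2:]
    hom = np.isin(calls, (A, B))
    flag = hom[1:-1] & hom[:-2] & hom[2:] & (prv == nxt) & (mid != prv)
    out[1:-1][flag] = MISSING
    return out, int(flag.sum())


@dataclass
class Bin:
    """A set of markers with zero observed recombination, plus consensus."""

    members: list[str]
    consensus: np.ndarray = field(repr=False)
    id: str = ""
    cm: float = float("nan")


def build_bins(calls: np.ndarray, marker_ids: list[str]) -> list[Bin]:
    """Merge markers with no pairwise discordant non-missing calls.

    Markers are processed in the given order; each joins the first
    existing bin whose consensus it does not conflict with (a conflict
    is a position where both are opposite homozygotes), otherwise it
    founds a new bin.  The consensus takes the non-missing value
    wherever any member has one.
    """
    bins: list[Bin] = []
    for row, mid in zip(calls, marker_ids):
        hom = np.isin(row, (A, B))
        placed = False
        for b in bins:
            c = b.consensus
            both = hom & np.isin(c, (A, B))
            if not np.any(row[both] != c[both]):
                b.members.append(mid)
                b.consensus = np.where((c == MISSING) & (row != MISSING), row, c).astype(np.int8)
                placed = True
                break
        if not placed:
            bins.append(Bin(members=[mid], consensus=row.astype(np.int8).copy()))
    return bins


def _path_cost(order: tuple[int, ...] | list[int], d: np.ndarray) -> float:
    return float(sum(d[a, b] for a, b in zip(order[:-1], order[1:])))


def _two_opt(order: list[int], d: np.ndarray) -> list[int]:
    improved = True
    best = _path_cost(order, d)
    n = len(order)
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                c = _path_cost(cand, d)
                if c < best - 1e-12:
                    order, best = cand, c
                    improved = True
    return order


def order_bins(distance: np.ndarray, exhaustive_max: int = 9) -> list[int]:
    """Order bins to minimise the sum of adjacent distances (open path).

    Exhaustive search for small instances (guaranteed optimal), greedy
    nearest-neighbour seeding from every start plus 2-opt otherwise.
    The returned path is canonicalised with the lower index endpoint
    first.  NaN distances (no informative individuals) are treated as
    the maximum penalty.
    """
    n = distance.shape[0]
    if n == 0:
        return []
    if n == 1:
        return [0]
    d = np.where(np.isnan(distance), 0.5, distance)
    if n <= exhaustive_max:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(n)):
            if perm[0] > perm[-1]:  # each open path has a mirror; scan one
                continue
            c = _path_cost(perm, d)
            if c < best_cost - 1e-12:
                best, best_cost = list(perm), c
        order = best
    else:
        best, best_cost = None, np.inf
        for start in range(n):
            left = set(range(n)) - {start}
            path = [start]
            while left:
                cur = path[-1]
                nxt = min(left, key=lambda j: (d[cur, j], j))
                path.append(nxt)
                left.remove(nxt)
            c = _path_cost(path, d)
            if c < best_cost - 1e-12:
                best, best_cost = path, c
        order = _two_opt(best, d)
    if order[0] > order[-1]:
        order = order[::-1]
    return order


def compute_distances(adjacent_r: np.ndarray) -> np.ndarray:
    """Cumulative cM positions from adjacent recombination fractions."""
    r = np.asarray(adjacent_r, dtype=float)
    if np.any(r >= 0.5):
        raise ValueError("adjacent r_hat of 0.5: bins are unlinked, ordering failed")
    d = haldane_cm(r)
    return np.concatenate([[0.0], np.cumsum(d)])


@dataclass
class LinkageGroup:
    id: str
    bins: list[Bin]

    @property
    def length_cm(self) -> float:
        return self.bins[-1].cm if self.bins else 0.0

    @property
    def n_markers(self) -> int:
        return sum(len(b.members) for b in self.bins)


@dataclass
class SkeletonMap:
    groups: list[LinkageGroup]
    unplaced: list[str]
    individuals: list[str] = field(default_factory=list)

    @property
    def total_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    def marker_table(self, marker_coords: pd.DataFrame | None = None) -> pd.DataFrame:
        """Long-format table: LG, bin, cM, marker (plus coordinates if given)."""
        rows = []
        for g in self.groups:
            for b in g.bins:
                for m in b.members:
                    rows.append((g.id, b.id, b.cm, m))
        df = pd.DataFrame(rows, columns=["lg", "bin", "cm", "marker"]).set_index("marker")
        if marker_coords is not None:
            df = df.join(marker_coords)
        return df

    def to_tsv(self, path, marker_coords: pd.DataFrame | None = None) -> None:
        self.marker_table(marker_coords).to_csv(path, sep="\t")


def place_residual_markers(
    skeleton: SkeletonMap,
    gm: GenotypeMatrix,
    residual_ids: list[str],
    min_lod: float = 4.0,
) -> SkeletonMap:
    """Attach leftover markers to the best-matching bin at a relaxed LOD.

    Each residual marker joins the bin with the highest LOD when that is
    at least ``min_lod`` (ties broken toward smaller r_hat, remaining
    ties leave the marker unplaced); others stay on the unplaced list.
    """
    all_bins = [b for g in skeleton.groups for b in g.bins]
    still_unplaced = []
    idx = {m: i for i, m in enumerate(gm.markers.index)}
    for mid in residual_ids:
        row = gm.calls[idx[mid]]
        best = None  # (lod, -r, bin)
        tied = False
        for b in all_bins:
            est = estimate_two_point(row, b.consensus)
            if est is None or est.lod < min_lod:
                continue
            key = (est.lod, -est.r_hat)
            if best is None or key > best[0]:
                best, tied = (key, b), False
            elif key == best[0]:
                tied = True
        if best is None or tied:
            still_unplaced.append(mid)
        else:
            best[1].members.append(mid)
    return SkeletonMap(groups=skeleton.groups, unplaced=still_unplaced, individuals=skeleton.individuals)


# ---------------------------------------------------------------------------
# full pipeline


def _adjacent_r(consensus: np.ndarray) -> np.ndarray:
    r = np.empty(consensus.shape[0] - 1)
    for i in range(consensus.shape[0] - 1):
        est = estimate_two_point(consensus[i], consensus[i + 1])
        r[i] = est.r_hat if est is not None else np.nan
    if np.any(np.isnan(r)):
        raise ValueError("adjacent bins share no informative individuals")
    return r


def _order_key(markers: pd.DataFrame) -> list[str]:
    """Deterministic marker order: (scaffold, bp, id), whatever is present."""
    df = markers.reset_index()
    idx_col = df.columns[0]
    cols = [c for c in ("scaffold", "bp") if c in markers.columns]
    return list(df.sort_values(cols + [idx_col], kind="mergesort")[idx_col])


def build_map(
    gm: GenotypeMatrix,
    lod_threshold: float = 10.0,
    min_lod: float = 4.0,
    r_max: float = 0.45,
    min_group_size: int = 2,
    het_policy: str = "set_missing",
) -> SkeletonMap:
    """Construct the skeleton bin map from a genotype matrix.

    Steps per linkage group: singleton cleaning on the within-scaffold
    bp order, provisional binning and ordering, a second singleton pass
    along the provisional map order, re-binning, final ordering, Haldane
    distances.  Groups smaller than ``min_group_size`` go to the
    residual pool, which is then re-attached bin-wise at ``min_lod``.
    Paths are canonicalised (end with the smallest member marker id
    first) so the result does not depend on input row order.
    """
    calls = gm.calls.copy()
    if het_policy == "set_missing":
        calls[calls == HET] = MISSING
    markers = gm.markers
    order_all = _order_key(markers)
    pos = {m: i for i, m in enumerate(markers.index)}
    calls = calls[[pos[m] for m in order_all]]
    marker_ids = order_all
    scaffold = markers.loc[marker_ids, "scaffold"].to_numpy() if "scaffold" in markers.columns else np.array(marker_ids)

    n_mat, R, r_mat, lod_mat = two_point_tables(calls)
    groups = group_markers(lod_mat, r_mat, lod_threshold, r_max)

    lgs: list[LinkageGroup] = []
    residual: list[str] = []
    for g in groups:
        if len(g) < min_group_size:
            residual.extend(marker_ids[i] for i in g)
            continue
        sub = calls[g].copy()
        ids = [marker_ids[i] for i in g]
        scafs = scaffold[g]

        # pass 1: clean along bp order within each scaffold
        for sc in pd.unique(scafs):
            rows = np.flatnonzero(scafs == sc)
            if len(rows) >= 3:
                cleaned, _ = clean_singletons(sub[rows])
                sub[rows] = cleaned

        # provisional bins and order
        bins = build_bins(sub, ids)
        cons = np.stack([b.consensus for b in bins])
        _, _, r_bins, _ = two_point_tables(cons)
        order = order_bins(r_bins)

        # pass 2: clean along the provisional map order, marker level
        marker_order = [m for bi in order for m in bins[bi].members]
        row_of = {m: i for i, m in enumerate(ids)}
        ordered_rows = [row_of[m] for m in marker_order]
        cleaned, _ = clean_singletons(sub[ordered_rows])

        # final bins, order, distances
        bins = build_bins(cleaned, marker_order)
        cons = np.stack([b.consensus for b in bins])
        _, _, r_bins, _ = two_point_tables(cons)
        order = order_bins(r_bins)
        bins = [bins[i] for i in order]
        if len(bins) > 1 and min(bins[-1].members) < min(bins[0].members):
            bins = bins[::-1]
        cons = np.stack([b.consensus for b in bins])
        cm = compute_distances(_adjacent_r(cons)) if len(bins) > 1 else np.array([0.0])
        for b, c in zip(bins, cm):
            b.cm = float(c)
        lgs.append(LinkageGroup(id="", bins=bins))

    lgs.sort(key=lambda lg: (-lg.n_markers, min(min(b.members) for b in lg.bins)))
    for i, lg in enumerate(lgs, start=1):
        lg.id = f"LG{i}"
        for j, b in enumerate(lg.bins, start=1):
            b.id = f"{i}bin{j}"

    skeleton = SkeletonMap(groups=lgs, unplaced=[], individuals=list(gm.individuals))
    return place_residual_markers(skeleton, gm, residual, min_lod=min_lod)
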