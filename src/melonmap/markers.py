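"""PCR marker discovery: SSR detection, InDel/SV filters, primer screens.

Marker classes follow the usual gel-scored length-polymorphism design:

* SSRs: maximal perfect tandem repeats with a primitive 2-6 bp unit,
  at least three repeats and a tract of at least 20 bp; the marker locus
  is the tract plus 200 bp of flank on each side.
* InDels: parental allele-length differences of 5-10 bp (inclusive),
  resolvable on polyacrylamide gels.
* SVs: structural variants of 120-1400 bp, resolvable on agarose gels.

Loci must be unique in the assembly (exact-occurrence count over both
strands), and primers must pass a false-priming screen: every 13-15 bp
substring of a primer has to be genome-unique.  Within a scaffold,
polymorphic SSRs are preferred over InDels over SVs, and when several
markers of the chosen class are available the subset minimising the
largest inter-marker gap (including the scaffold ends) is selected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SSRLocus",
    "InDelLocus",
    "SVLocus",
    "PrimerPair",
    "CandidateMarker",
    "GenomeIndex",
    "find_ssrs",
    "check_uniqueness",
    "filter_variants",
    "design_primers",
    "check_false_priming",
    "select_markers",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# loci


@dataclass(frozen=True)
class SSRLocus:
    scaffold: str
    motif: str
    n_repeats: int
    tract_start: int  # 0-based half-open on the scaffold
    tract_end: int
    locus_start: int  # tract +/- flank, clipped to the scaffold
    locus_end: int
    unique: bool | None = None

    @property
    def tract_length(self) -> int:
        return self.tract_end - self.tract_start


@dataclass(frozen=True)
class InDelLocus:
    scaffold: str
    bp: int
    length: int  # signed allele length difference
    unique: bool | None = None


@dataclass(frozen=True)
class SVLocus:
    scaffold: str
    bp: int
    size: int  # absolute size
    unique: bool | None = None


@dataclass(frozen=True)
class PrimerPair:
    left: str
    right: str
    product_size_a: int
    product_size_b: int
    false_priming_clean: bool | None = None


@dataclass(frozen=True)
class CandidateMarker:
    id: str
    type: str  # 'SSR', 'InDel' or 'SV'
    scaffold: str
    bp: int
    polymorphic: bool
    unique: bool = True
    primers: PrimerPair | None = None

    @property
    def clean(self) -> bool:
        return self.primers is None or bool(self.primers.false_priming_clean)


# ---------------------------------------------------------------------------
# SSR detection


def _is_primitive(motif: str) -> bool:
    """True if the motif is not a repetition of a shorter unit."""
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return False
    return True


def find_ssrs(
    sequence: str,
    scaffold: str = "",
    unit_range: tuple[int, int] = (2, 6),
    min_tract_bp: int = 20,
    min_repeats: int = 3,
    flank_bp: int = 200,
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats passing both thresholds.

    A tract at unit length k is a maximal run where ``s[i] == s[i+k]``
    (Ns never match, so an N terminates a tract); its length may include
    a partial final unit.  The reported motif is the first unit of the
    tract and must be primitive, which removes duplicate reports of the
    same tract at multiples of its true unit (and homopolymers).  When
    two reported tracts overlap, the longer wins; at equal length the
    smaller unit wins.
    """
    s = sequence.upper()
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    found: list[SSRLocus] = []
    for k in range(unit_range[0], unit_range[1] + 1):
        i = 0
        while i + k < n:
            if s[i] != s[i + k] or s[i] not in "ACGT":
                i += 1
                continue
            j = i
            while j + k < n and s[j] == s[j + k] and s[j + k] in "ACGT":
                j += 1
            tract_start, tract_end = i, j + k  # maximal periodic stretch
            tract_len = tract_end - tract_start
            reps = tract_len // k
            motif = s[tract_start : tract_start + k]
            if reps >= min_repeats and tract_len >= min_tract_bp and _is_primitive(motif):
                found.append(
                    SSRLocus(
                        scaffold=scaffold,
                        motif=motif,
                        n_repeats=reps,
                        tract_start=tract_start,
                        tract_end=tract_end,
                        locus_start=max(0, tract_start - flank_bp),
                        locus_end=min(n, tract_end + flank_bp),
                    )
                )
            i = j + 1
    # overlap resolution: longer tract first, then smaller unit, then position
    found.sort(key=lambda t: (-t.tract_length, len(t.motif), t.tract_start))
    kept: list[SSRLocus] = []
    for t in found:
        if all(t.tract_end <= u.tract_start or t.tract_start >= u.tract_end for u in kept):
            kept.append(t)
    kept.sort(key=lambda t: t.tract_start)
    return kept


# ---------------------------------------------------------------------------
# genome index and uniqueness


class GenomeIndex:
    """Exact-occurrence counts over all scaffolds, both strands."""

    def __init__(self, scaffolds: dict[str, str]):
        self.scaffolds = {name: seq.upper() for name, seq in scaffolds.items()}
        self._kmer_counts: dict[int, Counter] = {}

    @classmethod
    def from_fasta(cls, path) -> "GenomeIndex":
        from pyfaidx import Fasta

        with Fasta(str(path)) as fa:
            return cls({rec.name: str(rec) for rec in fa})

    @staticmethod
    def _count_in(haystack: str, needle: str) -> int:
        count = start = 0
        while True:
            start = haystack.find(needle, start)
            if start == -1:
                return count
            count += 1
            start += 1  # overlapping occurrences count

    def count(self, seq: str) -> int:
        """Occurrences of ``seq`` on either strand of the genome."""
        if not seq:
            raise ValueError("empty query sequence")
        seq = seq.upper()
        rc = _revcomp(seq)
        if len(seq) in self._kmer_counts:
            c = self._kmer_counts[len(seq)]
            return c[seq] + (c[rc] if rc != seq else 0)
        total = 0
        for s in self.scaffolds.values():
            total += self._count_in(s, seq)
            if rc != seq:
                total += self._count_in(s, rc)
        return total

    def build_kmer_counts(self, k: int) -> None:
        """Precompute forward-strand k-mer counts for fast repeated queries."""
        c: Counter = Counter()
        for s in self.scaffolds.values():
            for i in range(len(s) - k + 1):
                c[s[i : i + k]] += 1
        self._kmer_counts[k] = c


def check_uniqueness(locus_sequence: str, index: GenomeIndex) -> bool:
    """True iff the locus sequence occurs exactly once genome-wide."""
    return index.count(locus_sequence) == 1


def check_false_priming(
    primer: str, index: GenomeIndex, k_range: tuple[int, int] = (13, 15)
) -> bool:
    """True iff every 13-15 bp substring of the primer is genome-unique.

    Exhaustive over all windows of each length (deterministic and
    strictly stronger than spot-checking random windows).
    """
    if len(primer) < k_range[1]:
        raise ValueError(f"primer shorter than {k_range[1]} bp")
    primer = primer.upper()
    for k in range(k_range[0], k_range[1] + 1):
        for i in range(len(primer) - k + 1):
            if index.count(primer[i : i + k]) > 1:
                return False
    return True


# ---------------------------------------------------------------------------
# variant filters


def filter_variants(
    variants: pd.DataFrame,
    indel_range: tuple[int, int] = (5, 10),
    sv_range: tuple[int, int] = (120, 1400),
) -> tuple[list[InDelLocus], list[SVLocus], int]:
    """Apply the marker size filters to a typed variant table.

    InDels kept iff the absolute allele-length difference lies in
    ``indel_range`` (inclusive); SVs kept iff their size lies in
    ``sv_range`` (inclusive).  Returns (indels, svs, n_skipped) where
    skipped counts records with an unrecognised type.
    """
    indels: list[InDelLocus] = []
    svs: list[SVLocus] = []
    skipped = 0
    pos_col = "scaffold_pos" if "scaffold_pos" in variants.columns else "bp"
    for _, row in variants.iterrows():
        vtype = str(row.get("type", "")).upper()
        if vtype == "INDEL":
            if indel_range[0] <= abs(int(row["length"])) <= indel_range[1]:
                indels.append(InDelLocus(scaffold=row["scaffold"], bp=int(row[pos_col]), length=int(row["length"])))
        elif vtype == "SV":
            if sv_range[0] <= abs(int(row["length"])) <= sv_range[1]:
                svs.append(SVLocus(scaffold=row["scaffold"], bp=int(row[pos_col]), size=abs(int(row["length"]))))
        elif vtype == "SNP":
            continue
        else:
            skipped += 1
    return indels, svs, skipped


# ---------------------------------------------------------------------------
# primer design


def _gc_fraction(seq: str) -> float:
    return sum(b in "GC" for b in seq) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _pick_primer(flank: str, length: int = 20) -> tuple[int, str] | None:
    """Leftmost qualifying k-mer: GC in [40%, 60%], no mononucleotide run >= 5."""
    for i in range(len(flank) - length + 1):
        cand = flank[i : i + length]
        if 0.4 <= _gc_fraction(cand) <= 0.6 and _max_run(cand) < 5 and "N" not in cand:
            return i, cand
    return None


def design_primers(
    left_flank: str,
    right_flank: str,
    inner_len: int,
    allele_diff: int = 0,
    primer_len: int = 20,
) -> PrimerPair | None:
    """Deterministic primer pick from the two locus flanks.

    The left primer is the leftmost qualifying 20-mer of the left flank;
    the right primer is the reverse complement of the rightmost
    qualifying window of the right flank (leftmost in reverse-complement
    scan).  Product sizes are reported per parent, differing by the
    allele length difference.  Returns None (marker discarded) if either
    flank has no qualifying window.
    """
    if len(left_flank) < primer_len or len(right_flank) < primer_len:
        return None
    left = _pick_primer(left_flank.upper(), primer_len)
    right = _pick_primer(_revcomp(right_flank.upper()), primer_len)
    if left is None or right is None:
        return None
    (i, lp), (j, rp) = left, right
    product_a = (len(left_flank) - i) + inner_len + (len(right_flank) - j)
    return PrimerPair(left=lp, right=rp, product_size_a=product_a, product_size_b=product_a + allele_diff)


# ---------------------------------------------------------------------------
# per-scaffold selection


def _min_max_gap_subset(positions: list[int], k: int, length: int) -> list[int]:
    """Indices of the k positions minimising the largest gap (incl. ends).

    Dynamic program over (last chosen, count); ties resolve to the
    lexicographically smallest index set for determinism.
    """
    n = len(positions)
    k = min(k, n)
    if k == n:
        return list(range(n))
    INF = float("inf")
    cost = [[INF] * (k + 1) for _ in range(n)]
    prev = [[-1] * (k + 1) for _ in range(n)]
    for i in range(n):
        cost[i][1] = positions[i] - 0
    for c in range(2, k + 1):
        for i in range(n):
            for j in range(i):
                val = max(cost[j][c - 1], positions[i] - positions[j])
                if val < cost[i][c]:
                    cost[i][c] = val
                    prev[i][c] = j
    best_i, best_val = -1, INF
    for i in range(n):
        val = max(cost[i][k], length - positions[i])
        if val < best_val:
            best_val, best_i = val, i
    chosen = []
    i, c = best_i, k
    while i >= 0:
        chosen.append(i)
        i, c = prev[i][c], c - 1
    return sorted(chosen)


_TYPE_PRIORITY = ("SSR", "InDel", "SV")


def select_markers(
    candidates_by_scaffold: dict[str, list[CandidateMarker]],
    scaffold_lengths: dict[str, int],
    target_count: int = 1,
) -> tuple[list[CandidateMarker], list[str]]:
    """Per-scaffold marker selection with class priority and even spacing.

    Only polymorphic, unique, false-priming-clean candidates are
    eligible.  The highest-priority class (SSR > InDel > SV) with any
    eligible candidate supplies up to ``target_count`` markers, chosen
    to minimise the largest gap between selected positions including
    the scaffold ends.  Scaffolds with no eligible candidate are
    reported as unanchorable.
    """
    selected: list[CandidateMarker] = []
    unanchorable: list[str] = []
    for scaffold in sorted(candidates_by_scaffold):
        cands = [c for c in candidates_by_scaffold[scaffold] if c.polymorphic and c.unique and c.clean]
        chosen_class = next((t for t in _TYPE_PRIORITY if any(c.type == t for c in cands)), None)
        if chosen_class is None:
            unanchorable.append(scaffold)
            continue
        pool = sorted((c for c in cands if c.type == chosen_class), key=lambda c: (c.bp, c.id))
        idx = _min_max_gap_subset([c.bp for c in pool], target_count, scaffold_lengths[scaffold])
        selected.extend(pool[i] for i in idx)
    return selected, unanchorable


def marker_table(selected: list[CandidateMarker]) -> pd.DataFrame:
    """Flat table of selected markers (one row per marker)."""
    rows = []
    for c in selected:
        p = c.primers
        rows.append(
            (
                c.id,
                c.type,
                c.scaffold,
                c.bp,
                p.left if p else "",
                p.right if p else "",
                p.product_size_a if p else np.nan,
                p.product_size_b if p else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["marker", "type", "scaffold", "bp", "primer_left", "primer_right", "product_a", "product_b"],
    ).set_index("marker")
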