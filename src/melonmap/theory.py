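"""Closed-form expectations for selfing pedigrees.

This module provides the quantitative backbone used to validate both the
stochastic simulator and the two-point estimator:

* the Haldane (no-interference) map function and its inverse,
* the Haldane–Waddington relation ``R = 2r/(1+2r)`` between the meiotic
  recombination fraction ``r`` and the discordance ``R`` observed among
  fully inbred lines, and
* an exact generation-by-generation Markov chain for one or two linked
  loci under repeated selfing, optionally with viability selection
  against a disfavoured homozygote.

The chain tracks the distribution over ordered pairs of two-locus
haplotypes (4 x 4 states).  Generation 1 is the F1 (fully heterozygous,
coupling phase); each subsequent generation is one round of selfing.
Viability selection is applied to the population each generation:
offspring genotype probabilities are multiplied by their viability
weights and renormalised, which models lost individuals being replaced
from the surviving population.
"""

from __future__ import annotations

import numpy as np

# haplotypes are 2-bit integers: bit 1 = allele at locus 1, bit 0 = allele
# at locus 2; allele 0 = parent A, allele 1 = parent B.
_HAPLOTYPES = (0b00, 0b01, 0b10, 0b11)


def haldane_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Map distance in cM for recombination fraction ``r`` (Haldane)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("r must lie in [0, 0.5) for a finite Haldane distance")
    out = -50.0 * np.log1p(-2.0 * r)
    return out.item() if out.ndim == 0 else out


def haldane_r(cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a map distance in cM (inverse Haldane)."""
    cm = np.asarray(cm, dtype=float)
    if np.any(cm < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * (1.0 - np.exp(-cm / 50.0))
    return out.item() if out.ndim == 0 else out


def ril_discordance(r: float | np.ndarray) -> float | np.ndarray:
    """Haldane–Waddington: expected discordance among fixed selfed lines."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + 2.0 * r)
    return out.item() if out.ndim == 0 else out


def ril_r_from_discordance(R: float | np.ndarray) -> float | np.ndarray:
    """Invert ``R = 2r/(1+2r)``; clamped to the admissible [0, 0.5]."""
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = R / (2.0 - 2.0 * R)
    out = np.clip(r, 0.0, 0.5)
    return out.item() if out.ndim == 0 else out


def _gamete_distribution(h1: int, h2: int, r: float) -> np.ndarray:
    """Gamete haplotype distribution from an ordered haplotype pair."""
    g = np.zeros(4)
    g[h1] += (1.0 - r) / 2.0
    g[h2] += (1.0 - r) / 2.0
    g[(h1 & 0b10) | (h2 & 0b01)] += r / 2.0
    g[(h2 & 0b10) | (h1 & 0b01)] += r / 2.0
    return g


def _viability_weights(selection: dict[int, tuple[float, int]]) -> np.ndarray:
    """4x4 matrix of viability weights for ordered haplotype pairs.

    ``selection`` maps locus index (0 = locus 1, 1 = locus 2) to a pair
    ``(s, favored_allele)``; the homozygote for the *other* allele gets
    weight ``1 - s``.
    """
    w = np.ones((4, 4))
    for locus, (s, favored) in selection.items():
        if not 0.0 <= s < 1.0:
            raise ValueError("selection coefficient must lie in [0, 1)")
        bit = 1 - locus
        disfavored = 1 - favored
        for i in _HAPLOTYPES:
            for j in _HAPLOTYPES:
                if ((i >> bit) & 1) == disfavored and ((j >> bit) & 1) == disfavored:
                    w[i, j] *= 1.0 - s
    return w


def selfing_chain(
    r: float,
    generations: int,
    selection: dict[int, tuple[float, int]] | None = None,
) -> np.ndarray:
    """Exact two-locus genotype distribution after repeated selfing.

    Returns the 4x4 distribution over ordered haplotype pairs at the
    requested generation (generation 1 = F1 in coupling phase).
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if not 0.0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    P = np.zeros((4, 4))
    P[0b00, 0b11] = 0.5
    P[0b11, 0b00] = 0.5
    w = _viability_weights(selection or {})
    for _ in range(generations - 1):
        nxt = np.zeros((4, 4))
        for i in _HAPLOTYPES:
            for j in _HAPLOTYPES:
                p = P[i, j]
                if p == 0.0:
                    continue
                g = _gamete_distribution(i, j, r)
                nxt += p * np.outer(g, g)
        nxt *= w
        P = nxt / nxt.sum()
    return P


def fixed_discordance(r: float, generations: int) -> float:
    """P(two loci discordant | both fixed) at the given selfing generation.

    Converges to ``ril_discordance(r)`` as generations grow.
    """
    P = selfing_chain(r, generations)
    fixed = np.array([P[h, h] for h in _HAPLOTYPES])
    return (fixed[0b01] + fixed[0b10]) / fixed.sum()


def heterozygote_frequency(r: float, generations: int, locus: int = 0) -> float:
    """Marginal heterozygote frequency at one locus; (1/2)^(g-1) without selection."""
    P = selfing_chain(r, generations)
    bit = 1 - locus
    freq = 0.0
    for i in _HAPLOTYPES:
        for j in _HAPLOTYPES:
            if ((i >> bit) & 1) != ((j >> bit) & 1):
                freq += P[i, j]
    return freq


def allele_frequency(
    generations: int,
    s: float = 0.0,
    favored: int = 0,
    r: float = 0.5,
) -> float:
    """Marginal frequency of allele A at a (possibly selected) locus."""
    P = selfing_chain(r, generations, selection={0: (s, favored)} if s else None)
    freq = 0.0
    for i in _HAPLOTYPES:
        for j in _HAPLOTYPES:
            n_a = int(((i >> 1) & 1) == 0) + int(((j >> 1) & 1) == 0)
            freq += P[i, j] * n_a / 2.0
    return freq
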