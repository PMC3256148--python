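"""Synthetic genomes and F8 RIL populations with known truth.

The simulator emulates the setting of a fragmented plant genome assembly
mapped with a selfed recombinant inbred line (RIL) population:

* chromosomes tiled by scaffolds of random size, each scaffold presented
  in a shuffled "assembly view" with a hidden true order/orientation;
* markers at known positions, carried through to scaffold coordinates;
* a diverged second parent (SNPs at a configurable per-kb rate, InDels
  and structural variants) emitted as a minimal VCF-style table;
* F8 selfing with Haldane (no-interference) crossovers: per meiosis the
  crossover count on a chromosome is Poisson(genetic length in Morgans)
  with breakpoints uniform on the genetic scale;
* optional viability selection at distortion loci (weight ``1 - s``
  against the disfavoured homozygote each generation, with non-viable
  offspring replaced from the surviving population), which plants
  segregation distortion regions;
* a genotyping step adding allele-flip errors and missing data.

All coordinates are 0-based, half-open.  Everything is deterministic for
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from melonmap.genotypes import A, B, HET, MISSING, GenotypeMatrix

__all__ = [
    "ChromosomeSpec",
    "GenomeConfig",
    "DistortionLocus",
    "SimulatedGenome",
    "RILPopulation",
    "simulate_genome",
    "derive_alt_parent",
    "simulate_ril_population",
    "genotype_markers",
    "two_locus_genome",
    "watermelon_like_config",
    "watermelon_distortion_loci",
    "WATERMELON_TABLE1",
    "PERICENTROMERIC_PROFILE",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation settings."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome to simulate.

    ``recomb_profile`` is a monotone list of ``(bp_fraction, cm_fraction)``
    anchor points mapping relative physical to relative genetic position;
    ``None`` means a uniform landscape.  A sagging middle (e.g. 40% of the
    physical length holding 10% of the genetic length) emulates
    pericentromeric recombination suppression.
    """

    id: str
    length_bp: int
    cm_length: float
    n_scaffolds: int = 10
    n_markers: int = 50
    recomb_profile: tuple[tuple[float, float], ...] | None = None

    def cm_at(self, bp) -> np.ndarray:
        """Genetic position (cM) of physical position(s) bp."""
        bp = np.asarray(bp, dtype=float)
        if self.recomb_profile is None:
            return bp / self.length_bp * self.cm_length
        xs, ys = zip(*self.recomb_profile)
        return np.interp(bp / self.length_bp, xs, ys) * self.cm_length

    def bp_at(self, cm) -> np.ndarray:
        """Physical position for genetic position(s) cM (inverse of cm_at)."""
        cm = np.asarray(cm, dtype=float)
        if self.recomb_profile is None:
            return cm / self.cm_length * self.length_bp
        xs, ys = zip(*self.recomb_profile)
        return np.interp(cm / self.cm_length, ys, xs) * self.length_bp


@dataclass(frozen=True)
class GenomeConfig:
    chromosomes: tuple[ChromosomeSpec, ...]
    min_scaffold_bp: int = 1000
    with_sequence: bool = False
    #: expected planted SSR tracts per 10 kb in sequence mode
    ssr_rate_per_10kb: float = 0.5

    def __post_init__(self):
        if not self.chromosomes:
            raise ConfigurationError("at least one chromosome is required")
        for spec in self.chromosomes:
            if spec.length_bp <= 0:
                raise ConfigurationError(f"{spec.id}: length must be positive")
            if spec.cm_length <= 0:
                raise ConfigurationError(f"{spec.id}: cM length must be positive")
            if spec.n_markers < 1:
                raise ConfigurationError(f"{spec.id}: needs at least one marker")
            if spec.n_scaffolds < 1:
                raise ConfigurationError(f"{spec.id}: needs at least one scaffold")


@dataclass(frozen=True)
class DistortionLocus:
    """Viability-selected locus creating a segregation distortion region."""

    chrom: str
    bp: int
    favored: int  # genotypes.A or genotypes.B
    s: float

    def __post_init__(self):
        if not 0.0 <= self.s < 1.0:
            raise ConfigurationError("selection coefficient must lie in [0, 1)")
        if self.favored not in (A, B):
            raise ConfigurationError("favored allele must be A or B")


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class ScaffoldTruth:
    id: str
    chrom: str
    start: int  # on the chromosome, 0-based half-open
    end: int
    orientation: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MarkerTruth:
    id: str
    chrom: str
    bp: int  # on the chromosome
    scaffold: str
    offset: int  # on the scaffold, in its assembly presentation


@dataclass
class SimulatedGenome:
    chromosomes: list[tuple[str, int]]
    scaffolds: list[ScaffoldTruth]
    markers: list[MarkerTruth]
    config: GenomeConfig
    #: scaffold ids in shuffled order, as an assembly would present them
    assembly_order: list[str]
    sequences: dict[str, str] | None = None  # chromosome id -> sequence

    _scaffold_by_id: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._scaffold_by_id = {s.id: s for s in self.scaffolds}

    def spec(self, chrom: str) -> ChromosomeSpec:
        for s in self.config.chromosomes:
            if s.id == chrom:
                return s
        raise KeyError(chrom)

    def scaffold(self, scaffold_id: str) -> ScaffoldTruth:
        return self._scaffold_by_id[scaffold_id]

    def scaffold_lengths(self) -> dict[str, int]:
        return {s.id: s.length for s in self.scaffolds}

    def scaffold_sequence(self, scaffold_id: str) -> str:
        if self.sequences is None:
            raise ValueError("genome was simulated without sequence")
        sc = self._scaffold_by_id[scaffold_id]
        seq = self.sequences[sc.chrom][sc.start : sc.end]
        return _revcomp(seq) if sc.orientation == "-" else seq

    def marker_table(self) -> pd.DataFrame:
        """Truth table: marker -> chromosome bp and scaffold offset."""
        return pd.DataFrame(
            {
                "chrom": [m.chrom for m in self.markers],
                "bp": [m.bp for m in self.markers],
                "scaffold": [m.scaffold for m in self.markers],
                "offset": [m.offset for m in self.markers],
            },
            index=pd.Index([m.id for m in self.markers], name="marker"),
        )

    def scaffold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.scaffolds],
                "start": [s.start for s in self.scaffolds],
                "end": [s.end for s in self.scaffolds],
                "orientation": [s.orientation for s in self.scaffolds],
            },
            index=pd.Index([s.id for s in self.scaffolds], name="scaffold"),
        )

    def write_scaffold_table(self, path) -> None:
        self.scaffold_table().to_csv(path, sep="\t")

    def write_fasta(self, path, scaffolds: bool = True) -> None:
        """Write scaffold (assembly-view) or chromosome sequences as FASTA."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        if self.sequences is None:
            raise ValueError("genome was simulated without sequence")
        if scaffolds:
            records = [
                SeqRecord(Seq(self.scaffold_sequence(sid)), id=sid, description="")
                for sid in self.assembly_order
            ]
        else:
            records = [
                SeqRecord(Seq(seq), id=chrom, description="")
                for chrom, seq in self.sequences.items()
            ]
        with open(path, "w") as fh:
            seqio_write(records, fh, "fasta")


_BASES = np.array(list("ACGT"))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _partition_lengths(total: int, n: int, min_len: int, rng) -> np.ndarray:
    """Random composition of ``total`` into ``n`` parts, each >= min_len."""
    if n * min_len > total:
        raise ConfigurationError("chromosome too short for requested scaffolds")
    free = total - n * min_len
    weights = rng.dirichlet(np.full(n, 1.5))
    extra = np.floor(weights * free).astype(np.int64)
    extra[np.argmax(extra)] += free - extra.sum()
    return extra + min_len


def _plant_ssrs(seq: np.ndarray, rate_per_10kb: float, rng) -> None:
    """Overwrite random stretches with tandem motif repeats, in place."""
    n = rng.poisson(rate_per_10kb * len(seq) / 10_000)
    for _ in range(n):
        unit = rng.integers(2, 7)
        motif = _BASES[rng.integers(0, 4, unit)]
        if len(set(motif)) == 1:  # avoid homopolymers
            motif[rng.integers(0, unit)] = _BASES[(rng.integers(1, 4))]
        reps = rng.integers(4, 13)
        start = rng.integers(0, max(1, len(seq) - unit * reps))
        tract = np.tile(motif, reps)[: len(seq) - start]
        seq[start : start + len(tract)] = tract


def simulate_genome(config: GenomeConfig, seed: int) -> SimulatedGenome:
    """Simulate chromosomes, a scaffold tiling and marker positions.

    Scaffolds tile each chromosome without gaps or overlap; their true
    order and orientation are retained while ``assembly_order`` presents
    them shuffled.  Markers are placed on a jittered grid so that they
    are spread evenly along each chromosome, and are expressed both in
    chromosome coordinates (truth) and scaffold coordinates (observable).
    """
    rng = np.random.default_rng(seed)
    chromosomes: list[tuple[str, int]] = []
    scaffolds: list[ScaffoldTruth] = []
    markers: list[MarkerTruth] = []
    sequences: dict[str, str] | None = {} if config.with_sequence else None

    sc_counter = 0
    for spec in config.chromosomes:
        chromosomes.append((spec.id, spec.length_bp))
        lengths = _partition_lengths(
            spec.length_bp, spec.n_scaffolds, min(config.min_scaffold_bp, spec.length_bp // spec.n_scaffolds), rng
        )
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        chrom_scaffolds = []
        for ln, st in zip(lengths, starts):
            sc_counter += 1
            chrom_scaffolds.append(
                ScaffoldTruth(
                    id=f"scaffold{sc_counter}",
                    chrom=spec.id,
                    start=int(st),
                    end=int(st + ln),
                    orientation="+" if rng.random() < 0.5 else "-",
                )
            )
        scaffolds.extend(chrom_scaffolds)

        # jittered-grid marker placement (even coverage of the chromosome)
        k = spec.n_markers
        pos = ((np.arange(k) + rng.uniform(0.05, 0.95, k)) / k * spec.length_bp).astype(np.int64)
        pos = np.unique(pos)
        sc_ends = np.array([s.end for s in chrom_scaffolds])
        for i, bp in enumerate(pos):
            sc = chrom_scaffolds[int(np.searchsorted(sc_ends, bp, side="right"))]
            offset = bp - sc.start if sc.orientation == "+" else sc.end - 1 - bp
            markers.append(
                MarkerTruth(
                    id=f"M{spec.id}_{i:04d}",
                    chrom=spec.id,
                    bp=int(bp),
                    scaffold=sc.id,
                    offset=int(offset),
                )
            )

        if sequences is not None:
            seq = _BASES[rng.integers(0, 4, spec.length_bp)]
            _plant_ssrs(seq, config.ssr_rate_per_10kb, rng)
            sequences[spec.id] = "".join(seq)

    order = [scaffolds[i].id for i in rng.permutation(len(scaffolds))]
    return SimulatedGenome(
        chromosomes=chromosomes,
        scaffolds=scaffolds,
        markers=markers,
        config=config,
        assembly_order=order,
        sequences=sequences,
    )


# ---------------------------------------------------------------------------
# parental divergence


def derive_alt_parent(
    genome: SimulatedGenome,
    snp_per_kb: float = 7.14,
    indel_per_kb: float = 0.5,
    indel_size: tuple[int, int] = (1, 30),
    sv_per_mb: float = 2.0,
    sv_size: tuple[int, int] = (50, 2000),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a variant table describing the second (diverged) parent.

    Counts per chromosome are Poisson in the requested rates; positions
    are uniform.  ``length`` is the signed allele-length difference for
    InDels, the absolute size for SVs and 0 for SNPs.  Positions are
    reported both on the chromosome (truth) and on the containing
    scaffold in its assembly presentation (observable).
    """
    for rate in (snp_per_kb, indel_per_kb, sv_per_mb):
        if rate < 0:
            raise ConfigurationError("variant rates must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    sc_by_chrom: dict[str, list[ScaffoldTruth]] = {}
    for sc in genome.scaffolds:
        sc_by_chrom.setdefault(sc.chrom, []).append(sc)

    for chrom, length in genome.chromosomes:
        ends = np.array([s.end for s in sc_by_chrom[chrom]])
        plan = (
            ("SNP", rng.poisson(snp_per_kb * length / 1_000), lambda: 0),
            (
                "INDEL",
                rng.poisson(indel_per_kb * length / 1_000),
                lambda: int(rng.integers(indel_size[0], indel_size[1] + 1)) * (1 if rng.random() < 0.5 else -1),
            ),
            ("SV", rng.poisson(sv_per_mb * length / 1_000_000), lambda: int(rng.integers(sv_size[0], sv_size[1] + 1))),
        )
        for vtype, count, draw_len in plan:
            pos = np.sort(rng.integers(0, length, count))
            for bp in pos:
                sc = sc_by_chrom[chrom][int(np.searchsorted(ends, bp, side="right"))]
                if not sc.start <= bp < sc.end:
                    raise RuntimeError("variant placed outside its scaffold")
                offset = bp - sc.start if sc.orientation == "+" else sc.end - 1 - bp
                rows.append((chrom, int(bp), sc.id, int(offset), vtype, draw_len()))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "scaffold", "scaffold_pos", "type", "length"])
    df.index = [f"v{i:07d}" for i in range(len(df))]
    df.index.name = "id"
    return df


def write_variants_vcf(variants: pd.DataFrame, path) -> None:
    """Write the variant table as a minimal VCF (scaffold coordinates)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Allele length difference">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for vid, row in variants.iterrows():
            alt = {"SNP": "<SNP>", "INDEL": "<INDEL>", "SV": "<SV>"}[row["type"]]
            fh.write(
                f"{row['scaffold']}\t{row['scaffold_pos'] + 1}\t{vid}\tN\t{alt}\t.\t.\t"
                f"TYPE={row['type']};SVLEN={row['length']}\n"
            )


def read_variants_vcf(path) -> pd.DataFrame:
    """Read a minimal VCF back into the variant-table layout (via pysam)."""
    import pysam

    rows = []
    ids = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            ids.append(rec.id)
            rows.append(
                (rec.chrom, rec.start, str(rec.info.get("TYPE")), int(rec.info.get("SVLEN")))
            )
    df = pd.DataFrame(rows, columns=["scaffold", "scaffold_pos", "type", "length"])
    df.index = pd.Index(ids, name="id")
    return df


# ---------------------------------------------------------------------------
# RIL population

# a homolog is (bounds, alleles): bounds is an int64 array [0, b1, ..., L]
# and alleles[i] applies on [bounds[i], bounds[i+1])
Homolog = tuple[np.ndarray, np.ndarray]


def _slice_homolog(h: Homolog, a: int, b: int) -> tuple[list[int], list[int]]:
    bounds, alleles = h
    i = int(np.searchsorted(bounds, a, side="right")) - 1
    j = int(np.searchsorted(bounds, b, side="left"))
    seg_bounds = [a, *bounds[i + 1 : j].tolist()]
    seg_alleles = alleles[i:j].tolist()
    return seg_bounds, seg_alleles


def _simplify(bounds: list[int], alleles: list[int], L: int) -> Homolog:
    out_b = [bounds[0]]
    out_a = [alleles[0]]
    for b, a in zip(bounds[1:], alleles[1:]):
        if a == out_a[-1]:
            continue
        out_b.append(b)
        out_a.append(a)
    out_b.append(L)
    return np.asarray(out_b, dtype=np.int64), np.asarray(out_a, dtype=np.int8)


def _meiosis(h1: Homolog, h2: Homolog, spec: ChromosomeSpec, rng) -> Homolog:
    """One gamete: Poisson crossovers uniform on the genetic scale."""
    n_cx = rng.poisson(spec.cm_length / 100.0)
    L = spec.length_bp
    cur = int(rng.integers(2))
    if n_cx == 0:
        return (h1, h2)[cur]
    cx_bp = np.unique(spec.bp_at(np.sort(rng.uniform(0, spec.cm_length, n_cx))).astype(np.int64))
    cx_bp = cx_bp[(cx_bp > 0) & (cx_bp < L)]
    edges = [0, *cx_bp.tolist(), L]
    src = (h1, h2)
    bounds: list[int] = []
    alleles: list[int] = []
    for a, b in zip(edges[:-1], edges[1:]):
        sb, sa = _slice_homolog(src[cur], a, b)
        bounds.extend(sb)
        alleles.extend(sa)
        cur = 1 - cur
    return _simplify(bounds, alleles, L)


def _allele_at(h: Homolog, bp: np.ndarray) -> np.ndarray:
    bounds, alleles = h
    return alleles[np.searchsorted(bounds, bp, side="right") - 1]


Individual = dict[str, tuple[Homolog, Homolog]]


@dataclass
class RILPopulation:
    genome: SimulatedGenome
    generation: int
    individuals: list[str]
    homologs: list[Individual] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.individuals)

    def true_calls(self) -> np.ndarray:
        """Error-free genotype codes, markers x individuals."""
        mk = self.genome.markers
        by_chrom: dict[str, list[int]] = {}
        for idx, m in enumerate(mk):
            by_chrom.setdefault(m.chrom, []).append(idx)
        calls = np.empty((len(mk), self.n), dtype=np.int8)
        for chrom, idxs in by_chrom.items():
            bp = np.array([mk[i].bp for i in idxs], dtype=np.int64)
            for col, ind in enumerate(self.homologs):
                h1, h2 = ind[chrom]
                a1 = _allele_at(h1, bp)
                a2 = _allele_at(h2, bp)
                g = np.where(a1 == a2, a1, HET).astype(np.int8)
                calls[idxs, col] = g
        return calls

    def truth_crossovers(self) -> pd.DataFrame:
        """Breakpoints carried by each transmitted homolog, per chromosome."""
        rows = []
        for ril, ind in zip(self.individuals, self.homologs):
            for chrom, (h1, h2) in ind.items():
                for lineage, h in enumerate((h1, h2)):
                    for bp in h[0][1:-1]:
                        rows.append((ril, chrom, lineage, int(bp)))
        return pd.DataFrame(rows, columns=["individual", "chrom", "homolog", "bp"])

    def write_truth_crossovers(self, path) -> None:
        self.truth_crossovers().to_csv(path, sep="\t", index=False)


def _viability(ind: Individual, loci: list[tuple[str, np.ndarray, int, float]]) -> float:
    w = 1.0
    for chrom, bp, disfavored, s in loci:
        h1, h2 = ind[chrom]
        if _allele_at(h1, bp)[0] == disfavored and _allele_at(h2, bp)[0] == disfavored:
            w *= 1.0 - s
    return w


def simulate_ril_population(
    genome: SimulatedGenome,
    n: int,
    generations: int = 8,
    distortion: tuple[DistortionLocus, ...] = (),
    seed: int = 0,
) -> RILPopulation:
    """Self an F1 down to the requested generation for ``n`` lines.

    Viability selection: each generation every line produces one selfed
    offspring; an offspring survives with probability equal to the
    product of ``1 - s`` over distortion loci at which it is the
    disfavoured homozygote.  A non-surviving offspring is replaced by a
    new one drawn from a uniformly random line of the parent generation,
    so at the population level genotype frequencies follow the selfing
    transition reweighted by viability (the chain in
    :mod:`melonmap.theory`).
    """
    if generations < 2:
        raise ConfigurationError("generations must be >= 2 (generation 1 is the F1)")
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    chrom_len = dict(genome.chromosomes)
    for locus in distortion:
        if locus.chrom not in chrom_len:
            raise ConfigurationError(f"distortion locus on unknown chromosome {locus.chrom}")
        if not 0 <= locus.bp < chrom_len[locus.chrom]:
            raise ConfigurationError(f"distortion locus at {locus.bp} is off-chromosome")
    loci = [
        (d.chrom, np.array([d.bp], dtype=np.int64), 1 - d.favored, d.s) for d in distortion
    ]
    rng = np.random.default_rng(seed)
    specs = {s.id: s for s in genome.config.chromosomes}

    f1: Individual = {
        chrom: (
            (np.array([0, length], dtype=np.int64), np.array([A], dtype=np.int8)),
            (np.array([0, length], dtype=np.int64), np.array([B], dtype=np.int8)),
        )
        for chrom, length in genome.chromosomes
    }

    def self_offspring(parent: Individual) -> Individual:
        child: Individual = {}
        for chrom, (h1, h2) in parent.items():
            spec = specs[chrom]
            child[chrom] = (_meiosis(h1, h2, spec, rng), _meiosis(h1, h2, spec, rng))
        return child

    lines: list[Individual] = [f1] * n
    for _ in range(generations - 1):
        nxt: list[Individual] = []
        for i in range(n):
            parent = lines[i]
            while True:
                child = self_offspring(parent)
                if not loci or rng.random() < _viability(child, loci):
                    break
                parent = lines[int(rng.integers(n))]
            nxt.append(child)
        lines = nxt

    individuals = [f"RIL{i + 1:04d}" for i in range(n)]
    return RILPopulation(genome=genome, generation=generations, individuals=individuals, homologs=lines)


def genotype_markers(
    pop: RILPopulation,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    het_policy: str = "keep",
    seed: int = 0,
) -> GenotypeMatrix:
    """Score the population at the genome's markers, with noise.

    Each true call is independently flipped to the opposite homozygote
    with probability ``error_rate`` (heterozygous calls flip to a random
    homozygote) and masked with probability ``missing_rate``.
    ``het_policy`` is ``"keep"`` or ``"set_missing"`` for residual
    heterozygotes.
    """
    if not (0.0 <= error_rate < 1.0 and 0.0 <= missing_rate < 1.0):
        raise ConfigurationError("error and missing rates must lie in [0, 1)")
    if error_rate + missing_rate >= 1.0:
        raise ConfigurationError("error_rate + missing_rate must be < 1")
    if het_policy not in ("keep", "set_missing"):
        raise ConfigurationError("het_policy must be 'keep' or 'set_missing'")
    rng = np.random.default_rng(seed)
    calls = pop.true_calls().copy()

    flip = rng.random(calls.shape) < error_rate
    rand_hom = rng.integers(0, 2, calls.shape).astype(np.int8)
    flipped = np.where(calls == HET, rand_hom, 1 - calls).astype(np.int8)
    calls = np.where(flip, flipped, calls).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    if het_policy == "set_missing":
        calls[calls == HET] = MISSING

    truth = pop.genome.marker_table()
    markers = pd.DataFrame(
        {"scaffold": truth["scaffold"], "bp": truth["offset"]}, index=truth.index
    )
    return GenotypeMatrix(markers=markers, individuals=pop.individuals, calls=calls)


def two_locus_genome(r: float, length_bp: int = 1_000_000) -> SimulatedGenome:
    """One chromosome with exactly two markers a known r apart.

    The chromosome's genetic length is chosen so that the Haldane map
    distance between the two markers (placed at the first and last base)
    corresponds exactly to meiotic recombination fraction ``r``; used
    for calibrating two-point estimators against theory.
    """
    from melonmap.theory import haldane_cm

    L = length_bp
    cm = haldane_cm(r) * L / (L - 1)
    spec = ChromosomeSpec(id="c1", length_bp=L, cm_length=cm, n_scaffolds=1, n_markers=2)
    config = GenomeConfig(chromosomes=(spec,))
    sc = ScaffoldTruth(id="scaffold1", chrom="c1", start=0, end=L, orientation="+")
    markers = [
        MarkerTruth(id="Mc1_0000", chrom="c1", bp=0, scaffold="scaffold1", offset=0),
        MarkerTruth(id="Mc1_0001", chrom="c1", bp=L - 1, scaffold="scaffold1", offset=L - 1),
    ]
    return SimulatedGenome(
        chromosomes=[("c1", L)],
        scaffolds=[sc],
        markers=markers,
        config=config,
        assembly_order=["scaffold1"],
    )


# ---------------------------------------------------------------------------
# watermelon-scale preset

#: per-linkage-group (loci, anchored scaffolds, scaffold Mb, cM) of the
#: reference watermelon map; totals 953 loci, 234 scaffolds, 330.4 Mb, 798 cM.
WATERMELON_TABLE1: dict[str, tuple[int, int, float, float]] = {
    "chr01": (114, 30, 34.1, 115.4),
    "chr02": (107, 23, 34.4, 94.8),
    "chr03": (90, 25, 28.9, 65.2),
    "chr04": (71, 18, 24.3, 60.5),
    "chr05": (98, 21, 33.7, 96.4),
    "chr06": (79, 20, 27.0, 63.3),
    "chr07": (74, 26, 31.5, 63.9),
    "chr08": (63, 16, 26.1, 29.2),
    "chr09": (91, 21, 35.0, 79.1),
    "chr10": (91, 20, 28.4, 94.9),
    "chr11": (75, 14, 27.1, 35.3),
}

#: pericentromeric profile: chromosome ends recombine ~3.4x the average,
#: the middle 40% holds only 10% of the genetic length (suppressed)
PERICENTROMERIC_PROFILE = ((0.0, 0.0), (0.3, 0.45), (0.7, 0.55), (1.0, 1.0))


def watermelon_like_config(
    total_mb: float = 353.0,
    with_sequence: bool = False,
    pericentromeric: bool = True,
) -> GenomeConfig:
    """Eleven chromosomes mirroring the reference watermelon map.

    Per-chromosome marker counts, scaffold counts, genetic lengths and
    relative physical sizes follow the published per-LG summary; the
    physical lengths are rescaled so the genome totals ``total_mb``
    (default: the 353 Mb assembly size).
    """
    scale = total_mb / sum(v[2] for v in WATERMELON_TABLE1.values())
    chroms = tuple(
        ChromosomeSpec(
            id=chrom,
            length_bp=int(round(mb * scale * 1e6)),
            cm_length=cm,
            n_scaffolds=n_sc,
            n_markers=loci,
            recomb_profile=PERICENTROMERIC_PROFILE if pericentromeric else None,
        )
        for chrom, (loci, n_sc, mb, cm) in WATERMELON_TABLE1.items()
    )
    return GenomeConfig(chromosomes=chroms, min_scaffold_bp=100_000, with_sequence=with_sequence)


def watermelon_distortion_loci(
    config: GenomeConfig, s: float = 0.3
) -> tuple[DistortionLocus, ...]:
    """Nine selected loci emulating the observed distortion pattern.

    Eight favour the A (elite-line) parent and one, on chr10, favours
    the B (wild) parent; each sits mid-arm of its chromosome.
    """
    skewed = {
        "chr01": A, "chr02": A, "chr03": A, "chr04": A, "chr05": A,
        "chr07": A, "chr08": A, "chr09": A, "chr10": B,
    }
    loci = []
    for spec in config.chromosomes:
        if spec.id in skewed:
            bp = int(spec.bp_at(0.55 * spec.cm_length))
            loci.append(DistortionLocus(chrom=spec.id, bp=bp, favored=skewed[spec.id], s=s))
    return tuple(loci)
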