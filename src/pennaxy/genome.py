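"""Diploid bit-string genomes.

An individual's genome is a pair of bit strings per chromosome: 0 marks a
functional allele, 1 a defective recessive one.  Locus index encodes
activation age — a chromosome of ``q * basic_length`` loci activates ``q``
loci per year of life, and a phenotypic defect is expressed only when both
alleles at a locus are defective.  Gametes are produced by replication with
mutation (0 -> 1 only; no reversions), reciprocal crossover at intergenic
boundaries, and a uniform choice between the two products.

The one pair flagged ``is_sex_pair`` is treated as X/Y: in males the first
copy is X and the second is Y; crossover between them uses a caller-supplied
rate so the engine can turn X-Y recombination off, fix it, or let it evolve.
After an X-Y crossover the product that keeps the chromosome start of the
parental Y is labelled Y (the model has no explicit sex-determining locus, so
a stable positional convention stands in for one).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .errors import ConfigurationError, InvariantViolation

__all__ = [
    "ChromosomeSpec", "ChromosomeTable", "Genome", "Gamete",
    "replicate_with_mutation", "crossover", "crossover_at", "make_gamete",
    "count_homozygous_defects", "count_defective_alleles",
    "human_table", "toy_table",
]

_TABLE_COLUMNS = ["name", "length_genes", "mutation_mean", "recomb_mean", "is_sex_pair"]

_MUT_DIALECTS = {"bernoulli": K.MUT_BERNOULLI, "poisson": K.MUT_POISSON}
_CROSS_DIALECTS = {"poisson": K.CROSS_POISSON, "bernoulli": K.CROSS_BERNOULLI}


@dataclass(frozen=True)
class ChromosomeSpec:
    """Static parameters of one chromosome pair.

    mutation_mean is the expected number of new defective mutations per copy
    per replication; recomb_mean the expected crossover events per meiosis.
    """

    name: str
    length_genes: int
    mutation_mean: float
    recomb_mean: float
    is_sex_pair: bool = False

    def __post_init__(self) -> None:
        if self.length_genes <= 0:
            raise ConfigurationError(f"chromosome {self.name!r}: length_genes must be > 0")
        if self.mutation_mean < 0 or self.recomb_mean < 0:
            raise ConfigurationError(f"chromosome {self.name!r}: rates must be >= 0")


class ChromosomeTable:
    """Ordered set of chromosome specs plus the basic length L.

    Every chromosome length must be a positive multiple of ``basic_length``
    (the maximum lifespan); exactly one spec is the sex pair.
    """

    def __init__(self, specs: Iterable[ChromosomeSpec], basic_length: int = 128):
        self.specs: tuple[ChromosomeSpec, ...] = tuple(specs)
        self.basic_length = int(basic_length)
        if self.basic_length <= 0:
            raise ConfigurationError("basic_length must be positive")
        if not self.specs:
            raise ConfigurationError("chromosome table is empty")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        n_sex = sum(s.is_sex_pair for s in self.specs)
        if n_sex != 1:
            raise ConfigurationError(f"exactly one sex pair required, found {n_sex}")
        for s in self.specs:
            if s.length_genes % self.basic_length != 0:
                raise ConfigurationError(
                    f"chromosome {s.name!r}: length {s.length_genes} is not a "
                    f"multiple of basic_length {self.basic_length}")
        self.lengths = np.array([s.length_genes for s in self.specs], np.int64)
        self.starts = np.concatenate(([0], np.cumsum(self.lengths)[:-1])).astype(np.int64)
        self.genes_per_year = (self.lengths // self.basic_length).astype(np.int64)
        self.total_loci = int(self.lengths.sum())
        self.mutation_means = np.array([s.mutation_mean for s in self.specs], float)
        self.recomb_means = np.array([s.recomb_mean for s in self.specs], float)
        self.sex_index = next(i for i, s in enumerate(self.specs) if s.is_sex_pair)
        self._index = {s.name: i for i, s in enumerate(self.specs)}

    def __len__(self) -> int:
        return len(self.specs)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConfigurationError(f"unknown chromosome name {name!r}") from None

    def spec(self, name: str) -> ChromosomeSpec:
        return self.specs[self.index(name)]

    def slice_of(self, name: str) -> slice:
        i = self.index(name)
        return slice(int(self.starts[i]), int(self.starts[i] + self.lengths[i]))

    @property
    def sex_name(self) -> str:
        return self.specs[self.sex_index].name

    @property
    def genome_mutation_rate(self) -> float:
        """Expected new mutations per diploid genome per generation (2 copies/pair)."""
        return 2.0 * float(self.mutation_means.sum())

    # ---- tab-separated persistence (strict schema) ----

    @classmethod
    def from_tsv(cls, path, basic_length: int = 128) -> "ChromosomeTable":
        df = pd.read_csv(path, sep="\t", dtype={"name": str})
        if list(df.columns) != _TABLE_COLUMNS:
            raise ConfigurationError(
                f"chromosome table columns must be exactly {_TABLE_COLUMNS}, "
                f"got {list(df.columns)}")
        specs = [
            ChromosomeSpec(
                name=str(r["name"]),
                length_genes=int(r["length_genes"]),
                mutation_mean=float(r["mutation_mean"]),
                recomb_mean=float(r["recomb_mean"]),
                is_sex_pair=bool(int(r["is_sex_pair"])),
            )
            for r in df.to_dict("records")
        ]
        return cls(specs, basic_length=basic_length)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "name": [s.name for s in self.specs],
                "length_genes": [s.length_genes for s in self.specs],
                "mutation_mean": [s.mutation_mean for s in self.specs],
                "recomb_mean": [s.recomb_mean for s in self.specs],
                "is_sex_pair": [int(s.is_sex_pair) for s in self.specs],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def human_table() -> ChromosomeTable:
    """23-pair table approximating the human genome.

    Gene counts are rounded to multiples of 128; per-copy mutation means are
    proportional to length and sum (over both copies of all pairs) to one new
    mutation per genome per generation; crossover means are sex-averaged
    genetic-map lengths in Morgans.  Values are a documented approximation and
    fully overridable via ``ChromosomeTable.from_tsv``.
    """
    ref = importlib.resources.files("pennaxy.data") / "human23.tsv"
    with importlib.resources.as_file(ref) as p:
        return ChromosomeTable.from_tsv(p)


def toy_table(basic_length: int = 128) -> ChromosomeTable:
    """Three-pair desk-scale table: two autosomes and one sex pair.

    Each pair has one locus per year of life and undergoes one crossover per
    meiosis on average (the biological minimum for proper segregation), so
    the initial X-Y rate in the evolving regime is 1.0.  The per-copy
    mutation mean of 0.75 (4.5 new mutations per diploid genome per
    generation, the top of the empirical human range) compresses time: a
    desk-scale run of ~200 generations then reaches mutation-selection
    balance and exhibits ratchet dynamics that the full-scale genome needs
    thousands of generations to develop.  "A2" is the comparator autosome
    standing in for the length-matched 10th chromosome.
    """
    m = 0.75
    return ChromosomeTable(
        [
            ChromosomeSpec("A1", basic_length, m, 1.0),
            ChromosomeSpec("A2", basic_length, m, 1.0),
            ChromosomeSpec("XY", basic_length, m, 1.0, is_sex_pair=True),
        ],
        basic_length=basic_length,
    )


@dataclass
class Gamete:
    """One haploid product: one chromosome per spec, concatenated."""

    table: ChromosomeTable
    bits: np.ndarray
    sex_carried: str = "X"  # 'Y' only for male-parent gametes

    def chromosome(self, name: str) -> np.ndarray:
        return self.bits[self.table.slice_of(name)]


@dataclass
class Genome:
    """Diploid genome: bits[copy, locus] over concatenated chromosomes.

    Copy 0 is maternally inherited (always X at the sex pair); copy 1 is
    paternal (Y at the sex pair in males).
    """

    table: ChromosomeTable
    bits: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bits is None:
            self.bits = np.zeros((2, self.table.total_loci), np.uint8)
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (2, self.table.total_loci):
            raise InvariantViolation(
                f"genome shape {self.bits.shape} does not match table "
                f"(2, {self.table.total_loci})")

    @classmethod
    def zeros(cls, table: ChromosomeTable) -> "Genome":
        return cls(table)

    def pair(self, name: str) -> np.ndarray:
        """(2, length) view of one chromosome pair."""
        return self.bits[:, self.table.slice_of(name)]

    def copy(self) -> "Genome":
        return Genome(self.table, self.bits.copy())


def _as_bits(chrom: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.ascontiguousarray(chrom, dtype=np.uint8)
    if arr.ndim != 1:
        raise InvariantViolation("a chromosome is a 1-D bit vector")
    if arr.size and arr.max() > 1:
        raise InvariantViolation("chromosome bits must be 0/1")
    return arr


def replicate_with_mutation(chrom, mutation_mean: float, rng: np.random.Generator,
                            dialect: str = "bernoulli") -> np.ndarray:
    """Copy a chromosome, introducing new defective mutations.

    Under the default Bernoulli dialect exactly one uniformly chosen site is
    set to 1 with probability ``mutation_mean`` (which must then lie in
    [0, 1]); the Poisson dialect draws the number of mutated sites instead.
    A mutation landing on an already-defective site is consumed silently, so
    there are no reversions.
    """
    try:
        d = _MUT_DIALECTS[dialect]
    except KeyError:
        raise ConfigurationError(f"unknown mutation dialect {dialect!r}") from None
    if mutation_mean < 0 or (d == K.MUT_BERNOULLI and mutation_mean > 1):
        raise ConfigurationError(
            f"mutation_mean {mutation_mean} invalid for dialect {dialect!r}")
    out = _as_bits(chrom).copy()
    K.mutate_chrom(out, float(mutation_mean), d, rng)
    return out


def crossover(a, b, recomb_mean: float, rng: np.random.Generator,
              dialect: str = "poisson") -> tuple[np.ndarray, np.ndarray]:
    """Reciprocal crossover between two homologous copies.

    Draws the number of crossover events (Poisson(recomb_mean) by default, or
    a single Bernoulli(recomb_mean) event) at distinct intergenic boundaries
    and returns the two exchange products.  The per-position allele multiset
    is conserved.
    """
    try:
        d = _CROSS_DIALECTS[dialect]
    except KeyError:
        raise ConfigurationError(f"unknown crossover dialect {dialect!r}") from None
    if recomb_mean < 0 or (d == K.CROSS_BERNOULLI and recomb_mean > 1):
        raise ConfigurationError(
            f"recomb_mean {recomb_mean} invalid for dialect {dialect!r}")
    ca, cb = _as_bits(a).copy(), _as_bits(b).copy()
    if ca.shape != cb.shape:
        raise InvariantViolation(
            f"homologous copies differ in length: {ca.size} vs {cb.size}")
    K.crossover_pair(ca, cb, float(recomb_mean), d, rng)
    return ca, cb


def crossover_at(a, b, points: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic crossover at explicit intergenic boundaries (1..len-1)."""
    ca, cb = _as_bits(a).copy(), _as_bits(b).copy()
    if ca.shape != cb.shape:
        raise InvariantViolation(
            f"homologous copies differ in length: {ca.size} vs {cb.size}")
    pts = np.unique(np.asarray(points, np.int64))
    if pts.size and (pts.min() < 1 or pts.max() > ca.size - 1):
        raise InvariantViolation("crossover boundaries must lie in 1..len-1")
    K.exchange_at(ca, cb, pts)
    return ca, cb


def make_gamete(genome: Genome, sex: str, rng: np.random.Generator,
                xy_recomb: float | None = None,
                mutation_dialect: str = "bernoulli",
                crossover_dialect: str = "poisson") -> Gamete:
    """Form a haploid gamete from a diploid genome.

    Per pair: replicate both copies with mutation, cross them over (autosomes
    and the female sex pair use the table's recomb_mean; the male sex pair
    uses ``xy_recomb``), and pick one product uniformly.  For a male parent
    ``sex_carried`` records whether the sex-pair product is the Y-labelled
    one.
    """
    if sex not in ("male", "female"):
        raise ConfigurationError(f"sex must be 'male' or 'female', got {sex!r}")
    t = genome.table
    is_male = 1 if sex == "male" else 0
    if is_male:
        rate = t.recomb_means[t.sex_index] if xy_recomb is None else float(xy_recomb)
        if rate < 0:
            raise ConfigurationError("xy_recomb must be >= 0")
    else:
        rate = 0.0  # unused: females cross X-X at the table rate
    md = _MUT_DIALECTS[mutation_dialect]
    cd = _CROSS_DIALECTS[crossover_dialect]
    total = t.total_loci
    buf_a = np.empty(total, np.uint8)
    buf_b = np.empty(total, np.uint8)
    out = np.empty(total, np.uint8)
    carries_y = K.gamete_from_rows(
        genome.bits[0], genome.bits[1], t.starts, t.lengths,
        t.mutation_means, t.recomb_means, t.sex_index,
        is_male, rate, md, cd, buf_a, buf_b, out, rng)
    return Gamete(t, out, "Y" if carries_y else "X")


def count_homozygous_defects(genome: Genome, year_lo: int = 0,
                             year_hi: int | None = None) -> int:
    """Homozygous defective loci whose activation year lies in [year_lo, year_hi).

    Each chromosome contributes its ``genes_per_year`` loci per year; the sex
    pair's X and Y copies are compared positionally like any homologous pair.
    """
    t = genome.table
    L = t.basic_length
    if year_hi is None:
        year_hi = L
    if not (0 <= year_lo <= year_hi <= L):
        raise InvariantViolation(
            f"activation-year window [{year_lo}, {year_hi}) outside [0, {L})")
    hom = (genome.bits[0] & genome.bits[1])
    total = 0
    for i in range(len(t)):
        k = int(t.genes_per_year[i])
        s = int(t.starts[i])
        total += int(hom[s + year_lo * k: s + year_hi * k].sum())
    return total


def count_defective_alleles(genome: Genome, spec_name: str) -> tuple[int, int]:
    """Defective-allele count of each copy of the named pair.

    Reported per copy so callers can pool X copies (both sexes) and Y copies
    (males only) separately.
    """
    pair = genome.pair(spec_name)
    return int(pair[0].sum()), int(pair[1].sum())
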