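"""Monte Carlo scheduler for the lattice Penna model.

One Monte Carlo step (one model "year") ages every individual by one,
discloses the homozygous defects of the loci activating at the new age, kills
individuals that reach the defect threshold T or the maximum age L, and then
lets every reproductive-age female attempt conception.  Population size is
bounded by the lattice (one individual per cell) rather than a Verhulst
factor; a panmictic mode replaces neighborhoods by the whole population and
the lattice by a fixed pool of slots.

Mating systems: ``unfaithful`` females pick a new partner within range D_p on
every attempt; ``faithful`` females bond to one male for life (widows may
re-pair).  X-Y recombination regimes: ``off`` (rate 0), ``on`` (the sex
pair's table rate) and ``evolving`` (sons inherit the father's rate perturbed
by +/- modifier_step, absorbing at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from . import _kernels as K
from . import stats as _stats
from .errors import ConfigurationError, InvariantViolation
from .genome import ChromosomeTable, Genome, human_table, toy_table
from .lattice import Individual, neighbor_table

__all__ = [
    "ScenarioConfig", "RunState", "RunResult", "ExperimentResult",
    "initialize", "aging_phase", "reproduction_phase", "mutate_modifier",
    "run", "run_replicates", "preset_config", "available_presets", "PRESETS",
]

_MATINGS = ("unfaithful", "faithful")
_REGIMES = {"off": K.REGIME_OFF, "on": K.REGIME_ON, "evolving": K.REGIME_EVOLVING}

RECORD_COLUMNS = ["step", "pop", "births", "deaths", "norm_xy"] + [
    f"{q}_{coh}" for coh in ("newborns", "youths", "adults")
    for q in ("x10", "yx", "mf", "n", "males")
]


@dataclass
class ScenarioConfig:
    """Every free parameter of a run.

    Defaults are the full-scale study conditions: L=128, b=75, R=105, B=8,
    D_p=D_c=6 on a 128x128 torus for 1,000,000 steps and 50 replicates, with
    one new mutation per genome per generation spread over 23 chromosome
    pairs.  T defaults to 3 (unfaithful mating); faithful scenarios use 20.
    """

    mating: str = "unfaithful"
    xy_regime: str = "on"
    death_threshold: int = 3            # T
    basic_length: int = 128             # L, also the maximum age
    birth_check: int = 75               # b, activation years checked prenatally
    repro_age: int = 105                # R
    attempts_mean: float = 8.0          # B, Poisson mean conception attempts
    partner_range: int = 6              # D_p
    child_range: int = 6                # D_c
    lattice_side: int = 128
    steps: int = 1_000_000
    replicates: int = 50
    seed: int = 0
    modifier_step: float = 0.05
    chromosome_table: object = "human23"  # name, path, or ChromosomeTable
    comparator: str = "10"              # reference autosome for the X/10 ratio
    mutation_dialect: str = "bernoulli"
    crossover_dialect: str = "poisson"
    panmictic: bool = False
    record_every: Optional[int] = None

    def resolve_table(self) -> ChromosomeTable:
        t = self.chromosome_table
        if isinstance(t, ChromosomeTable):
            table = t
        elif t == "human23":
            table = human_table()
        elif t == "toy3":
            table = toy_table(self.basic_length)
        else:
            table = ChromosomeTable.from_tsv(t, basic_length=self.basic_length)
        return table

    def validate(self) -> ChromosomeTable:
        L, b, R = self.basic_length, self.birth_check, self.repro_age
        if not (0 < b < R <= L):
            raise ConfigurationError(
                f"need 0 < birth_check < repro_age <= basic_length, got "
                f"birth_check={b}, repro_age={R}, basic_length={L}")
        if self.death_threshold < 1:
            raise ConfigurationError("death_threshold must be >= 1")
        if self.partner_range <= 0 or self.child_range <= 0:
            raise ConfigurationError("partner_range and child_range must be positive")
        if self.lattice_side <= 0:
            raise ConfigurationError("lattice_side must be positive")
        if self.steps < 0:
            raise ConfigurationError("steps must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.attempts_mean < 0:
            raise ConfigurationError("attempts_mean must be >= 0")
        if self.modifier_step < 0:
            raise ConfigurationError("modifier_step must be >= 0")
        if self.mating not in _MATINGS:
            raise ConfigurationError(f"mating must be one of {_MATINGS}")
        if self.xy_regime not in _REGIMES:
            raise ConfigurationError(f"xy_regime must be one of {tuple(_REGIMES)}")
        if self.record_every is not None and self.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")
        table = self.resolve_table()
        if table.basic_length != L:
            raise ConfigurationError(
                f"table basic_length {table.basic_length} != config basic_length {L}")
        table.index(self.comparator)
        if table.index(self.comparator) == table.sex_index:
            raise ConfigurationError("comparator cannot be the sex pair")
        if self.mutation_dialect == "bernoulli" and table.mutation_means.max() > 1:
            raise ConfigurationError(
                "bernoulli mutation dialect requires all mutation means <= 1")
        if self.mutation_dialect not in ("bernoulli", "poisson"):
            raise ConfigurationError(f"unknown mutation dialect {self.mutation_dialect!r}")
        if self.crossover_dialect not in ("poisson", "bernoulli"):
            raise ConfigurationError(f"unknown crossover dialect {self.crossover_dialect!r}")
        return table

    def effective_record_every(self) -> int:
        if self.record_every is not None:
            return self.record_every
        return 1 if self.steps <= 100_000 else 100

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if isinstance(d["chromosome_table"], ChromosomeTable):
            d["chromosome_table"] = "<in-memory table>"
        return d


_FIG7 = {
    "RU": dict(mating="unfaithful", xy_regime="on", death_threshold=3),
    "RF": dict(mating="faithful", xy_regime="on", death_threshold=20),
    "NU": dict(mating="unfaithful", xy_regime="off", death_threshold=3),
    "NF": dict(mating="faithful", xy_regime="off", death_threshold=20),
    "EU": dict(mating="unfaithful", xy_regime="evolving", death_threshold=3),
    "EF": dict(mating="faithful", xy_regime="evolving", death_threshold=20),
}

_FULL = dict(lattice_side=128, steps=1_000_000, replicates=50,
             chromosome_table="human23", comparator="10")
# Desk-scale profile for quick, reproducible behavioural checks.
_DESK = dict(lattice_side=32, steps=20_000, replicates=5,
             chromosome_table="toy3", comparator="A2")

PRESETS: dict[str, dict] = {}
for _name, _kw in _FIG7.items():
    PRESETS[_name] = {**_kw, **_FULL}
    PRESETS["DESK-" + _name] = {**_kw, **_DESK}


def available_presets() -> list[str]:
    return sorted(PRESETS)


def preset_config(name: str, **overrides) -> ScenarioConfig:
    """Expand a scenario preset, then apply field overrides."""
    key = name.upper()
    if key not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}")
    kw = dict(PRESETS[key])
    kw.update(overrides)
    cfg = ScenarioConfig(**kw)
    cfg.validate()
    return cfg


@dataclass
class RunState:
    """Mutable per-replicate state, cell-indexed (one slot per lattice cell)."""

    config: ScenarioConfig
    table: ChromosomeTable
    rng: np.random.Generator
    ncells: int
    occ: np.ndarray          # bool, alive flag per cell
    sex: np.ndarray          # int64, 0 female / 1 male
    age: np.ndarray          # int64
    cum: np.ndarray          # int64, disclosed homozygous defects
    xymod: np.ndarray        # float64, males' X-Y recombination value
    partner: np.ndarray      # int64, bonded partner cell or -1
    genome: np.ndarray       # uint8 (ncells, 2, total_loci)
    year_def: np.ndarray     # int32 (ncells, L) homozygous defects per activation year
    cnt_s0: np.ndarray       # int64 defective alleles on sex-pair copy 0 (X)
    cnt_s1: np.ndarray       # int64 on copy 1 (Y in males)
    cnt_c0: np.ndarray       # int64 on comparator copy 0
    cnt_c1: np.ndarray       # int64 on comparator copy 1
    nbr_p: np.ndarray        # int32 neighbor table for partner search
    nbr_c: np.ndarray        # for child placement
    partner_full: bool       # scan the whole pool instead of a neighborhood
    child_full: bool
    initial_xy_rate: float
    step: int = 0
    extinct: bool = False

    @property
    def population_size(self) -> int:
        return int(self.occ.sum())

    def genome_of(self, cell: int) -> Genome:
        return Genome(self.table, self.genome[cell])

    def individuals(self) -> Iterator[Individual]:
        side = self.config.lattice_side
        for i in np.flatnonzero(self.occ):
            i = int(i)
            yield Individual(
                id=i,
                sex="male" if self.sex[i] == 1 else "female",
                age=int(self.age[i]),
                genome=self.genome_of(i),
                cum_defects=int(self.cum[i]),
                xy_modifier=float(self.xymod[i]),
                partner_id=int(self.partner[i]) if self.partner[i] >= 0 else None,
                position=None if self.config.panmictic else divmod(i, side),
            )

    def refresh_derived(self, cells=None) -> None:
        """Recompute year_def and per-copy counts from genome bits.

        Only needed after direct edits of genome arrays (tests, fixtures);
        the engine maintains these incrementally.
        """
        t = self.table
        idx = np.flatnonzero(self.occ) if cells is None else np.asarray(cells)
        ss, se = t.starts[t.sex_index], t.starts[t.sex_index] + t.lengths[t.sex_index]
        cidx = t.index(self.config.comparator)
        cs, ce = t.starts[cidx], t.starts[cidx] + t.lengths[cidx]
        for i in idx:
            g = self.genome[i]
            K.zygote_year_defects(g[0], g[1], t.starts, t.lengths,
                                  t.genes_per_year, t.basic_length,
                                  self.year_def[i])
            self.cnt_s0[i] = g[0, ss:se].sum()
            self.cnt_s1[i] = g[1, ss:se].sum()
            self.cnt_c0[i] = g[0, cs:ce].sum()
            self.cnt_c1[i] = g[1, cs:ce].sum()


def _neighbor_setup(config: ScenarioConfig):
    """Neighbor tables, switching to full scans when a range wraps the torus."""
    side = config.lattice_side
    dummy = np.zeros((1, 1), np.int32)
    if config.panmictic:
        return dummy, dummy, True, True
    partner_full = 2 * config.partner_range + 1 >= side
    child_full = 2 * config.child_range + 1 >= side
    nbr_p = dummy if partner_full else neighbor_table(side, config.partner_range)
    nbr_c = dummy if child_full else neighbor_table(side, config.child_range)
    return nbr_p, nbr_c, partner_full, child_full


def initialize(config: ScenarioConfig, rng: np.random.Generator) -> RunState:
    """Fill every cell with a mutation-free individual of random sex and age.

    Sex is uniform, age uniform on [0, L-1]; males start with the regime's
    X-Y recombination value (the sex pair's table rate for ``on`` and
    ``evolving``, 0 for ``off``); nobody is pair-bonded.
    """
    table = config.validate()
    ncells = config.lattice_side ** 2
    L = config.basic_length
    sex = rng.integers(0, 2, ncells).astype(np.int64)
    age = rng.integers(0, L, ncells).astype(np.int64)
    regime = _REGIMES[config.xy_regime]
    initial_rate = float(table.recomb_means[table.sex_index])
    xymod = np.zeros(ncells, float)
    if regime != K.REGIME_OFF:
        xymod[sex == 1] = initial_rate
    nbr_p, nbr_c, pf, cf = _neighbor_setup(config)
    return RunState(
        config=config, table=table, rng=rng, ncells=ncells,
        occ=np.ones(ncells, bool), sex=sex, age=age,
        cum=np.zeros(ncells, np.int64), xymod=xymod,
        partner=np.full(ncells, -1, np.int64),
        genome=np.zeros((ncells, 2, table.total_loci), np.uint8),
        year_def=np.zeros((ncells, L), np.int32),
        cnt_s0=np.zeros(ncells, np.int64), cnt_s1=np.zeros(ncells, np.int64),
        cnt_c0=np.zeros(ncells, np.int64), cnt_c1=np.zeros(ncells, np.int64),
        nbr_p=nbr_p, nbr_c=nbr_c, partner_full=pf, child_full=cf,
        initial_xy_rate=initial_rate,
    )


def aging_phase(state: RunState) -> int:
    """Age everyone by one year, disclose defects, apply deaths; returns deaths."""
    c = state.config
    return int(K.aging_k(state.occ, state.sex, state.age, state.cum,
                         state.partner, state.year_def,
                         c.basic_length, c.birth_check, c.death_threshold))


def reproduction_phase(state: RunState) -> tuple[int, int]:
    """Let reproductive females attempt conception; returns (births, attempts)."""
    c = state.config
    t = state.table
    eligible = state.occ & (state.sex == 0) & (state.age >= c.repro_age)
    order = state.rng.permutation(np.flatnonzero(eligible)).astype(np.int64)
    if order.size == 0:
        return 0, 0
    births, attempts = K.reproduction_k(
        order, state.occ, state.sex, state.age, state.cum, state.xymod,
        state.partner, state.genome, state.year_def,
        state.cnt_s0, state.cnt_s1, state.cnt_c0, state.cnt_c1,
        state.nbr_p, state.nbr_c, state.partner_full, state.child_full,
        t.starts, t.lengths, t.genes_per_year, t.mutation_means,
        t.recomb_means, t.sex_index, t.index(c.comparator),
        c.basic_length, c.birth_check, c.repro_age, c.death_threshold,
        float(c.attempts_mean), c.mating == "faithful", _REGIMES[c.xy_regime],
        float(t.recomb_means[t.sex_index]), float(c.modifier_step),
        0 if c.mutation_dialect == "bernoulli" else 1,
        0 if c.crossover_dialect == "poisson" else 1,
        state.rng)
    return int(births), int(attempts)


def mutate_modifier(parent_value: float, step: float,
                    rng: np.random.Generator) -> float:
    """Transmit the X-Y recombination modifier father -> son.

    0 is absorbing; otherwise the value moves by +/- step with equal
    probability, clamped at 0 (no upper bound).
    """
    if parent_value < 0:
        raise InvariantViolation("modifier value must be >= 0")
    return float(K.mutate_modifier_k(float(parent_value), float(step), rng))


@dataclass
class RunResult:
    """A single replicate: per-step records plus the final state."""

    config: ScenarioConfig
    seed: int
    records: pd.DataFrame
    extinct: bool
    extinct_step: Optional[int]
    state: RunState


@dataclass
class ExperimentResult:
    """Replicate set: individual runs and their step-wise mean aggregate."""

    config: ScenarioConfig
    seeds: list[int]
    runs: list[RunResult]
    aggregate: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        frames = [r.records for r in self.runs]
        self.aggregate = (
            pd.concat(frames, ignore_index=True)
            .groupby("step", as_index=False).mean()
            .sort_values("step").reset_index(drop=True)
        )

    @property
    def any_extinct(self) -> bool:
        return any(r.extinct for r in self.runs)


def _record(state: RunState, births: int, deaths: int) -> tuple:
    row = [float(state.step), float(state.population_size),
           float(births), float(deaths), _stats.mean_norm_xy(state)]
    masks = _stats.cohort_masks(state)
    for coh in ("newborns", "youths", "adults"):
        mask = masks[coh]
        x10, yx = _stats.mutation_ratios(state, mask)
        row.extend([x10, yx, _stats.sex_ratio(state, mask), float(mask.sum()),
                    float((mask & (state.sex == 1)).sum())])
    return tuple(row)


def run(config: ScenarioConfig, seed: Optional[int] = None) -> RunResult:
    """Execute one replicate: initialize, then age/reproduce/record per step.

    Deterministic for a fixed (config, seed).  Extinction truncates the
    series and is flagged on the result rather than raised.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    state = initialize(config, rng)
    every = config.effective_record_every()
    rows = [_record(state, 0, 0)]
    extinct_step = None
    for step in range(1, config.steps + 1):
        state.step = step
        deaths = aging_phase(state)
        births, _ = reproduction_phase(state)
        if step % every == 0 or state.population_size == 0:
            rows.append(_record(state, births, deaths))
        if state.population_size == 0:
            state.extinct = True
            extinct_step = step
            break
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records["step"] = records["step"].astype(np.int64)
    return RunResult(config=config, seed=seed, records=records,
                     extinct=state.extinct, extinct_step=extinct_step,
                     state=state)


def run_replicates(config: ScenarioConfig,
                   base_seed: Optional[int] = None) -> ExperimentResult:
    """Run ``config.replicates`` replicates with seeds base_seed + r."""
    if base_seed is None:
        base_seed = config.seed
    seeds = [base_seed + r for r in range(config.replicates)]
    runs = [run(config, seed=s) for s in seeds]
    return ExperimentResult(config=config, seeds=seeds, runs=runs)
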