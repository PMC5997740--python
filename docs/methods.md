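# Methods

## Model

`pennaxy` implements a sexual, diploid Penna ageing model with explicit sex
chromosomes on a torus lattice.

**Genomes.** An individual is a set of chromosome pairs of bit strings;
bit 1 is a defective, fully recessive allele. Locus order encodes activation
time: a chromosome of `q·L` loci activates `q` loci per year, where
`L` (default 128) is both the basic chromosome length and the maximum age.
There are no back mutations, no beneficial mutations, no dominance other
than full recessivity, and no gene conversion.

**Life cycle.** One Monte Carlo step is one year. Ageing discloses the
homozygous defects of the loci activating at the new age; an individual dies
of "genetic death" when its cumulative disclosed count reaches `T`, or of
old age at `L`. Reproduction then iterates over reproductive-age females in
random order; each draws `Poisson(B)` conception attempts and stops at the
first success. An attempt is: partner search → free-cell search → gamete
formation → fertilization → prenatal check. The prenatal check counts
homozygous defects across the first `b` activation years (the housekeeping
loci, active from embryogenesis); the zygote is discarded if the count
reaches `T`. The newborn starts at age 0 with that prenatal count already on
its ledger, so ages `1..b−1` disclose nothing new and disclosure resumes at
age `b`.

**Gametes.** Each parental chromosome copy is replicated with mutation, the
two copies recombine, and one product is chosen uniformly. Mutation dialect
(configurable): the default draws one uniformly placed mutation per copy
with probability `M` (valid for `M ≤ 1`); a Poisson(`M`) dialect is
available. A mutation landing on an already-defective site is consumed
without effect. Crossover dialect: the default draws `Poisson(C)` distinct
intergenic boundaries (`C` is an expected crossover count, i.e. a map length
in Morgans); a single-Bernoulli dialect is available. Autosomes and the
female X–X pair use the table's `C`; the male X–Y pair uses the scenario's
rate: 0 (`off`), the table rate (`on`), or the father's heritable value
(`evolving`).

**Sex and the X–Y modifier.** The product of a male sex-pair meiosis that
retains the chromosome start of the parental Y is labelled Y (there is no
explicit sex-determining locus; position 0 is never exchanged because
crossover boundaries lie strictly between loci, so the label is stable). A
zygote receiving a Y-labelled paternal gamete is male. In the `evolving`
regime a son inherits his father's X–Y recombination value shifted by
±`modifier_step` (default 0.05, equiprobable, clamped at 0); 0 is absorbing.
The initial value is the X pair's `C`, and reported trajectories are
normalized by it.

**Space.** The lattice is a `side × side` torus, one individual per cell;
distance is toroidal Chebyshev, so a range `D` is a square neighborhood of
half-width `D`, and ranges with `2D+1 ≥ side` cover the whole torus.
Partner choice among eligible males and cell choice among free cells are
uniform; the child's range is centred on the mother. Individuals never move.
Population size is bounded by the lattice itself — there is no Verhulst
factor. Panmictic mode replaces both neighborhoods by the whole population
and the lattice by a fixed pool of `side²` slots. In faithful mating, an
unpaired female bonds to a uniformly chosen unpaired eligible male within
`D_p` at first need; bonds last until a partner dies, and widows may
re-pair. In unfaithful mating a partner is redrawn on every attempt and one
male may serve several females per step.

**Scheduling.** All deaths are applied before any reproduction within a
step; newborns are placed immediately (they appear in that step's
statistics) and begin ageing the next step. Extinction terminates a run
early and is flagged on the result, not raised: faithful scenarios at `T=3`
are expected to die out, which is why the faithful presets use `T=20`.

## Parameters

| symbol | field | default | meaning |
|---|---|---|---|
| L | `basic_length` | 128 | basic chromosome length = maximum age (years) |
| b | `birth_check` | 75 | activation years checked prenatally |
| R | `repro_age` | 105 | minimum reproductive age |
| T | `death_threshold` | 3 (unfaithful) / 20 (faithful) | homozygous defects causing death |
| B | `attempts_mean` | 8 | mean conception attempts per female per step |
| D_p | `partner_range` | 6 | partner search range (cells) |
| D_c | `child_range` | 6 | child placement range (cells) |
| — | `lattice_side` | 128 | torus side |
| — | `steps` | 10⁶ | Monte Carlo steps |
| — | `replicates` | 50 | replicate runs, seeds `seed + r` |
| — | `modifier_step` | 0.05 | X–Y modifier mutation size |
| M, C | chromosome table | see below | per-pair mutation / crossover means |

Scenario presets `RU, RF, NU, NF, EU, EF` combine
(on / off / evolving) × (unfaithful, T=3 / faithful, T=20) at full scale;
`DESK-*` variants swap in the desk-scale profile below.

## Chromosome tables

**`human23.tsv`** (default for full-scale presets): 23 pairs whose lengths
are approximate human protein-coding gene counts rounded to multiples of
128 (19,968 loci in total); per-copy mutation means proportional to length
and summing, over both copies of all pairs, to one new mutation per diploid
genome per generation; crossover means are sex-averaged genetic-map lengths
in Morgans. The X pair (896 loci, C = 1.8) is compared against the 10th
autosome (length-comparable, C = 1.81). The table is a documented
approximation and can be replaced by any strict five-column TSV.

**Toy table** (`toy3`, desk-scale presets): three pairs — autosome `A1`,
comparator `A2` and sex pair `XY` — each of 128 loci (one per year), each
with `C = 1.0` (one crossover per bivalent per meiosis, the biological
minimum for proper segregation) and `M = 0.75` per copy per replication.
The mutation mean is the deliberate time compression of the desk profile: a
desk run spans only ~190 generations, and at the full-scale genome-wide
rate of ~1 mutation per generation such a run never leaves its initial
neutral transient. `M = 0.75` (4.5 per diploid genome per generation, the
top of the empirical human range) brings mutation–selection balance, and
with it the ratchet and purification dynamics of interest, inside the run.
Because load comparisons use per-copy mean defective *fractions*, ratios
remain comparable across tables.

## Desk-scale study conditions

The behavioural test tier and `scripts/acceptance.py` run every scenario at
a fixed desk profile: 32 × 32 lattice, toy table, 20,000 steps,
5 replicates, recording every step. These sizes keep a full scenario under
two minutes per replicate on one CPU while leaving cohort sizes (~1,000
individuals, ~60 adults per step) large enough for stable replicate-averaged
ratios.

What the desk conditions do reproduce:

* `RU`: X/10, Y/X and M/F all near 1 — recombination keeps the sex
  chromosomes autosome-like.
* `NU`: near-linear rise of Y/X (slope ≈ 16 per 100,000 steps, R² ≈ 0.98),
  Y/X well above 2 by 20,000 steps, X/10 dipping below 1 (X purification),
  and a clear female excess among adults (pooled M/F ≈ 0.6) after a brief
  male-biased phase driven by the initially lower X–Y allele-sharing of male
  zygotes.
* `EF`: Y/X near 1 and a normalized X–Y recombination rate that stays well
  away from the absorbing zero state.

Known desk-scale limitations (documented, not patched over):

* `NF` (faithful, recombination off): the Y-load ratio drifts to ~1.9–2.2
  by 20,000 steps instead of staying at 1. The faithful protection of the Y
  rests on a large Y-lineage effective size and weak per-locus selection;
  with ~500 males and time-compressed mutation pressure, ratchet clicks
  remain visible. At the uncompressed mutation rate the protection holds,
  but then no scenario shows any differentiation within 20,000 steps — the
  two regimes cannot be captured simultaneously at this scale.
* `EU` (evolving, unfaithful): spontaneous suppression of X–Y recombination
  does not occur within 20,000 desk steps (nor by 80,000 in pilots). In the
  compressed high-load regime recombination is strongly purging — desk
  populations with `C < 1` go extinct — so selection does not push the
  modifier towards zero; its full-scale counterpart operates at 16× the
  population and 1/60 the per-locus load. The modifier machinery itself
  (father-to-son inheritance, ±0.05 walk, absorption at 0) is verified
  directly against a gambler's-ruin oracle.

Passing desk-scale tests therefore demonstrate the implementation's
correctness and the headline unfaithful-mating phenomenology, not a
quantitative miniature of full-scale runs.

## Statistics and conventions

* Cohorts: newborns are age 0 (born this step); youths `0 < age < R`;
  adults `age ≥ R`.
* X pool: maternal sex-pair copies of everyone plus paternal copies of
  females; Y pool: paternal copies of males. Load ratios divide per-copy
  mean defective fractions; undefined ratios (empty pool or zero
  denominator) are emitted as missing values, never 0.
* Per-step M/F ratios of small cohorts are upward-biased (Jensen); analyses
  that need a window-level sex ratio pool the male/female counts first
  (`males_*` and `n_*` record columns).
* `yx_slope` is ordinary least squares of Y/X against step, rescaled to
  per-100,000-steps; `suppression_step` is the first recorded step with the
  population-mean normalized rate exactly 0 (absorption makes later
  re-emergence impossible; if observed it warns).
* Jukes–Cantor: `K = −(3/4)·ln(1 − (4/3)p)` for `0 ≤ p < 0.75`; a domain
  error otherwise.
* Recording cadence: every step for runs ≤ 100,000 steps, every 100th
  beyond, overridable via `record_every`. Replicate aggregation is the
  step-wise arithmetic mean over replicates (missing values skipped).
* Determinism: one `numpy` PCG64 generator per replicate drives every draw
  (including inside the jitted kernels); replicate `r` uses seed
  `base + r`. Identical configuration and seed reproduce trajectories bit
  for bit; outputs are independent of how replicates are scheduled because
  each owns its generator.

## Numerical / implementation notes

* Genomes are dense `uint8` arrays; per-activation-year homozygous-defect
  tables and per-copy defect counts are computed once at birth (bits are
  immutable during life), making ageing and per-step statistics O(1) per
  individual. Hot loops are numba-jitted; public operations wrap the same
  kernels, and tests compare them against naive per-bit Python loops.
* Crossover points are sampled as distinct intergenic boundaries by
  rejection (counts are tiny relative to chromosome length) and applied as
  alternating segment swaps; a Poisson draw exceeding `length − 1` is
  clamped.
* Neighborhood tables are precomputed per (side, range) with wraparound
  duplicates merged; ranges covering the torus switch to full scans, which
  is also how panmictic mode is implemented.
* The comparator autosome for X/10 is configurable (`comparator`), and may
  not be the sex pair.
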