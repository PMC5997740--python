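"""Engine: initialization, ageing/death rules, reproduction, modifier walk,
determinism, capacity and extinction handling."""

import numpy as np
import pytest

import pennaxy as px
from pennaxy import engine
from pennaxy.errors import ConfigurationError, InvariantViolation


def desk_config(**kw):
    kw.setdefault("chromosome_table", "toy3")
    kw.setdefault("comparator", "A2")
    cfg = px.ScenarioConfig(**kw)
    cfg.validate()
    return cfg


# ------------------------------------------------------------ initialize

def test_initialize_fills_lattice_with_clean_individuals():
    cfg = desk_config(lattice_side=8, steps=10, replicates=1)
    st = engine.initialize(cfg, np.random.default_rng(3))
    assert st.population_size == 64
    assert st.genome.sum() == 0
    assert st.cum.sum() == 0
    assert np.all((st.age >= 0) & (st.age < cfg.basic_length))
    assert np.all(st.partner == -1)
    males = st.sex == 1
    assert np.all(st.xymod[males] == st.initial_xy_rate)


def test_initialize_sex_is_unbiased():
    """Empirical male fraction over 50 initializations within 3 binomial SE."""
    cfg = desk_config(lattice_side=64, steps=1, replicates=1)
    total = males = 0
    for seed in range(50):
        st = engine.initialize(cfg, np.random.default_rng(seed))
        males += int((st.sex == 1).sum())
        total += st.ncells
    se = np.sqrt(0.25 / total)
    assert abs(males / total - 0.5) < 3 * se


def test_initialize_is_deterministic():
    cfg = desk_config(lattice_side=8, steps=1, replicates=1)
    a = engine.initialize(cfg, np.random.default_rng(11))
    b = engine.initialize(cfg, np.random.default_rng(11))
    assert np.array_equal(a.sex, b.sex) and np.array_equal(a.age, b.age)


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        desk_config(birth_check=130)  # b > L
    with pytest.raises(ConfigurationError):
        desk_config(birth_check=110, repro_age=105)  # b >= R
    with pytest.raises(ConfigurationError):
        desk_config(death_threshold=0)
    with pytest.raises(ConfigurationError):
        desk_config(comparator="XY")  # comparator must not be the sex pair
    with pytest.raises(ConfigurationError):
        px.preset_config("NOPE")


def test_presets_match_scenario_grid():
    expect = {
        "RU": ("unfaithful", "on", 3), "RF": ("faithful", "on", 20),
        "NU": ("unfaithful", "off", 3), "NF": ("faithful", "off", 20),
        "EU": ("unfaithful", "evolving", 3), "EF": ("faithful", "evolving", 20),
    }
    for name, (mating, regime, T) in expect.items():
        for prefix, side in (("", 128), ("DESK-", 32)):
            cfg = px.preset_config(prefix + name)
            assert (cfg.mating, cfg.xy_regime, cfg.death_threshold) == (mating, regime, T)
            assert cfg.lattice_side == side
    full = px.preset_config("RU")
    assert full.steps == 1_000_000 and full.replicates == 50
    desk = px.preset_config("DESK-RU")
    assert desk.steps == 20_000 and desk.replicates == 5


# ----------------------------------------------------------------- ageing

def test_clean_genomes_survive_to_maximum_age():
    cfg = desk_config(lattice_side=4, replicates=1)
    st = engine.initialize(cfg, np.random.default_rng(0))
    st.age[:] = 0
    for year in range(1, cfg.basic_length):
        assert engine.aging_phase(st) == 0, f"death before age L at year {year}"
    assert engine.aging_phase(st) == 16  # everyone reaches L together


def test_death_at_exact_threshold_age():
    """T defects all activating in year a kill the carrier exactly at age a."""
    cfg = desk_config(lattice_side=4, replicates=1, death_threshold=3)
    st = engine.initialize(cfg, np.random.default_rng(0))
    a = 80  # past the prenatal window
    st.age[:] = 0
    st.cum[:] = 0
    # cell 0: both alleles defective at position a of all three chromosomes
    for start in st.table.starts:
        st.genome[0, :, start + a] = 1
    st.refresh_derived()
    for year in range(1, a):
        assert engine.aging_phase(st) == 0
    assert engine.aging_phase(st) == 1
    assert not st.occ[0]


def test_lifespan_matches_per_year_hand_simulation():
    """Engine deaths reproduce a step-by-step Python simulation for 100
    individuals with random defect patterns."""
    cfg = desk_config(lattice_side=10, replicates=1, death_threshold=3)
    rng = np.random.default_rng(5)
    st = engine.initialize(cfg, rng)
    st.age[:] = 0
    st.genome[:] = (rng.random(st.genome.shape) < 0.08).astype(np.uint8)
    st.refresh_derived()
    L, b, T = cfg.basic_length, cfg.birth_check, cfg.death_threshold
    # the prenatal count is carried from birth (housekeeping loci already active)
    st.cum[:] = st.year_def[:, :b].sum(axis=1)
    alive0 = st.cum < T  # embryos over threshold would never have been born
    st.occ[:] = alive0

    expected = {}
    for i in range(st.ncells):
        if not alive0[i]:
            continue
        cum = int(st.cum[i])
        span = L
        for age in range(1, L):
            if age >= b:
                cum += int(st.year_def[i, age])
            if cum >= T:
                span = age
                break
        expected[i] = span

    death_year = {}
    for year in range(1, L + 1):
        before = st.occ.copy()
        engine.aging_phase(st)
        for i in np.flatnonzero(before & ~st.occ):
            death_year[int(i)] = year
    assert death_year == expected


# ------------------------------------------------------------- modifier

def test_modifier_zero_is_absorbing(rng):
    assert all(px.mutate_modifier(0.0, 0.05, rng) == 0.0 for _ in range(1000))


def test_modifier_step_and_clamp(rng):
    vals = {px.mutate_modifier(0.03, 0.05, rng) for _ in range(500)}
    assert vals == {0.0, 0.08}
    ups = sum(px.mutate_modifier(1.0, 0.05, rng) > 1.0 for _ in range(2000))
    assert abs(ups / 2000 - 0.5) < 3 * np.sqrt(0.25 / 2000)


def test_modifier_rejects_negative(rng):
    with pytest.raises(InvariantViolation):
        px.mutate_modifier(-0.1, 0.05, rng)


# ---------------------------------------------------------- reproduction

def test_attempt_budget_is_poisson_with_mean_b():
    """When every attempt fails, attempts per female per step average B."""
    cfg = desk_config(lattice_side=16, replicates=1, attempts_mean=8.0)
    st = engine.initialize(cfg, np.random.default_rng(9))
    st.sex[:] = 0          # no males -> every attempt fails at partner search
    st.age[:] = cfg.repro_age
    females = st.ncells
    total_attempts = 0
    steps = 20
    for _ in range(steps):
        births, attempts = engine.reproduction_phase(st)
        assert births == 0
        total_attempts += attempts
    n = females * steps
    se = np.sqrt(cfg.attempts_mean / n)
    assert abs(total_attempts / n - cfg.attempts_mean) < 3 * se


def test_no_free_cell_means_no_births():
    cfg = desk_config(lattice_side=6, replicates=1)
    st = engine.initialize(cfg, np.random.default_rng(2))
    st.age[:] = cfg.repro_age  # full lattice, everyone adult
    births, attempts = engine.reproduction_phase(st)
    assert births == 0 and attempts > 0


def test_prenatal_check_kills_engineered_homozygotes():
    """Parents homozygous-defective at an early locus with T=1 never conceive."""
    cfg = desk_config(lattice_side=6, replicates=1, death_threshold=1)
    st = engine.initialize(cfg, np.random.default_rng(4))
    st.age[:] = cfg.repro_age
    st.genome[:, :, 10] = 1  # year-10 locus (< b) defective on every copy
    st.refresh_derived()
    st.occ[5] = False  # one vacancy so placement cannot be the bottleneck
    for _ in range(5):
        births, _ = engine.reproduction_phase(st)
        assert births == 0


def test_sons_inherit_fathers_modifier_with_one_step():
    cfg = desk_config(lattice_side=8, replicates=1, xy_regime="evolving",
                      death_threshold=20)
    st = engine.initialize(cfg, np.random.default_rng(6))
    st.age[:] = cfg.repro_age
    st.xymod[st.sex == 1] = 0.4
    st.occ[st.ncells // 2:] = False  # room for children
    engine.reproduction_phase(st)
    newborn = st.occ & (st.age == 0)
    sons = newborn & (st.sex == 1)
    daughters = newborn & (st.sex == 0)
    assert newborn.sum() > 0
    assert set(np.round(st.xymod[sons], 10)) <= {0.35, 0.45}
    assert np.all(st.xymod[daughters] == 0.0)


# ------------------------------------------------------------------ runs

def test_zero_steps_yields_only_initial_record():
    cfg = desk_config(lattice_side=6, steps=0, replicates=1)
    res = px.run(cfg, seed=1)
    assert len(res.records) == 1 and res.records["step"].iloc[0] == 0


def test_run_is_deterministic_and_seed_sensitive():
    cfg = desk_config(lattice_side=12, steps=150, replicates=1)
    a = px.run(cfg, seed=77)
    b = px.run(cfg, seed=77)
    c = px.run(cfg, seed=78)
    assert a.records.equals(b.records)
    assert np.array_equal(a.state.genome, b.state.genome)
    assert np.array_equal(a.state.age, b.state.age)
    assert not a.records.equals(c.records)


def test_capacity_invariant_sweep():
    """2,000 steps on 16x16 keep occupancy within the lattice capacity."""
    cfg = desk_config(lattice_side=16, steps=2000, replicates=1)
    res = px.run(cfg, seed=3)
    assert not res.extinct
    assert (res.records["pop"] <= 256).all()
    assert (res.records["pop"] > 0).all()


def test_extinction_is_flagged_not_raised():
    """With no conception attempts the population ages to extinction."""
    cfg = desk_config(lattice_side=6, steps=400, replicates=1, attempts_mean=0.0)
    res = px.run(cfg, seed=1)
    assert res.extinct
    assert res.extinct_step is not None and res.extinct_step <= 128
    assert res.records["pop"].iloc[-1] == 0


def test_replicates_average_and_seed_policy():
    cfg = desk_config(lattice_side=8, steps=30, replicates=3, seed=100)
    exp = px.run_replicates(cfg)
    assert exp.seeds == [100, 101, 102]
    assert len(exp.runs) == 3
    # aggregate pop at step 0 equals the mean of full lattices
    assert exp.aggregate["pop"].iloc[0] == 64.0
    again = px.run_replicates(cfg)
    assert exp.aggregate.equals(again.aggregate)


def test_panmictic_mode_runs_and_respects_ceiling():
    cfg = desk_config(lattice_side=12, steps=300, replicates=1, panmictic=True)
    res = px.run(cfg, seed=2)
    assert (res.records["pop"] <= 144).all()
    assert not res.extinct
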