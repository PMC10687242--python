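"""Synthetic phage/antibiotic microcosm experiments.

Emulates a 3 x 3 factorial invasion experiment on a planktonic lake
community: an unsuccessful bacterial invader added at no/low/high density,
a single dose of either a host-specific lytic phage or a broad-spectrum
antibiotic applied one hour later, daily 11% medium exchange, and community
observation by amplicon sequencing (multinomial reads) and flow cytometry
(lognormal-noise density readout) on a fixed sampling grid.

The within-microcosm dynamics are a deliberately small mechanistic model:

* Monod growth on a single dissolved-organic-matter (DOM) pool, with cell
  yield 1 (resource is measured in cell equivalents per mL);
* antibiotic kill at a class-dependent rate (susceptibility is assigned
  from the taxon's class label);
* lytic phage infection of the invader only (adsorption/burst/decay);
* background mortality;
* lysed and dead cells recycle into the DOM pool at ``dom_yield``
  (< 1, so recycling is dissipative) — this is what produces the
  feast-famine density response when a large invader population collapses;
* demographic drift as Poisson resampling of each population at an
  effective volume ``drift_volume`` (volume -> infinity recovers the
  deterministic ODE).

Integration is fixed-step forward Euler with all fluxes capped at the
available pool so no state becomes negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .tables import CountTable, DensitySeries, SampleFrame

__all__ = [
    "SimulationConfig",
    "MicrocosmState",
    "TaxonSet",
    "ExperimentBundle",
    "moi",
    "round_moi",
    "step_dynamics",
    "apply_dilution",
    "observe_reads",
    "observe_density",
    "simulate_experiment",
    "selection_regime_config",
    "drift_regime_config",
    "planted_effect_tables",
]

# Small fixed taxonomy ontology; class labels drive antibiotic susceptibility
# and life strategy.  Opportunists (r-strategists: Pseudomonas, Aquirufa-type
# debris consumers) are rare under oligotrophic conditions but respond fast to
# a DOM pulse and crash fast once it is gone.
# (class, order, genus, susceptible_to_antibiotic, opportunist)
_ONTOLOGY = [
    ("Betaproteobacteria", "Burkholderiales", "Limnohabitans", True, False),
    ("Betaproteobacteria", "Burkholderiales", "Polynucleobacter", True, False),
    ("Gammaproteobacteria", "Pseudomonadales", "Pseudomonas", False, True),
    ("Bacteroidia", "Cytophagales", "Aquirufa", False, True),
    ("Alphaproteobacteria", "Sphingomonadales", "Sphingomonas", True, False),
    ("Actinomycetia", "Frankiales", "Candidatus Planktophila", True, False),
    ("Bacteroidia", "Flavobacteriales", "Fluviicola", True, False),
]
_INVADER_TAXONOMY = (
    "Bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;Flavobacteriaceae;Flavobacterium"
)


def moi(phage_conc: float, host_conc: float) -> float:
    """Multiplicity of infection: phage particles added per host cell present.

    Parameters are concentrations in the same volume (PFU/mL and cells/mL).
    """
    if host_conc <= 0:
        raise ValueError(f"host concentration must be positive, got {host_conc}")
    if phage_conc < 0:
        raise ValueError(f"phage concentration must be non-negative, got {phage_conc}")
    return phage_conc / host_conc


def round_moi(value: float) -> float:
    """Round an MOI to one decimal, as typically reported."""
    return round(value, 1)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic microcosm experiment.

    Defaults encode the study conditions: a resident lake community at
    6.25e5 cells/mL, invader additions of 0 / 1.38e5 / 1.07e6 cells/mL,
    phage doses of 3.12e5 (low-invader) and 3.12e6 PFU/mL (high-invader and
    uninvaded groups), 11% daily medium exchange, 5 replicates of each of
    the 9 treatment x invader groups, 7 days with community sampling at
    days 0/1/3/7 and daily density readings.
    """

    n_taxa: int = 30
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.5
    resident_density: float = 6.25e5
    invader_levels: dict = field(
        default_factory=lambda: {"no": 0.0, "low": 1.38e5, "high": 1.07e6}
    )
    treatments: tuple = ("none", "phage", "antibiotic")
    n_replicates: int = 5
    days_simulated: int = 7
    sampling_days: tuple = (0, 1, 3, 7)
    dt: float = 0.05
    dilution_fraction: float = 0.11
    phage_dose_low: float = 3.12e5
    phage_dose_high: float = 3.12e6
    adsorption_rate: float = 1.5e-6  # mL/(cell day)
    burst_size: float = 50.0
    phage_decay: float = 0.5  # 1/day
    antibiotic_kill: float = 1.5  # 1/day on susceptible taxa
    antibiotic_decay: float = 0.0  # 1/day on activity A
    dom_yield: float = 0.9  # resource units released per lysed/dead cell
    monod_mumax_mean: float = 0.9  # 1/day, bulk (oligotroph) taxa
    monod_mumax_sd: float = 0.4
    mumax_values: tuple | None = None  # explicit per-resident rates (overrides draw)
    monod_K: float = 2.0e5  # resource units/mL, opportunist half-saturation
    monod_K_oligotroph: float = 5.0e6  # bulk taxa barely respond to DOM pulses
    opportunist_mumax_boost: float = 3.0  # growth-rate multiplier for opportunists
    opportunist_death_mult: float = 4.0  # turnover multiplier for opportunists
    opportunist_init_downweight: float = 0.02  # opportunists start rare
    invader_fitness_penalty: float = 1.0  # fraction of mumax removed from invader
    invader_death_mult: float = 5.0  # unsuccessful invader dies fast
    death_rate: float = 0.12  # 1/day background mortality, bulk taxa
    r_init: float = 5.0e4  # initial DOM pool, cell equivalents/mL
    r_medium: float = 5.0e4  # DOM in exchange medium
    drift_volume: float = 1.0  # mL; Poisson resampling volume (inf = off)
    init_volume: float = 5.0e-4  # mL; effective inoculum bottleneck volume
    read_depth_mean: float = 5.0e4
    read_depth_dispersion: float = 25.0  # negative-binomial size parameter
    density_cv: float = 0.1  # lognormal sigma on cytometry readout
    seed: int = 3003

    def validate(self) -> None:
        problems = []
        nonneg = [
            "resident_density", "phage_dose_low", "phage_dose_high",
            "adsorption_rate", "burst_size", "phage_decay", "antibiotic_kill",
            "antibiotic_decay", "dom_yield", "monod_mumax_mean", "monod_mumax_sd",
            "monod_K", "monod_K_oligotroph", "opportunist_mumax_boost",
            "opportunist_death_mult", "opportunist_init_downweight",
            "invader_death_mult", "death_rate", "r_init", "r_medium",
            "read_depth_mean", "density_cv",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not (0 < self.dilution_fraction < 1):
            problems.append("dilution_fraction must be in (0, 1)")
        if self.dt <= 0 or abs(round(1.0 / self.dt) - 1.0 / self.dt) > 1e-9:
            problems.append("dt must be positive and divide 1.0")
        if self.n_taxa < 1:
            problems.append("n_taxa must be >= 1")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if self.invader_levels.get("no", None) != 0.0:
            problems.append("invader_levels['no'] must be exactly 0")
        if any(v < 0 for v in self.invader_levels.values()):
            problems.append("invader levels must be >= 0")
        unknown = set(self.treatments) - {"none", "phage", "antibiotic"}
        if unknown:
            problems.append(f"unknown treatments {sorted(unknown)}")
        if not (0 <= self.invader_fitness_penalty <= 1):
            problems.append("invader_fitness_penalty must be in [0, 1]")
        if self.drift_volume <= 0 or self.init_volume <= 0:
            problems.append("drift_volume and init_volume must be positive (inf allowed)")
        if max(self.sampling_days) > self.days_simulated:
            problems.append("sampling_days exceed days_simulated")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("treatments", "sampling_days"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["treatments"] = list(self.treatments)
        data["sampling_days"] = list(self.sampling_days)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class MicrocosmState:
    """State vector of one microcosm: time, populations, phage, DOM, antibiotic."""

    t: float
    N: np.ndarray  # cells/mL; index 0 = invader
    P: float = 0.0  # PFU/mL
    R: float = 0.0  # resource units/mL
    A: float = 0.0  # antibiotic activity multiplier

    def copy(self) -> "MicrocosmState":
        return MicrocosmState(self.t, self.N.copy(), self.P, self.R, self.A)

    @property
    def total(self) -> float:
        return float(self.N.sum())


@dataclass
class TaxonSet:
    """Per-taxon parameters drawn once per experiment (taxon 0 = invader)."""

    names: list
    taxonomy: pd.Series
    mumax: np.ndarray
    K: np.ndarray
    death: np.ndarray  # 1/day background mortality per taxon
    susceptible: np.ndarray  # bool; antibiotic kills these
    opportunist: np.ndarray  # bool; r-strategists (fast growth, fast crash)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.names,
                "taxonomy": self.taxonomy.to_numpy(),
                "mumax": self.mumax,
                "K": self.K,
                "death": self.death,
                "susceptible": self.susceptible,
                "opportunist": self.opportunist,
            }
        )


@dataclass
class ExperimentBundle:
    """Everything a downstream analysis needs, plus the generating truth."""

    counts: CountTable
    samples: SampleFrame
    density: DensitySeries
    truth: dict


def make_taxa(config: SimulationConfig, rng: np.random.Generator) -> TaxonSet:
    """Draw per-taxon growth parameters and assign ontology labels.

    Taxon 0 is the invader (growth reduced by ``invader_fitness_penalty``,
    susceptible to the antibiotic and the only phage host); residents cycle
    through a small fixed ontology whose class labels set antibiotic
    susceptibility.
    """
    n = config.n_taxa + 1
    names = ["ASV1"] + [f"ASV{i + 1}" for i in range(1, n)]
    lineages = [_INVADER_TAXONOMY]
    susceptible = [True]
    opportunist = [False]
    for i in range(config.n_taxa):
        cls, order, genus, susc, opp = _ONTOLOGY[i % len(_ONTOLOGY)]
        lineages.append(f"Bacteria;-;{cls};{order};-;{genus}")
        susceptible.append(susc)
        opportunist.append(opp)
    opp_mask = np.array(opportunist, dtype=bool)
    mumax = rng.normal(config.monod_mumax_mean, config.monod_mumax_sd, size=n)
    mumax = np.clip(mumax, 0.05 * config.monod_mumax_mean, None)
    mumax[opp_mask] *= config.opportunist_mumax_boost
    if config.mumax_values is not None:
        if len(config.mumax_values) != config.n_taxa:
            raise ValueError("mumax_values must list one rate per resident taxon")
        mumax[1:] = np.asarray(config.mumax_values, dtype=float)
    mumax[0] = config.monod_mumax_mean * (1.0 - config.invader_fitness_penalty)
    K = np.full(n, config.monod_K_oligotroph)
    K[opp_mask] = config.monod_K
    K[0] = config.monod_K
    death = np.full(n, config.death_rate)
    death[opp_mask] *= config.opportunist_death_mult
    death[0] = config.death_rate * config.invader_death_mult
    return TaxonSet(
        names=names,
        taxonomy=pd.Series(lineages, index=names),
        mumax=mumax,
        K=K,
        death=death,
        susceptible=np.array(susceptible, dtype=bool),
        opportunist=opp_mask,
    )


def step_dynamics(
    state: MicrocosmState,
    config: SimulationConfig,
    taxa: TaxonSet,
    dt: float,
    rng: np.random.Generator | None = None,
) -> MicrocosmState:
    """Advance one Euler step of length ``dt`` days.

    Update order: Monod growth (consuming DOM), antibiotic kill of
    susceptible taxa, phage infection of the invader, background death,
    DOM release from all lysed/dead cells, then demographic drift by
    Poisson resampling.  Every flux is capped at its source pool, so no
    field goes negative.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = state.copy()
    N = s.N

    # (1) Monod growth, yield 1 cell per resource unit, capped by the pool
    growth = taxa.mumax * s.R / (taxa.K + s.R) * N * dt
    demand = growth.sum()
    if demand > s.R > 0:
        growth *= s.R / demand
    elif s.R <= 0:
        growth[:] = 0.0
    N += growth
    s.R = max(s.R - growth.sum(), 0.0)

    # (2) antibiotic kill on susceptible taxa
    killed = np.zeros_like(N)
    if s.A > 0:
        killed[taxa.susceptible] = np.minimum(
            config.antibiotic_kill * s.A * N[taxa.susceptible] * dt,
            N[taxa.susceptible],
        )
        N -= killed
        s.A *= math.exp(-config.antibiotic_decay * dt)

    # (3) phage infection of the host (taxon 0)
    lysed = 0.0
    if s.P > 0 and N[0] > 0:
        lysed = min(config.adsorption_rate * s.P * N[0] * dt, N[0])
        N[0] -= lysed
    s.P += config.burst_size * lysed
    s.P -= min(config.phage_decay * s.P * dt, s.P)

    # (4) background death (per-taxon: opportunists and the invader turn
    # over faster than the oligotrophic bulk)
    dead = np.minimum(taxa.death * N * dt, N)
    N -= dead

    # (5) DOM release from lysed and dead cells
    s.R += config.dom_yield * (killed.sum() + lysed + dead.sum())

    # (6) demographic drift
    if np.isfinite(config.drift_volume):
        if rng is None:
            raise ValueError("rng required when drift_volume is finite")
        V = config.drift_volume
        N[:] = rng.poisson(np.maximum(N, 0.0) * V) / V

    np.maximum(N, 0.0, out=N)
    s.t = state.t + dt
    return s


def apply_dilution(state: MicrocosmState, config: SimulationConfig) -> MicrocosmState:
    """Daily medium exchange: replace ``dilution_fraction`` of the volume.

    Cells, phage and antibiotic are diluted; the resource pool relaxes
    toward the medium's DOM concentration.
    """
    f = config.dilution_fraction
    s = state.copy()
    s.N = s.N * (1.0 - f)
    s.P *= 1.0 - f
    s.A *= 1.0 - f
    s.R = (1.0 - f) * s.R + f * config.r_medium
    return s


def observe_reads(
    state: MicrocosmState, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequence the community: multinomial reads proportional to density."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    total = state.N.sum()
    if total <= 0:
        raise ValueError("cannot sequence an all-zero community")
    return rng.multinomial(depth, state.N / total)


def observe_density(
    state: MicrocosmState, config: SimulationConfig, rng: np.random.Generator
) -> float:
    """Flow-cytometry readout: total density with lognormal noise."""
    total = state.N.sum()
    if total <= 0:
        return 0.0
    if config.density_cv == 0:
        return float(total)
    return float(total * math.exp(rng.normal(0.0, config.density_cv)))


def _phage_dose(config: SimulationConfig, invader_level: str) -> float:
    # the uninvaded phage group receives the high dose, matching the design
    # where the no-host control is dosed at the high-invader level
    return config.phage_dose_low if invader_level == "low" else config.phage_dose_high


def _sample_depth(config: SimulationConfig, rng: np.random.Generator) -> int:
    k = config.read_depth_dispersion
    m = config.read_depth_mean
    if k <= 0 or not np.isfinite(k):
        return max(int(round(m)), 1)
    p = k / (k + m)
    return max(int(rng.negative_binomial(k, p)), 1)


def _resident_relative(
    config: SimulationConfig, taxa: TaxonSet, rng: np.random.Generator
) -> np.ndarray:
    """Initial resident relative abundances (lognormal ranks, rare opportunists)."""
    rel = rng.lognormal(
        config.abundance_lognormal_mu, config.abundance_lognormal_sigma, config.n_taxa
    )
    rel[taxa.opportunist[1:]] *= config.opportunist_init_downweight
    return rel / rel.sum()


def _initial_state(
    config: SimulationConfig,
    resident_rel: np.ndarray,
    invader_density: float,
    rng: np.random.Generator,
) -> MicrocosmState:
    N = np.empty(config.n_taxa + 1)
    N[0] = invader_density
    N[1:] = resident_rel * config.resident_density
    if np.isfinite(config.init_volume):
        V = config.init_volume
        N = rng.poisson(N * V) / V
    return MicrocosmState(t=0.0, N=N, P=0.0, R=config.r_init, A=0.0)


def _run_microcosm(
    config: SimulationConfig,
    taxa: TaxonSet,
    state: MicrocosmState,
    treatment: str,
    invader_level: str,
    rng: np.random.Generator | None,
) -> dict:
    """Integrate one microcosm to ``days_simulated``; return daily states.

    The treatment pulse lands at the first step boundary after one hour
    (t = 1/24 day); sampling day d reflects the state just before that
    day's medium exchange.
    """
    dt = config.dt
    steps_per_day = int(round(1.0 / dt))
    treat_step = max(int(math.ceil((1.0 / 24.0) / dt)), 1)
    daily: dict[int, MicrocosmState] = {0: state.copy()}
    step = 0
    for day in range(config.days_simulated):
        for _ in range(steps_per_day):
            state = step_dynamics(state, config, taxa, dt, rng)
            step += 1
            if step == treat_step:
                if treatment == "phage":
                    state.P += _phage_dose(config, invader_level)
                elif treatment == "antibiotic":
                    state.A = 1.0
        daily[day + 1] = state.copy()
        state = apply_dilution(state, config)
    return daily


def simulate_experiment(config: SimulationConfig | None = None) -> ExperimentBundle:
    """Run the full factorial experiment and emit observed tables.

    Builds one seeded resident community, prepares a source bottle per
    invader level, splits each bottle into ``treatments x n_replicates``
    microcosms, doses phage or antibiotic one hour after invasion and
    integrates to ``days_simulated`` with daily 11% medium exchange.
    Community read counts are emitted on ``sampling_days``, density daily.
    A deterministic twin of every group (drift and observation noise off)
    is stored in ``truth`` together with the per-taxon parameters.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_taxa, s_resident, s_cells = root.spawn(3)
    taxa = make_taxa(config, np.random.default_rng(s_taxa))
    rng_res = np.random.default_rng(s_resident)
    resident_rel = _resident_relative(config, taxa, rng_res)

    invader_names = list(config.invader_levels)
    layout = [
        (inv, trt, rep)
        for inv in invader_names
        for trt in config.treatments
        for rep in range(1, config.n_replicates + 1)
    ]
    child_seeds = root.spawn(len(layout))

    count_rows, count_index = [], []
    meta_rows, dens_rows = [], []
    for (inv, trt, rep), seq in zip(layout, child_seeds):
        rng = np.random.default_rng(seq)
        m_id = f"{trt[0].upper()}{inv}_{rep}"
        state0 = _initial_state(config, resident_rel, config.invader_levels[inv], rng)
        drift_rng = rng if np.isfinite(config.drift_volume) else None
        daily = _run_microcosm(config, taxa, state0.copy(), trt, inv, drift_rng)
        for day in range(config.days_simulated + 1):
            dens_rows.append(
                {
                    "microcosm_id": m_id,
                    "day": day,
                    "total_density": observe_density(daily[day], config, rng),
                }
            )
        for day in config.sampling_days:
            sid = f"{m_id}_d{day}"
            depth = _sample_depth(config, rng)
            if daily[day].total <= 0:
                # a fully extinct community yields no amplicon library;
                # the sample is simply absent from the count table
                continue
            count_rows.append(observe_reads(daily[day], depth, rng))
            count_index.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "microcosm_id": m_id,
                    "replicate": rep,
                    "day": day,
                    "treatment": trt,
                    "invader_level": inv,
                }
            )

    counts = CountTable(
        pd.DataFrame(np.array(count_rows), index=count_index, columns=taxa.names),
        taxa.taxonomy.copy(),
    )
    samples = SampleFrame(pd.DataFrame(meta_rows))
    density = DensitySeries(pd.DataFrame(dens_rows))

    # deterministic twin per group for parameter-recovery tests
    det_cfg = replace(config, drift_volume=float("inf"), init_volume=float("inf"))
    truth_rows = []
    for inv in invader_names:
        for trt in config.treatments:
            st = _initial_state(det_cfg, resident_rel, config.invader_levels[inv], rng_res)
            daily = _run_microcosm(det_cfg, taxa, st, trt, inv, None)
            for day, s in daily.items():
                row = {"treatment": trt, "invader_level": inv, "day": day,
                       "total_density": s.total, "phage": s.P, "resource": s.R}
                row.update({name: n for name, n in zip(taxa.names, s.N)})
                truth_rows.append(row)
    truth = {
        "params": taxa.as_frame(),
        "trajectories": pd.DataFrame(truth_rows),
        "resident_relative": pd.Series(resident_rel, index=taxa.names[1:]),
    }
    return ExperimentBundle(counts, samples, density, truth)


# ---------------------------------------------------------------------------
# Benchmark regimes used by the assembly and differential-abundance suites
# ---------------------------------------------------------------------------


def selection_regime_config(seed: int, **overrides) -> SimulationConfig:
    """Single-group regime where deterministic selection dominates assembly.

    Replicate microcosms receive a finite inoculum (Poisson-sampled at
    ``init_volume``), so they start slightly different; growth-rate
    differences between taxa then drive every replicate toward the same
    competitive outcome, and replicate similarity rises over time.
    Demographic drift is switched off; the only ongoing noise is
    observational (reads and cytometry).
    """
    cfg = SimulationConfig(
        n_taxa=8,
        abundance_lognormal_sigma=0.5,
        treatments=("none",),
        invader_levels={"no": 0.0},
        n_replicates=5,
        monod_mumax_mean=2.5,
        monod_mumax_sd=1.2,
        mumax_values=(4.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
        monod_K=2e5,
        monod_K_oligotroph=2e5,
        opportunist_mumax_boost=1.0,
        opportunist_death_mult=1.0,
        opportunist_init_downweight=1.0,
        death_rate=0.8,
        r_init=2e6,
        r_medium=2e6,
        drift_volume=float("inf"),
        init_volume=2e-4,
        read_depth_mean=1e4,
        read_depth_dispersion=50.0,
        seed=seed,
    )
    return replace(cfg, **overrides)


def drift_regime_config(seed: int, **overrides) -> SimulationConfig:
    """Single-group neutral regime where demographic drift dominates.

    All taxa share one growth rate (no selection), replicates start from an
    identical inoculum, and a small effective volume makes the per-step
    Poisson resampling noisy, so replicate communities diverge by drift and
    replicate similarity falls over time.
    """
    cfg = SimulationConfig(
        n_taxa=15,
        treatments=("none",),
        invader_levels={"no": 0.0},
        n_replicates=5,
        monod_mumax_mean=1.2,
        monod_mumax_sd=0.0,
        monod_K=2e5,
        monod_K_oligotroph=2e5,
        opportunist_mumax_boost=1.0,
        opportunist_death_mult=1.0,
        opportunist_init_downweight=1.0,
        r_init=4e5,
        r_medium=4e5,
        drift_volume=2e-3,
        init_volume=float("inf"),
        read_depth_mean=1e4,
        read_depth_dispersion=50.0,
        seed=seed,
    )
    return replace(cfg, **overrides)


def planted_effect_tables(
    seed: int,
    n_bloom: int = 5,
    n_null: int = 20,
    fold: float = 10.0,
    n_per_group: int = 5,
    depth: int = 20000,
):
    """Planted differential-abundance benchmark.

    Simulates one untreated community, takes its final-day state, and builds
    two groups of replicate samples: controls observed as-is and a
    "treatment" group in which ``n_bloom`` randomly chosen resident taxa are
    multiplied ``fold``-fold before observation.  Returns
    ``(absolute_table, group_labels, planted_asv_ids)`` where the absolute
    table is reconstructed from reads and noisy density exactly as the real
    pipeline would.
    """
    from .tables import AbsoluteTable

    cfg = SimulationConfig(
        n_taxa=n_bloom + n_null,
        treatments=("none",),
        invader_levels={"no": 0.0},
        n_replicates=1,
        drift_volume=float("inf"),
        init_volume=float("inf"),
        seed=seed,
    )
    cfg.validate()
    root = np.random.SeedSequence(seed)
    s_taxa, s_resident, s_obs = root.spawn(3)
    taxa = make_taxa(cfg, np.random.default_rng(s_taxa))
    rng_res = np.random.default_rng(s_resident)
    rel = _resident_relative(cfg, taxa, rng_res)
    state0 = _initial_state(cfg, rel, 0.0, rng_res)
    daily = _run_microcosm(cfg, taxa, state0, "none", "no", None)
    base = daily[cfg.days_simulated]

    rng = np.random.default_rng(s_obs)
    resident_ids = taxa.names[1:]
    planted = sorted(rng.choice(len(resident_ids), size=n_bloom, replace=False))
    planted_ids = [resident_ids[i] for i in planted]
    rows, labels, index = [], [], []
    for g, scale_planted in (("control", 1.0), ("treatment", fold)):
        for rep in range(n_per_group):
            st = base.copy()
            for i in planted:
                st.N[i + 1] *= scale_planted
            reads = observe_reads(st, int(depth), rng)[1:]  # residents only
            dens = observe_density(st, cfg, rng)
            rows.append(reads / reads.sum() * dens)
            labels.append(g)
            index.append(f"{g}_{rep + 1}")
    values = pd.DataFrame(np.array(rows), index=index, columns=resident_ids)
    abs_table = AbsoluteTable(values, taxa.taxonomy.reindex(resident_ids))
    return abs_table, pd.Series(labels, index=index), planted_ids
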