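"""Forward-time individual-based simulation of the dominance-modifier network.

Discrete non-overlapping generations, Wright-Fisher-style soft selection
within each sex: every generation N/2 mothers and N/2 fathers are sampled
with replacement with probability proportional to viability, each
offspring receives one random haplotype per gene per parent (genes A and
B assort independently; the alpha-A and beta-B units are fully linked),
and sexes are assigned to keep N/2 of each.  Only the alpha and beta
binding sites mutate; the coding alleles and stimulus sequences are
fixed.  Fitness acts on the standardized network output ``phi`` through
a linear (default) or Gaussian sexually antagonistic scheme.

Populations are stored as packed numpy arrays (one row per individual,
females first) rather than lists of genotype objects, which keeps
replicate experiments on a single CPU tractable; ``Population.genotype``
recovers a per-individual :class:`~domrev.regnet.RegNetGenotype` when an
object view is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import regnet
from .regnet import (
    A1_RECOGNITION_SEQ,
    A2_RECOGNITION_SEQ,
    BETA_INIT_SEQ,
    FEMALE_D_SEQ,
    MALE_D_SEQ,
    NEUTRAL_ALPHA_SEQ,
    CodingAlleleA,
    HaplotypeA,
    HaplotypeB,
    RegNetGenotype,
    RegNetParams,
    RegulatoryStimulus,
    encode_seq,
)

__all__ = [
    "SimConfig",
    "Population",
    "Trajectory",
    "init_population",
    "mutate_sites",
    "individual_fitness",
    "population_fitness",
    "next_generation",
    "run_simulation",
    "retention_time",
    "ase_ratio_heterozygotes",
    "replicate_experiment",
    "sign_test",
    "ExperimentResult",
]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a simulation run.

    Defaults give a desk-scale run with visible dynamics: N = 500
    individuals, 8-nt binding sites, per-nucleotide mutation rate 1e-3 at
    the mutable sites, [D] = 1, stepwise dissociation multiplier
    k_step = 2 per mismatched nucleotide (a factor 256 across a fully
    mismatched site), TF concentration scale A_max = 30 (a matched
    activator occupies its beta site >90% of the time), symmetric linear
    selection s_f = s_m = 0.2 on phi, 5000 generations.
    """

    N: int = 500
    n_generations: int = 5000
    mu_site: float = 1e-3
    mu_site_alpha: float | None = None  # default: mu_site
    mu_site_beta: float | None = 0.0  # default: beta sites held fixed
    s_f: float = 0.2
    s_m: float = 0.2
    fitness_shape: str = "linear"  # 'linear' | 'gaussian'
    optimum_f: float = 1.0
    optimum_m: float = 0.0
    width: float = 0.5
    k_step: float = 2.0
    D_concentration: float = 1.0
    A_max: float = 30.0
    female_D_seq: str = FEMALE_D_SEQ
    male_D_seq: str = MALE_D_SEQ
    init_alpha_seq: str = NEUTRAL_ALPHA_SEQ
    init_beta_seq: str = BETA_INIT_SEQ
    a1_recognition_seq: str = A1_RECOGNITION_SEQ
    a2_recognition_seq: str = A2_RECOGNITION_SEQ
    effect_a1: float = regnet.EFFECT_A1
    effect_a2: float = regnet.EFFECT_A2
    basal_B: float = 0.5
    init_freq_A2: float = 0.5
    modifier_enabled: bool = True
    equalize_stimulus: bool = False
    seed: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.N <= 0 or self.N % 2:
            raise ValueError(f"N must be a positive even integer, got {self.N}")
        for name in ("mu_site", "init_freq_A2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("s_f", "s_m"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.fitness_shape not in ("linear", "gaussian"):
            raise ValueError(f"unknown fitness_shape {self.fitness_shape!r}")
        lens = {
            len(s)
            for s in (
                self.female_D_seq,
                self.male_D_seq,
                self.init_alpha_seq,
                self.init_beta_seq,
                self.a1_recognition_seq,
                self.a2_recognition_seq,
            )
        }
        if len(lens) != 1:
            raise ValueError("all sequences must share one site length")

    @property
    def L_site(self) -> int:
        return len(self.init_alpha_seq)

    @property
    def k_total(self) -> float:
        """Dissociation-constant base in mismatch-*proportion* units.

        ``k_step`` is the per-mismatched-nucleotide (stepwise) multiplier;
        the occupancy formula takes the mismatch proportion, so the
        equivalent base is ``k_step ** L_site``.
        """
        return self.k_step**self.L_site

    @property
    def mu_alpha(self) -> float:
        return self.mu_site if self.mu_site_alpha is None else self.mu_site_alpha

    @property
    def mu_beta(self) -> float:
        return self.mu_site if self.mu_site_beta is None else self.mu_site_beta

    @property
    def params(self) -> RegNetParams:
        return RegNetParams(
            k=self.k_total,
            D_concentration=self.D_concentration,
            A_max=self.A_max,
            basal_B=self.basal_B,
            max_effect=max(self.effect_a1, self.effect_a2),
        )

    @property
    def stimulus(self) -> RegulatoryStimulus:
        male = self.female_D_seq if self.equalize_stimulus else self.male_D_seq
        return RegulatoryStimulus(self.female_D_seq, male, self.D_concentration)

    def with_overrides(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class Population:
    """Packed array representation of N diploid individuals.

    Rows 0..N/2-1 are females, the rest males.  ``alpha`` and ``beta``
    are (N, 2, L) uint8 code arrays; ``acode`` is (N, 2) in {0, 1}
    (0 -> A1, 1 -> A2).
    """

    female: np.ndarray  # (N,) bool
    alpha: np.ndarray  # (N, 2, L) uint8
    acode: np.ndarray  # (N, 2) uint8
    beta: np.ndarray  # (N, 2, L) uint8
    generation: int = 0

    @property
    def size(self) -> int:
        return len(self.female)

    def freq_A2(self) -> float:
        return float(self.acode.mean())

    def genotype(self, i: int, config: "SimConfig") -> RegNetGenotype:
        """Object view of individual ``i`` (for inspection and tests)."""
        codings = {
            0: CodingAlleleA("A1", config.a1_recognition_seq, config.effect_a1),
            1: CodingAlleleA("A2", config.a2_recognition_seq, config.effect_a2),
        }
        hapA = tuple(
            HaplotypeA(regnet.decode_seq(self.alpha[i, j]), codings[int(self.acode[i, j])])
            for j in range(2)
        )
        hapB = tuple(HaplotypeB(regnet.decode_seq(self.beta[i, j])) for j in range(2))
        return RegNetGenotype(
            sex="female" if self.female[i] else "male", hapA=hapA, hapB=hapB
        )


def init_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """Found a population: half of each sex, A2 haplotypes at the configured
    initial frequency by Bernoulli sampling, all alpha sites at the common
    neutral sequence and all beta sites at the initial beta sequence."""
    N, L = config.N, config.L_site
    female = np.zeros(N, dtype=bool)
    female[: N // 2] = True
    alpha = np.broadcast_to(encode_seq(config.init_alpha_seq), (N, 2, L)).copy()
    beta = np.broadcast_to(encode_seq(config.init_beta_seq), (N, 2, L)).copy()
    acode = (rng.random((N, 2)) < config.init_freq_A2).astype(np.uint8)
    return Population(female=female, alpha=alpha, acode=acode, beta=beta)


def mutate_sites(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> Population:
    """Mutate binding sites in place (and return the population).

    Each nucleotide of each alpha site (when the modifier is enabled)
    and each beta site mutates independently with its per-site rate to a
    uniformly chosen *different* symbol; by default the beta rate is 0
    (the dominance modifier under study is the alpha site) and can be
    enabled via ``mu_site_beta``.  Coding domains and stimulus sequences
    never change.
    """
    if config.modifier_enabled and config.mu_alpha > 0:
        _mutate_array(pop.alpha, config.mu_alpha, rng)
    if config.mu_beta > 0:
        _mutate_array(pop.beta, config.mu_beta, rng)
    return pop


def _mutate_array(sites: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    hit = rng.random(sites.shape) < mu
    n = int(hit.sum())
    if n:
        # shift by 1..3 mod 4: uniform over the three other symbols
        sites[hit] = (sites[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4


class _SimContext:
    """Per-run precomputed constants (sequence codes, lookups, scales)."""

    def __init__(self, config: SimConfig, n: int):
        stim = config.stimulus
        d_f = encode_seq(stim.recognition_seq_female)
        d_m = encode_seq(stim.recognition_seq_male)
        female = np.zeros(n, dtype=bool)
        female[: n // 2] = True
        # own-sex stimulus recognition sequence per individual, (N, 1, L)
        self.own_d = np.where(female[:, None, None], d_f, d_m)
        self.recs = np.stack(
            [
                encode_seq(config.a1_recognition_seq),
                encode_seq(config.a2_recognition_seq),
            ]
        )
        self.effects = np.array([config.effect_a1, config.effect_a2])
        self.basal = config.basal_B
        self.b_max = config.params.b_scale
        self.log_k = np.log(config.k_total)


def _network_state(
    pop: Population, config: SimConfig, ctx: _SimContext | None = None
) -> dict[str, np.ndarray]:
    """Vectorized network evaluation for every individual.

    Returns per-individual arrays: mismatch of each alpha site to the
    own-sex stimulus sequence ('m_alpha', (N,2)), allele-specific
    concentrations ('conc', (N,2)), expression 'B' and standardized
    'phi' ((N,)).
    """
    if ctx is None:
        ctx = _SimContext(config, pop.size)
    m_alpha = (pop.alpha != ctx.own_d).mean(axis=-1)  # (N,2)

    w_d = config.D_concentration * np.exp(-ctx.log_k * m_alpha)
    conc = config.A_max * w_d / (1.0 + 2.0 * w_d)  # (N,2)

    tf_rec = ctx.recs[pop.acode]  # (N,2,L)
    # mismatch of TF j to beta site b: (N, 2 tf, 2 beta)
    m_beta = (tf_rec[:, :, None, :] != pop.beta[:, None, :, :]).mean(axis=-1)
    w = conc[:, :, None] * np.exp(-ctx.log_k * m_beta)  # (N,2,2)
    occ = w / (1.0 + w.sum(axis=1, keepdims=True))
    effects = ctx.effects[pop.acode]  # (N,2)
    bound = (occ * effects[:, :, None]).sum(axis=(1, 2))
    empty = 2.0 - occ.sum(axis=(1, 2))  # unbound probability over both copies
    B = bound + empty * ctx.basal
    phi = np.minimum(1.0, B / ctx.b_max)
    return {"m_alpha": m_alpha, "conc": conc, "B": B, "phi": phi}


def population_fitness(
    pop: Population, config: SimConfig, state: dict | None = None
) -> np.ndarray:
    """Viability of every individual from its network output phi."""
    if state is None:
        state = _network_state(pop, config)
    phi = state["phi"]
    if config.fitness_shape == "linear":
        return np.where(
            pop.female, 1.0 - config.s_f * (1.0 - phi), 1.0 - config.s_m * phi
        )
    opt = np.where(pop.female, config.optimum_f, config.optimum_m)
    return np.exp(-((phi - opt) ** 2) / (2.0 * config.width**2))


def individual_fitness(ind: RegNetGenotype, config: SimConfig) -> float:
    """Viability of a single genotype object (object-level reference path).

    Evaluates the network through :mod:`domrev.regnet` rather than the
    packed-array route; the test suite holds the two paths to agreement.
    """
    B = regnet.expression_B(ind, config.stimulus, config.params)
    phi = regnet.phi(B, config.params)
    if config.fitness_shape == "linear":
        if ind.sex == "female":
            return 1.0 - config.s_f * (1.0 - phi)
        return 1.0 - config.s_m * phi
    opt = config.optimum_f if ind.sex == "female" else config.optimum_m
    return float(np.exp(-((phi - opt) ** 2) / (2.0 * config.width**2)))


def next_generation(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    state: dict | None = None,
    ctx: _SimContext | None = None,
) -> Population:
    """Produce the next generation by fitness-proportional sampling.

    Soft selection within sexes; independent assortment of the A and B
    genes; alpha-A and beta-B transmitted as units; mutation applied to
    the offspring.
    """
    N = pop.size
    half = N // 2
    if state is None:
        state = _network_state(pop, config, ctx)
    w = population_fitness(pop, config, state)
    wf, wm = w[:half], w[half:]
    if wf.sum() <= 0 or wm.sum() <= 0:
        raise RuntimeError("all fitness zero in one sex; selection degenerate")

    cdf_f = np.cumsum(wf)
    cdf_m = np.cumsum(wm)
    mothers = np.searchsorted(cdf_f, rng.random(N) * cdf_f[-1], side="right")
    fathers = half + np.searchsorted(cdf_m, rng.random(N) * cdf_m[-1], side="right")

    # one haplotype per gene per parent; A and B assort independently
    pick = rng.integers(0, 2, size=(N, 4))
    alpha = np.empty_like(pop.alpha)
    acode = np.empty_like(pop.acode)
    beta = np.empty_like(pop.beta)
    alpha[:, 0] = pop.alpha[mothers, pick[:, 0]]
    acode[:, 0] = pop.acode[mothers, pick[:, 0]]
    alpha[:, 1] = pop.alpha[fathers, pick[:, 1]]
    acode[:, 1] = pop.acode[fathers, pick[:, 1]]
    beta[:, 0] = pop.beta[mothers, pick[:, 2]]
    beta[:, 1] = pop.beta[fathers, pick[:, 3]]

    child = Population(
        female=pop.female.copy(),
        alpha=alpha,
        acode=acode,
        beta=beta,
        generation=pop.generation + 1,
    )
    return mutate_sites(child, config, rng)


def ase_ratio_heterozygotes(
    pop: Population, config: SimConfig, state: dict | None = None
) -> tuple[float, float]:
    """Mean allele-specific expression ratio [A1]/([A1]+[A2]) among A1A2
    heterozygotes, per sex (female, male); NaN when a sex has no
    heterozygote or zero total concentration."""
    if state is None:
        state = _network_state(pop, config)
    conc = state["conc"]
    het = pop.acode.sum(axis=1) == 1
    out = []
    for sex_mask in (pop.female, ~pop.female):
        sel = het & sex_mask
        if not sel.any():
            out.append(float("nan"))
            continue
        c = conc[sel]
        a1_is_first = pop.acode[sel, 0] == 0
        c_a1 = np.where(a1_is_first, c[:, 0], c[:, 1])
        tot = c.sum(axis=1)
        ok = tot > 0
        if not ok.any():
            out.append(float("nan"))
            continue
        out.append(float(np.mean(c_a1[ok] / tot[ok])))
    return out[0], out[1]


_GCLASS = ("A1A1", "A1A2", "A2A2")

_TRAJ_COLS = (
    ["generation", "freq_A2"]
    + [f"mean_phi_{s}_{g}" for s in ("female", "male") for g in _GCLASS]
    + ["mean_fitness_female", "mean_fitness_male"]
    + ["ase_ratio_A1_female", "ase_ratio_A1_male"]
    + [f"mean_m_alpha_{s}_{a}" for s in ("female", "male") for a in ("A1", "A2")]
)


@dataclass
class Trajectory:
    """Per-generation record of a simulation run."""

    config: SimConfig
    records: pd.DataFrame
    lost_at: int | None  # generation of fixation/loss of the A polymorphism
    final_freq_A2: float

    @property
    def n_recorded(self) -> int:
        return len(self.records)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _record(pop: Population, config: SimConfig, state: dict | None = None) -> list[float]:
    if state is None:
        state = _network_state(pop, config)
    phi = state["phi"]
    nA2 = pop.acode.sum(axis=1)  # 0,1,2 copies of A2
    sex_id = (~pop.female).astype(np.intp)  # 0 female, 1 male
    half = pop.size // 2

    with np.errstate(invalid="ignore"):
        # mean phi by sex x A-genotype class (empty classes -> NaN)
        grp = sex_id * 3 + nA2.astype(np.intp)
        mean_phi = np.bincount(grp, weights=phi, minlength=6) / np.bincount(
            grp, minlength=6
        )
        # mean mismatch to the own-sex stimulus by sex x linked allele
        grp_a = (sex_id[:, None] * 2 + pop.acode.astype(np.intp)).ravel()
        ma = state["m_alpha"].ravel()
        mean_m = np.bincount(grp_a, weights=ma, minlength=4) / np.bincount(
            grp_a, minlength=4
        )
    w = population_fitness(pop, config, state)
    ase_f, ase_m = ase_ratio_heterozygotes(pop, config, state)

    row = [float(pop.generation), pop.freq_A2()]
    row.extend(mean_phi.tolist())
    row.append(float(w[:half].mean()))
    row.append(float(w[half:].mean()))
    row.extend((ase_f, ase_m))
    row.extend(mean_m.tolist())
    return row


def run_simulation(config: SimConfig) -> Trajectory:
    """Run one replicate: iterate generations, recording every generation,
    stopping early once the A coding polymorphism is lost (the absorbing
    generation is recorded).  Fully reproducible from (config, seed)."""
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng)
    ctx = _SimContext(config, pop.size)
    state = _network_state(pop, config, ctx)
    rows = [_record(pop, config, state)]
    lost_at = None
    p = pop.freq_A2()
    if p in (0.0, 1.0):
        lost_at = 0
    else:
        for _ in range(config.n_generations):
            pop = next_generation(pop, config, rng, state=state, ctx=ctx)
            state = _network_state(pop, config, ctx)
            rows.append(_record(pop, config, state))
            p = pop.freq_A2()
            if p in (0.0, 1.0):
                lost_at = pop.generation
                break
    records = pd.DataFrame(rows, columns=_TRAJ_COLS)
    return Trajectory(
        config=config, records=records, lost_at=lost_at, final_freq_A2=p
    )


def retention_time(traj: Trajectory) -> tuple[int, bool]:
    """Generations until the A polymorphism was lost.

    Returns ``(time, censored)``: censored is True when the polymorphism
    survived the whole run, with time = n_generations.
    """
    if traj.lost_at is None:
        return traj.config.n_generations, True
    return traj.lost_at, False


def sign_test(x, y, alternative: str = "two-sided"):
    """Paired sign test: are the x values larger than their paired y?

    Ties are dropped.  Returns (n_pos, n_informative, p_value); p = 1.0
    when every pair is tied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    pos = int((x > y).sum())
    neg = int((x < y).sum())
    n = pos + neg
    if n == 0:
        return 0, 0, 1.0
    p = stats.binomtest(pos, n, 0.5, alternative=alternative).pvalue
    return pos, n, float(p)


@dataclass
class ExperimentResult:
    """Replicate-experiment output: one row per (arm, replicate)."""

    summary: pd.DataFrame
    arms: dict[str, dict]
    seeds: list[int]

    def arm(self, name: str) -> pd.DataFrame:
        return self.summary[self.summary["arm"] == name].reset_index(drop=True)

    def compare_retention(
        self, arm_a: str, arm_b: str, alternative: str = "greater"
    ) -> dict:
        """Paired sign test on per-seed retention times (arm_a vs arm_b)."""
        a = self.arm(arm_a).sort_values("seed")["retention_time"].to_numpy()
        b = self.arm(arm_b).sort_values("seed")["retention_time"].to_numpy()
        pos, n, p = sign_test(a, b, alternative=alternative)
        return {"n_pos": pos, "n_informative": n, "p_value": p}


_SUMMARY_COLS = [
    "arm",
    "seed",
    "retention_time",
    "censored",
    "final_freq_A2",
    "final_ase_ratio_A1_female",
    "final_ase_ratio_A1_male",
    "mean_abs_ase_diff",
    "final_mean_fitness_female",
    "final_mean_fitness_male",
    "het_phi_shift_female",
    "het_phi_shift_male",
]

#: Window (generations) at the end of a run over which per-replicate
#: summary statistics are averaged.
SUMMARY_WINDOW = 100


def _summarize(traj: Trajectory, arm: str, seed: int) -> dict:
    t, cens = retention_time(traj)
    rec = traj.records
    last = rec.iloc[-1]
    # ASE ratios at the last generation where both sexes had measurable
    # heterozygotes (the final generation for runs that stay polymorphic)
    both = rec[
        rec["ase_ratio_A1_female"].notna() & rec["ase_ratio_A1_male"].notna()
    ]
    if len(both):
        ase_last = both.iloc[-1]
        ase_f = float(ase_last["ase_ratio_A1_female"])
        ase_m = float(ase_last["ase_ratio_A1_male"])
        abs_diff = float(
            (both["ase_ratio_A1_male"] - both["ase_ratio_A1_female"]).abs().mean()
        )
    else:
        ase_f = ase_m = abs_diff = float("nan")
    out = {
        "arm": arm,
        "seed": seed,
        "retention_time": t,
        "censored": cens,
        "final_freq_A2": traj.final_freq_A2,
        "final_ase_ratio_A1_female": ase_f,
        "final_ase_ratio_A1_male": ase_m,
        "mean_abs_ase_diff": abs_diff,
        "final_mean_fitness_female": last["mean_fitness_female"],
        "final_mean_fitness_male": last["mean_fitness_male"],
    }
    # heterozygote phi relative to the additive (homozygote-midpoint)
    # baseline, per sex, averaged over the last recorded generations
    tail = rec.iloc[-SUMMARY_WINDOW:]
    for sex in ("female", "male"):
        het = tail[f"mean_phi_{sex}_A1A2"]
        mid = 0.5 * (tail[f"mean_phi_{sex}_A1A1"] + tail[f"mean_phi_{sex}_A2A2"])
        shift = (het - mid).dropna()
        out[f"het_phi_shift_{sex}"] = float(shift.mean()) if len(shift) else float("nan")
    return out


def replicate_experiment(
    base_config: SimConfig,
    n_reps: int = 50,
    seed_list: list[int] | None = None,
    arms: dict[str, dict] | None = None,
    base_seed: int = 0,
) -> ExperimentResult:
    """Run paired replicate arms of the simulation.

    Each arm applies its config overrides to ``base_config``; replicate i
    of every arm shares seed ``seed_list[i]`` so arms are compared
    pairwise on identical random streams.  Default arms are the
    modifier-on vs modifier-off contrast.
    """
    if arms is None:
        arms = {
            "modifier_on": {"modifier_enabled": True},
            "modifier_off": {"modifier_enabled": False},
        }
    if len(arms) < 2:
        raise ValueError("at least two arms are required")
    if seed_list is None:
        seed_list = [base_seed + i for i in range(n_reps)]
    rows = []
    for arm_name, overrides in arms.items():
        for seed in seed_list:
            cfg = base_config.with_overrides(seed=seed, **overrides)
            traj = run_simulation(cfg)
            rows.append(_summarize(traj, arm_name, seed))
    summary = pd.DataFrame(rows, columns=_SUMMARY_COLS)
    return ExperimentResult(summary=summary, arms=arms, seeds=list(seed_list))
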