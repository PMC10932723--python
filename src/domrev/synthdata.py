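"""Synthetic data with known ground truth for the detection methods.

Generates (a) full-diallel phenotype tables from panels of homozygous
strains whose per-locus dominance is additive, unconditional, or
context-reversed, (b) per-gene allele-specific read-count tables with
binomial sampling at specified imbalance ratios, and (c) small named
preset fixtures used throughout the test suite.  Every generator is
reproducible from its seed, and the returned truth records suffice to
score detection calls exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import AseGeneCounts, DiallelData
from .simulator import SimConfig

__all__ = [
    "DiallelSimSpec",
    "AseSimSpec",
    "simulate_diallel",
    "simulate_ase_counts",
    "preset_fixtures",
]

_MODES = ("additive", "unconditional", "dominance_reversed")


@dataclass(frozen=True)
class DiallelSimSpec:
    """Genetic architecture of a synthetic diallel panel.

    Each of ``n_strains`` inbred strains is homozygous at ``n_loci``
    biallelic loci; allele 1 adds ``+effect`` to the phenotype in context
    A and ``-effect`` in context B (allele 0 the reverse).  At
    heterozygous loci of a cross the value is the midpoint plus
    ``dominance_deviation * effect`` with the sign set by the mode:
    ``dominance_reversed`` pushes toward the context-beneficial allele in
    both contexts; ``unconditional`` toward a globally dominant allele
    drawn once per locus; ``additive`` has no deviation.  Gaussian noise
    of sd ``noise_sd`` is added per observation.
    """

    n_strains: int = 16
    n_loci: int = 50
    dominance_mode: str = "dominance_reversed"
    effect: float = 1.0
    dominance_deviation: float = 0.8
    noise_sd: float = 1.0
    replicates: int = 2
    contexts: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dominance_mode not in _MODES:
            raise ValueError(
                f"dominance_mode must be one of {_MODES}, got {self.dominance_mode!r}"
            )
        if self.n_strains < 4:
            raise ValueError(f"need >= 4 strains, got {self.n_strains}")
        if self.n_loci < 1:
            raise ValueError("need >= 1 locus")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.dominance_deviation <= 1.0:
            raise ValueError("dominance_deviation must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class AseSimSpec:
    """Design of a synthetic allele-specific read-count table.

    Reversed genes draw allele-1 counts Binomial(depth, ratio) in context
    1 and Binomial(depth, 1 - ratio) in context 2; null genes use 0.5 in
    both.  ``depth_mean`` is a fixed depth, or a Poisson mean when
    ``depth_poisson`` is set (zero draws are redrawn as 1).
    """

    n_genes: int = 2000
    proportion_reversed: float = 0.0
    reversed_ratio: float = 0.7
    depth_mean: int = 100
    depth_poisson: bool = False
    contexts: tuple[str, str] = ("context1", "context2")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion_reversed <= 1.0:
            raise ValueError("proportion_reversed must lie in [0, 1]")
        if not 0.0 < self.reversed_ratio < 1.0:
            raise ValueError("reversed_ratio must lie in (0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth must be > 0")


def _het_deviation(spec: DiallelSimSpec, rng: np.random.Generator):
    """Per-locus heterozygote deviation (in units of effect) per context.

    Returns (dev_A, dev_B) arrays of length n_loci and the truth
    assignment used to produce them.
    """
    d = spec.dominance_deviation * spec.effect
    L = spec.n_loci
    if spec.dominance_mode == "additive":
        dev_A = np.zeros(L)
        dev_B = np.zeros(L)
        truth = np.full(L, "additive")
    elif spec.dominance_mode == "dominance_reversed":
        # context-beneficial allele dominant in both contexts: allele 1
        # is beneficial in A (+e) and allele 0 in B (+e), so the
        # heterozygote deviates upward in both contexts.
        dev_A = np.full(L, +d)
        dev_B = np.full(L, +d)
        truth = np.full(L, "reversed")
    else:  # unconditional
        dom = rng.integers(0, 2, size=L)  # globally dominant allele
        dev_A = np.where(dom == 1, +d, -d)
        dev_B = np.where(dom == 1, -d, +d)
        truth = np.where(dom == 1, "dominant_allele_1", "dominant_allele_0")
    return dev_A, dev_B, truth


def simulate_diallel(spec: DiallelSimSpec) -> tuple[DiallelData, pd.DataFrame]:
    """Generate a full diallel (ordered pairs, selfs, replicates) and its
    per-locus truth record."""
    rng = np.random.default_rng(spec.seed)
    S, L = spec.n_strains, spec.n_loci
    G = rng.integers(0, 2, size=(S, L))  # strain genotypes (homozygous)
    dev_A, dev_B, truth_assign = _het_deviation(spec, rng)

    e = spec.effect
    # homozygote per-locus effects: allele 1 -> +e in A, -e in B
    hom_A = e * (2.0 * G - 1.0)  # (S, L)
    hom_B = -hom_A

    strains = [f"S{i+1:02d}" for i in range(S)]
    het = G[:, None, :] != G[None, :, :]  # (S, S, L)
    mid_A = 0.5 * (hom_A[:, None, :] + hom_A[None, :, :])
    mid_B = 0.5 * (hom_B[:, None, :] + hom_B[None, :, :])
    value_A = np.where(het, mid_A + dev_A, mid_A).sum(axis=2)  # (S, S)
    value_B = np.where(het, mid_B + dev_B, mid_B).sum(axis=2)

    rows = []
    for ctx, val in zip(spec.contexts, (value_A, value_B)):
        for rep in range(1, spec.replicates + 1):
            noise = rng.normal(0.0, spec.noise_sd, size=(S, S))
            for i in range(S):
                for j in range(S):
                    rows.append(
                        (strains[i], strains[j], ctx, rep, val[i, j] + noise[i, j])
                    )
    table = pd.DataFrame(
        rows, columns=["strain_a", "strain_b", "context", "replicate", "phenotype"]
    )
    truth = pd.DataFrame(
        {
            "locus": np.arange(L),
            "dominance": truth_assign,
            "dev_A": dev_A,
            "dev_B": dev_B,
        }
    )
    truth.attrs["genotypes"] = G
    truth.attrs["strains"] = strains
    return DiallelData(table), truth


def simulate_ase_counts(spec: AseSimSpec) -> AseGeneCounts:
    """Generate a per-gene two-context allele count table with truth labels."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    reversed_mask = rng.random(n) < spec.proportion_reversed
    # alternate the direction of reversal between genes so neither allele
    # is globally favoured
    flip = rng.random(n) < 0.5
    rho = np.where(reversed_mask, np.where(flip, spec.reversed_ratio, 1 - spec.reversed_ratio), 0.5)
    rho_c2 = np.where(reversed_mask, 1.0 - rho, 0.5)

    if spec.depth_poisson:
        depth1 = np.maximum(1, rng.poisson(spec.depth_mean, size=n))
        depth2 = np.maximum(1, rng.poisson(spec.depth_mean, size=n))
    else:
        depth1 = np.full(n, spec.depth_mean)
        depth2 = np.full(n, spec.depth_mean)

    a1_c1 = rng.binomial(depth1, rho)
    a1_c2 = rng.binomial(depth2, rho_c2)

    genes = [f"g{i+1:05d}" for i in range(n)]
    labels = np.where(reversed_mask, "reversed", "null")
    c1, c2 = spec.contexts
    table = pd.DataFrame(
        {
            "gene": genes * 2,
            "context": [c1] * n + [c2] * n,
            "allele1_count": np.concatenate([a1_c1, a1_c2]).astype(int),
            "allele2_count": np.concatenate(
                [depth1 - a1_c1, depth2 - a1_c2]
            ).astype(int),
            "truth": np.concatenate([labels, labels]),
        }
    )
    return AseGeneCounts(table)


def _fixture_diallel_additive_3strain() -> DiallelData:
    """Noiseless additive 3-strain diallel: every cross is the midparent."""
    selfs = {"S1": 0.0, "S2": 2.0, "S3": 6.0}
    rows = []
    for a in selfs:
        for b in selfs:
            rows.append((a, b, "A", 1, 0.5 * (selfs[a] + selfs[b])))
            rows.append((a, b, "B", 1, 0.5 * (selfs[a] + selfs[b])))
    return DiallelData(
        pd.DataFrame(
            rows, columns=["strain_a", "strain_b", "context", "replicate", "phenotype"]
        )
    )


def _fixture_ase_10gene() -> AseGeneCounts:
    """Ten genes at depth 100 covering all four classification outcomes."""
    spec = [
        ("g1", 90, 10, 10, 90, "reversal"),
        ("g2", 10, 90, 90, 10, "reversal"),
        ("g3", 90, 10, 90, 10, "consistent_imbalance"),
        ("g4", 10, 90, 10, 90, "consistent_imbalance"),
        ("g5", 90, 10, 55, 45, "context_dependent"),
        ("g6", 45, 55, 10, 90, "context_dependent"),
        ("g7", 50, 50, 50, 50, "none"),
        ("g8", 55, 45, 45, 55, "none"),
        ("g9", 48, 52, 52, 48, "none"),
        ("g10", 52, 48, 48, 52, "none"),
    ]
    rows = []
    for gene, a1c1, a2c1, a1c2, a2c2, label in spec:
        rows.append((gene, "context1", a1c1, a2c1, label))
        rows.append((gene, "context2", a1c2, a2c2, label))
    return AseGeneCounts(
        pd.DataFrame(
            rows,
            columns=["gene", "context", "allele1_count", "allele2_count", "truth"],
        )
    )


_FIXTURES = {
    "diallel_additive_3strain": _fixture_diallel_additive_3strain,
    "box1_default_network": lambda: SimConfig(),
    "ase_10gene": _fixture_ase_10gene,
}


def preset_fixtures(name: str):
    """Return a documented small preset instance by name."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
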