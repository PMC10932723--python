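"""Deterministic single-locus two-sex viability model.

Quantifies when sex-specific dominance maintains a sexually antagonistic
polymorphism.  One autosomal locus with a female-benefit allele F and a
male-benefit allele M; selection acts on viability with sex-specific
coefficients (s_f against MM in females, s_m against FF in males) and
sex-specific dominance of the locally deleterious allele (h_f, h_m).
h = 0.5 is the additive reference; h < 0.5 in both sexes is a beneficial
dominance reversal.

Assumptions: infinite population, discrete generations, random mating
(zygotes by random union of sex-specific gamete pools), equal sex ratio,
viability selection before gametogenesis, no mutation or drift.

A protected polymorphism requires each allele to invade when rare: the
leading eigenvalue of the rare-allele branching process is

    lambda_M = 1/2 [ (1 - h_f s_f) / 1 + (1 - h_m s_m) / (1 - s_m) ]
    lambda_F = 1/2 [ (1 - h_f s_f) / (1 - s_f) + (1 - h_m s_m) / 1 ]

(the rare allele resides in heterozygotes, transmitted through both
sexes, relative to the resident homozygote's fitness in each sex).
Because both lambdas fall as h rises, lowering h (partial dominance
reversal) expands the protected region of the (s_f, s_m) plane; at
h_f = h_m = 0 every selection pair with s < 1 is protected, while under
additivity (h = 0.5) protection requires strong and/or nearly symmetric
selection.  Every closed form here is cross-checked against brute-force
iteration of the exact recursion in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SelectionRegime",
    "SexFrequencies",
    "EquilibriumResult",
    "InvasionResult",
    "genotype_fitnesses",
    "recursion_step",
    "iterate_to_equilibrium",
    "invasion_conditions",
    "protected_region_fraction",
    "classification_grid",
]

#: Strictness tolerance for the "protected" inequality; |lambda - 1| below
#: this is reported as a boundary case, not protected.
BOUNDARY_TOL = 1e-12

#: A frequency within this of 0 or 1 at convergence counts as fixation.
FIXATION_TOL = 1e-6


@dataclass(frozen=True)
class SelectionRegime:
    """Sex-specific selection and dominance parameters.

    s_f: selection against the male-benefit allele's homozygote (MM) in
    females; s_m: against the female-benefit homozygote (FF) in males;
    h_f, h_m: dominance of the locally deleterious allele in each sex.
    """

    s_f: float
    s_m: float
    h_f: float = 0.5
    h_m: float = 0.5

    def __post_init__(self) -> None:
        for name, s in (("s_f", self.s_f), ("s_m", self.s_m)):
            if not 0.0 <= s < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {s}")
        for name, h in (("h_f", self.h_f), ("h_m", self.h_m)):
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {h}")


@dataclass(frozen=True)
class SexFrequencies:
    """Frequency of the female-benefit allele among gametes of each sex."""

    p_f: float
    p_m: float

    def __post_init__(self) -> None:
        for name, p in (("p_f", self.p_f), ("p_m", self.p_m)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class EquilibriumResult:
    status: str  # 'fixation_F' | 'fixation_M' | 'polymorphic' | 'unconverged'
    p_f: float
    p_m: float
    generations: int
    converged: bool


@dataclass(frozen=True)
class InvasionResult:
    lambda_F: float
    lambda_M: float
    protected: bool
    boundary: bool


def genotype_fitnesses(regime: SelectionRegime) -> dict[str, dict[str, float]]:
    """Per-sex viabilities of FF / FM / MM genotypes."""
    return {
        "female": {
            "FF": 1.0,
            "FM": 1.0 - regime.h_f * regime.s_f,
            "MM": 1.0 - regime.s_f,
        },
        "male": {
            "FF": 1.0 - regime.s_m,
            "FM": 1.0 - regime.h_m * regime.s_m,
            "MM": 1.0,
        },
    }


def recursion_step(freqs, regime: SelectionRegime):
    """One generation of the exact two-sex viability recursion.

    Zygotes form by random union of female gametes (allele-F frequency
    p_f) and male gametes (p_m); sex-specific viability selection acts;
    the post-selection gamete frequencies per sex are returned.  Accepts
    a :class:`SexFrequencies` (returning the same) or a ``(p_f, p_m)``
    pair of scalars/arrays (vectorized over parameter grids).
    """
    wrapped = isinstance(freqs, SexFrequencies)
    p_f, p_m = (freqs.p_f, freqs.p_m) if wrapped else freqs
    p_f = np.asarray(p_f, dtype=float)
    p_m = np.asarray(p_m, dtype=float)

    x_FF = p_f * p_m
    x_FM = p_f * (1.0 - p_m) + (1.0 - p_f) * p_m
    x_MM = (1.0 - p_f) * (1.0 - p_m)

    w = genotype_fitnesses(regime)
    wf, wm = w["female"], w["male"]

    num_f = x_FF * wf["FF"] + 0.5 * x_FM * wf["FM"]
    den_f = x_FF * wf["FF"] + x_FM * wf["FM"] + x_MM * wf["MM"]
    num_m = x_FF * wm["FF"] + 0.5 * x_FM * wm["FM"]
    den_m = x_FF * wm["FF"] + x_FM * wm["FM"] + x_MM * wm["MM"]

    new_f = num_f / den_f
    new_m = num_m / den_m
    if wrapped:
        return SexFrequencies(float(new_f), float(new_m))
    if new_f.ndim == 0:
        return float(new_f), float(new_m)
    return new_f, new_m


def iterate_to_equilibrium(
    freqs0,
    regime: SelectionRegime,
    tol: float = 1e-12,
    max_gen: int = 10**6,
    check_every: int = 64,
) -> EquilibriumResult:
    """Iterate the recursion until the per-step change falls below ``tol``.

    Classification: fixation if both frequencies end within
    ``FIXATION_TOL`` of the same boundary, polymorphic if both are
    interior at convergence; non-convergence within ``max_gen`` is
    flagged (``converged=False``), not raised.
    """
    p_f, p_m = (
        (freqs0.p_f, freqs0.p_m) if isinstance(freqs0, SexFrequencies) else freqs0
    )
    gen = 0
    converged = False
    while gen < max_gen:
        steps = min(check_every, max_gen - gen)
        for _ in range(steps):
            n_f, n_m = recursion_step((p_f, p_m), regime)
            delta = max(abs(n_f - p_f), abs(n_m - p_m))
            p_f, p_m = n_f, n_m
            gen += 1
            if delta < tol:
                converged = True
                break
        if converged:
            break

    lo = min(p_f, p_m)
    hi = max(p_f, p_m)
    if converged and lo > FIXATION_TOL and hi < 1.0 - FIXATION_TOL:
        status = "polymorphic"
    elif hi < FIXATION_TOL:
        status = "fixation_M"
    elif lo > 1.0 - FIXATION_TOL:
        status = "fixation_F"
    else:
        status = "unconverged"
    return EquilibriumResult(status, float(p_f), float(p_m), gen, converged)


def invasion_conditions(regime: SelectionRegime) -> InvasionResult:
    """Rare-allele invasion growth rates and protection classification.

    Protected iff both lambdas exceed 1 strictly (tolerance
    ``BOUNDARY_TOL``); boundary cases are flagged and not counted
    protected.
    """
    w = genotype_fitnesses(regime)
    wf, wm = w["female"], w["male"]
    lam_M = 0.5 * (wf["FM"] / wf["FF"] + wm["FM"] / wm["FF"])
    lam_F = 0.5 * (wf["FM"] / wf["MM"] + wm["FM"] / wm["MM"])
    boundary = (
        abs(lam_F - 1.0) <= BOUNDARY_TOL or abs(lam_M - 1.0) <= BOUNDARY_TOL
    )
    protected = (not boundary) and lam_F > 1.0 and lam_M > 1.0
    return InvasionResult(float(lam_F), float(lam_M), protected, boundary)


def _lambda_grid(h_f: float, h_m: float, s_f: np.ndarray, s_m: np.ndarray):
    """Vectorized invasion lambdas over broadcastable s_f, s_m arrays."""
    w_FM_f = 1.0 - h_f * s_f
    w_FM_m = 1.0 - h_m * s_m
    lam_M = 0.5 * (w_FM_f + w_FM_m / (1.0 - s_m))
    lam_F = 0.5 * (w_FM_f / (1.0 - s_f) + w_FM_m)
    return lam_F, lam_M


def protected_region_fraction(h_f: float, h_m: float, s_grid) -> float:
    """Fraction of an (s_f, s_m) grid deterministically protected.

    ``s_grid`` is an iterable of (s_f, s_m) pairs, e.g. the cartesian
    41 x 41 grid over (0.005 .. 0.5)^2.
    """
    pairs = np.asarray(list(s_grid), dtype=float)
    if pairs.size == 0:
        raise ValueError("s_grid must be non-empty")
    lam_F, lam_M = _lambda_grid(h_f, h_m, pairs[:, 0], pairs[:, 1])
    protected = (lam_F > 1.0 + BOUNDARY_TOL) & (lam_M > 1.0 + BOUNDARY_TOL)
    return float(protected.mean())


def default_s_grid(n: int = 41, lo: float = 0.005, hi: float = 0.5):
    """Cartesian n x n grid of (s_f, s_m) pairs over [lo, hi]^2."""
    s = np.linspace(lo, hi, n)
    sf, sm = np.meshgrid(s, s, indexing="ij")
    return np.column_stack([sf.ravel(), sm.ravel()])


def classification_grid(
    h_f: float, h_m: float, s_values: np.ndarray | None = None
) -> pd.DataFrame:
    """Invasion classification over an (s_f, s_m) grid as a tidy table.

    Columns: s_f, s_m, h_f, h_m, lambda_F, lambda_M, protected.
    """
    pairs = default_s_grid() if s_values is None else np.asarray(s_values, float)
    lam_F, lam_M = _lambda_grid(h_f, h_m, pairs[:, 0], pairs[:, 1])
    protected = (lam_F > 1.0 + BOUNDARY_TOL) & (lam_M > 1.0 + BOUNDARY_TOL)
    return pd.DataFrame(
        {
            "s_f": pairs[:, 0],
            "s_m": pairs[:, 1],
            "h_f": h_f,
            "h_m": h_m,
            "lambda_F": lam_F,
            "lambda_M": lam_M,
            "protected": protected,
        }
    )


def equilibrium_grid(
    h_f: float,
    h_m: float,
    s_values: np.ndarray,
    p0: float = 0.5,
    tol: float = 1e-10,
    max_gen: int = 200_000,
) -> pd.DataFrame:
    """Brute-force equilibrium classification over an (s_f, s_m) grid.

    Vectorized companion to :func:`iterate_to_equilibrium`: every grid
    point is iterated simultaneously; points are frozen once their
    per-step change drops below ``tol`` or a frequency passes the
    fixation threshold.  Used as the independent arbiter for
    :func:`invasion_conditions`.
    """
    pairs = np.asarray(s_values, dtype=float)
    s_f, s_m = pairs[:, 0], pairs[:, 1]
    n = len(pairs)
    p_f = np.full(n, p0)
    p_m = np.full(n, p0)
    active = np.ones(n, dtype=bool)

    w_FM_f = 1.0 - h_f * s_f
    w_MM_f = 1.0 - s_f
    w_FM_m = 1.0 - h_m * s_m
    w_FF_m = 1.0 - s_m

    gen = 0
    while active.any() and gen < max_gen:
        pf, pm = p_f[active], p_m[active]
        x_FF = pf * pm
        x_FM = pf * (1.0 - pm) + (1.0 - pf) * pm
        x_MM = (1.0 - pf) * (1.0 - pm)
        wFMf = w_FM_f[active]
        wMMf = w_MM_f[active]
        wFMm = w_FM_m[active]
        wFFm = w_FF_m[active]
        num_f = x_FF + 0.5 * x_FM * wFMf
        den_f = x_FF + x_FM * wFMf + x_MM * wMMf
        num_m = x_FF * wFFm + 0.5 * x_FM * wFMm
        den_m = x_FF * wFFm + x_FM * wFMm + x_MM
        new_f = num_f / den_f
        new_m = num_m / den_m
        delta = np.maximum(np.abs(new_f - pf), np.abs(new_m - pm))
        p_f[active] = new_f
        p_m[active] = new_m
        done = (delta < tol) | (np.maximum(new_f, new_m) < FIXATION_TOL / 10) | (
            np.minimum(new_f, new_m) > 1.0 - FIXATION_TOL / 10
        )
        idx = np.flatnonzero(active)
        active[idx[done]] = False
        gen += 1

    lo = np.minimum(p_f, p_m)
    hi = np.maximum(p_f, p_m)
    status = np.where(
        hi < FIXATION_TOL,
        "fixation_M",
        np.where(
            lo > 1.0 - FIXATION_TOL,
            "fixation_F",
            np.where(~active, "polymorphic", "unconverged"),
        ),
    )
    return pd.DataFrame(
        {
            "s_f": s_f,
            "s_m": s_m,
            "h_f": h_f,
            "h_m": h_m,
            "p_f": p_f,
            "p_m": p_m,
            "status": status,
        }
    )
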