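"""Genotype -> phenotype -> fitness composition.

The dominance of a biallelic genotype for *fitness* is the product of two
maps: a genotype-phenotype map (additive, or with the heterozygote drawn
toward the context-beneficial homozygote: phenotypic dominance reversal)
and a phenotype-fitness map (linear, or curved/Gaussian with
context-specific optima).  A fitness-level dominance reversal can arise
from either map: an additive trait filtered through two Gaussian fitness
functions whose concave vicinities overlap makes the heterozygote
dominant-beneficial in both contexts, without any phenotypic dominance.

Contexts are abstract labels (sexes, environments, generations); nothing
in this module is sex-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhenotypeMap",
    "FitnessFunction",
    "GenotypeFitnessPanel",
    "linear_fitness",
    "gaussian_fitness",
    "effective_dominance",
    "compose_panel",
]

_GENOTYPES = ("AA", "Aa", "aa")


def linear_fitness(phi: float, context: str, s_f: float, s_m: float) -> float:
    """Linear sexually antagonistic fitness on a standardized trait phi.

    Male-like contexts are penalized for high phi, female-like for low:
    w_male = 1 - s_m * phi, w_female = 1 - s_f * (1 - phi).
    """
    for name, s in (("s_f", s_f), ("s_m", s_m)):
        if not 0.0 <= s < 1.0:
            raise ValueError(f"{name} must lie in [0, 1), got {s}")
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    if context in ("male", "male-like"):
        return 1.0 - s_m * phi
    if context in ("female", "female-like"):
        return 1.0 - s_f * (1.0 - phi)
    raise ValueError(f"unknown context {context!r}")


def gaussian_fitness(z, optimum: float, width: float):
    """Gaussian stabilizing fitness exp(-(z - optimum)^2 / (2 width^2)).

    Maximal (1) at the optimum; concave within one width of it, convex
    beyond.  Broadcasts over ``z``.
    """
    if width <= 0:
        raise ValueError(f"width must be > 0, got {width}")
    z = np.asarray(z, dtype=float)
    out = np.exp(-((z - optimum) ** 2) / (2.0 * width**2))
    return float(out) if out.ndim == 0 else out


def effective_dominance(w_AA: float, w_Aa: float, w_aa: float) -> float:
    """Dominance coefficient of the locally deleterious allele.

    h_eff = (w_best - w_Aa) / (w_best - w_worst), where best/worst are the
    homozygote fitnesses.  h_eff = 0.5 is additivity; h_eff < 0.5 means
    the locally beneficial allele is dominant (beneficial dominance);
    values outside [0, 1] encode over- (< 0) or under- (> 1) dominance
    and are reported unclipped.  Returns NaN for w_AA == w_aa (undefined).
    """
    if w_AA == w_aa:
        return float("nan")
    w_best, w_worst = max(w_AA, w_aa), min(w_AA, w_aa)
    return (w_best - w_Aa) / (w_best - w_worst)


@dataclass(frozen=True)
class PhenotypeMap:
    """Trait values of the three genotypes (z_AA, z_Aa, z_aa) per context.

    ``mode`` records how the map was built: 'additive' forces the
    heterozygote to the homozygote midpoint in every context;
    'dominance_reversed' places it a fraction ``d`` of the way toward the
    context-beneficial homozygote in each context; 'custom' is free.
    """

    values: dict[str, tuple[float, float, float]]
    mode: str = "custom"

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "dominance_reversed", "custom"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "additive":
            for ctx, (zAA, zAa, zaa) in self.values.items():
                if abs(zAa - 0.5 * (zAA + zaa)) > 1e-12:
                    raise ValueError(
                        f"additive mode requires the midpoint heterozygote "
                        f"(context {ctx!r})"
                    )

    @property
    def contexts(self) -> tuple[str, ...]:
        return tuple(self.values)

    @classmethod
    def additive(cls, homozygotes: dict[str, tuple[float, float]]) -> "PhenotypeMap":
        """Additive map from per-context (z_AA, z_aa) homozygote values."""
        vals = {
            ctx: (zAA, 0.5 * (zAA + zaa), zaa) for ctx, (zAA, zaa) in homozygotes.items()
        }
        return cls(vals, mode="additive")

    @classmethod
    def dominance_reversed(
        cls,
        homozygotes: dict[str, tuple[float, float]],
        beneficial: dict[str, str],
        d: float = 1.0,
    ) -> "PhenotypeMap":
        """Reversed map: heterozygote drawn toward the context-beneficial
        homozygote ('AA' or 'aa' per context) by a fraction ``d`` of the
        half-range (d=1: complete reversal, heterozygote at the beneficial
        homozygote; d=0 would be additive)."""
        if not 0.0 < d <= 1.0:
            raise ValueError(f"d must lie in (0, 1], got {d}")
        vals = {}
        for ctx, (zAA, zaa) in homozygotes.items():
            mid = 0.5 * (zAA + zaa)
            target = zAA if beneficial[ctx] == "AA" else zaa
            vals[ctx] = (zAA, mid + d * (target - mid), zaa)
        return cls(vals, mode="dominance_reversed")


@dataclass(frozen=True)
class FitnessFunction:
    """Per-context phenotype -> fitness map.

    ``shape='linear'``: params[ctx] = {'s': selection coefficient,
    'benefit': 'high' or 'low' (which end of the trait the context
    favours)}; slopes must oppose each other between the two contexts
    (antagonism).  ``shape='gaussian'``: params[ctx] = {'optimum': theta,
    'width': omega}.
    """

    shape: str
    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "gaussian"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "linear":
            benefits = set()
            for ctx, p in self.params.items():
                if not 0.0 <= p["s"] < 1.0:
                    raise ValueError(f"s must lie in [0, 1) (context {ctx!r})")
                if p["benefit"] not in ("high", "low"):
                    raise ValueError("benefit must be 'high' or 'low'")
                benefits.add(p["benefit"])
            if len(self.params) == 2 and len(benefits) != 2:
                raise ValueError(
                    "linear antagonism requires opposite-benefit contexts"
                )
        else:
            for ctx, p in self.params.items():
                if p["width"] <= 0:
                    raise ValueError(f"width must be > 0 (context {ctx!r})")

    @property
    def contexts(self) -> tuple[str, ...]:
        return tuple(self.params)

    def evaluate(self, z: float, context: str) -> float:
        p = self.params[context]
        if self.shape == "linear":
            # z interpreted as a standardized trait in [0, 1]
            if p["benefit"] == "low":
                return 1.0 - p["s"] * z
            return 1.0 - p["s"] * (1.0 - z)
        return gaussian_fitness(z, p["optimum"], p["width"])


@dataclass(frozen=True)
class GenotypeFitnessPanel:
    """Resultant per-context genotype fitnesses with dominance classification.

    ``classification`` is one of 'additive', 'reversal_from_phenotype',
    'reversal_from_fitness', 'reversal_combined', 'underdominant',
    'other'.  ``h_eff`` is per-context effective dominance of the locally
    deleterious allele; ``underdominant`` flags marginal heterozygote
    inferiority (mean across contexts below both marginal homozygote
    means).
    """

    fitness: dict[str, tuple[float, float, float]]
    h_eff: dict[str, float]
    classification: str
    underdominant: bool
    marginal_means: tuple[float, float, float]


def _marginal_means(fitness: dict[str, tuple[float, float, float]]):
    arr = np.array(list(fitness.values()))
    return tuple(arr.mean(axis=0))


def compose_panel(
    pm: PhenotypeMap, ff: FitnessFunction, tol: float = 1e-9
) -> GenotypeFitnessPanel:
    """Compose a phenotype map with a fitness function.

    Evaluates all three genotypes in both contexts, computes per-context
    effective dominance, flags marginal underdominance, and classifies the
    panel by the (phenotype map, fitness shape) combination that produced
    it.  With a Gaussian fitness function the 'reversal_from_fitness'
    class additionally requires the heterozygote trait to lie inside the
    concave region of both contexts' curves, which is exactly when an
    additive trait yields beneficial dominance in both contexts.
    """
    if set(pm.contexts) != set(ff.contexts):
        raise ValueError(
            f"contexts differ: map {pm.contexts} vs fitness {ff.contexts}"
        )
    fitness = {
        ctx: tuple(ff.evaluate(z, ctx) for z in pm.values[ctx]) for ctx in pm.contexts
    }
    h_eff = {ctx: effective_dominance(*fitness[ctx]) for ctx in pm.contexts}

    mAA, mAa, maa = _marginal_means(fitness)
    underdominant = mAa < min(mAA, maa)

    reversed_both = all(
        np.isfinite(h) and h < 0.5 - tol for h in h_eff.values()
    )
    if pm.mode == "additive" and ff.shape == "linear":
        classification = "additive"
    elif pm.mode == "dominance_reversed" and ff.shape == "linear":
        classification = "reversal_from_phenotype"
    elif pm.mode == "additive" and ff.shape == "gaussian":
        het_concave = all(
            abs(pm.values[ctx][1] - ff.params[ctx]["optimum"])
            < ff.params[ctx]["width"]
            for ctx in pm.contexts
        )
        if het_concave and reversed_both:
            classification = "reversal_from_fitness"
        elif underdominant:
            classification = "underdominant"
        else:
            classification = "other"
    elif pm.mode == "dominance_reversed" and ff.shape == "gaussian":
        if reversed_both:
            classification = "reversal_combined"
        elif underdominant:
            classification = "underdominant"
        else:
            classification = "other"
    elif underdominant:
        classification = "underdominant"
    else:
        classification = "other"

    return GenotypeFitnessPanel(
        fitness=fitness,
        h_eff=h_eff,
        classification=classification,
        underdominant=underdominant,
        marginal_means=(mAA, mAa, maa),
    )
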