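"""Biophysical model of a three-gene dominance-modifier network.

A sex-limited regulatory stimulus ``D`` binds the cis-regulatory site
``alpha_i`` of a transcription-factor gene ``A``; the two A protein variants
then compete for the cis-regulatory site ``beta_i`` of a downstream gene
``B``.  Binding affinity decays geometrically with the proportion of
mismatched nucleotides between a recognition sequence and a binding site
(stepwise dissociation-constant multiplier ``k``), so mutations in the
freely mutating alpha and beta sites tune allele-specific concentrations
and occupancies.  The standardized expression level of B, ``phi``, is the
trait under sexually antagonistic selection: the male-benefit allele A1
lowers [B], the female-benefit allele A2 raises it.

The central quantity is the fractional occupancy of a site by a
transcription factor at concentration ``c`` with mismatch proportion ``m``:

    occ = (c / k**m) / (1 + 2 * c / k**m)

for the stimulus binding an alpha site (the factor 2 reflecting the two
diploid copies of the regulated gene competing for stimulus), and the
competitive multi-factor analogue for the shared beta sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHABET",
    "BindingSequence",
    "RegulatoryStimulus",
    "CodingAlleleA",
    "HaplotypeA",
    "HaplotypeB",
    "RegNetGenotype",
    "RegNetParams",
    "encode_seq",
    "decode_seq",
    "mismatch_proportion",
    "fractional_occupancy",
    "allele_concentration",
    "competitive_site_occupancy",
    "expression_B",
    "network_max_B",
    "phi",
    "default_stimulus",
    "default_genotype",
    "FEMALE_D_SEQ",
    "MALE_D_SEQ",
    "NEUTRAL_ALPHA_SEQ",
    "A1_RECOGNITION_SEQ",
    "A2_RECOGNITION_SEQ",
    "BETA_INIT_SEQ",
    "EFFECT_A1",
    "EFFECT_A2",
]

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}

# Default sequence set (site length 8).  The two sex-specific stimulus
# recognition sequences are fully divergent, so every alpha-site position
# trades affinity for one sex against the other; the initial alpha site
# matches each of them at exactly 4/8 positions, so neither A allele
# starts with a sex-biased cis advantage.  The initial beta site matches
# A2's recognition sequence exactly (A2 "intrinsically dominant") while
# A1 mismatches it at 2/8 positions.
FEMALE_D_SEQ = "AAAAAAAA"
MALE_D_SEQ = "CCCCCCCC"
NEUTRAL_ALPHA_SEQ = "AAAACCCC"
A1_RECOGNITION_SEQ = "TTGGGGGG"
A2_RECOGNITION_SEQ = "GGGGGGGG"
BETA_INIT_SEQ = "GGGGGGGG"

#: Default allelic effects on [B]: A1 decreases, A2 increases expression.
EFFECT_A1 = 0.0
EFFECT_A2 = 1.0


def encode_seq(seq: str | np.ndarray) -> np.ndarray:
    """Encode a nucleotide string over ``ACGT`` as a uint8 code array.

    Arrays of codes are passed through (validated).
    """
    if isinstance(seq, np.ndarray):
        arr = np.asarray(seq, dtype=np.uint8)
        if arr.size and arr.max() > 3:
            raise ValueError("sequence codes must lie in 0..3")
        return arr
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(
            f"invalid symbol {exc.args[0]!r}; alphabet is {ALPHABET!r}"
        ) from None


def decode_seq(arr: np.ndarray) -> str:
    """Inverse of :func:`encode_seq`."""
    return "".join(ALPHABET[int(i)] for i in np.asarray(arr).ravel())


@dataclass(frozen=True)
class BindingSequence:
    """A fixed-length nucleotide sequence (binding site or recognition seq).

    Thin value wrapper used where a named domain type aids readability;
    most operations accept plain strings or code arrays interchangeably.
    """

    symbols: str

    def __post_init__(self) -> None:
        encode_seq(self.symbols)  # validates alphabet membership

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def codes(self) -> np.ndarray:
        return encode_seq(self.symbols)


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, BindingSequence):
        return seq.codes
    return encode_seq(seq)


@dataclass(frozen=True)
class RegulatoryStimulus:
    """The sex-limited regulatory stimulus D.

    One stimulus with two sex-specific recognition sequences; the
    sequences may be equal (the sex-equalized network-dependence
    control).  ``concentration`` is [D] >= 0.
    """

    recognition_seq_female: str = FEMALE_D_SEQ
    recognition_seq_male: str = MALE_D_SEQ
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"[D] must be >= 0, got {self.concentration}")
        encode_seq(self.recognition_seq_female)
        encode_seq(self.recognition_seq_male)

    def recognition_seq(self, sex: str) -> str:
        if sex == "female":
            return self.recognition_seq_female
        if sex == "male":
            return self.recognition_seq_male
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")


@dataclass(frozen=True)
class CodingAlleleA:
    """A protein-coding allele of gene A (A1 male-benefit, A2 female-benefit).

    The recognition sequence (for binding the downstream beta site) and the
    effect on [B] are fixed properties of the allele: only the cis sites
    alpha and beta mutate during evolution.
    """

    identity: str  # "A1" or "A2"
    recognition_seq: str
    effect_on_B: float

    def __post_init__(self) -> None:
        if self.identity not in ("A1", "A2"):
            raise ValueError(f"identity must be 'A1' or 'A2', got {self.identity!r}")
        if not 0.0 <= self.effect_on_B <= 1.0:
            raise ValueError(f"effect_on_B must lie in [0, 1], got {self.effect_on_B}")
        encode_seq(self.recognition_seq)


def _default_coding(which: int) -> CodingAlleleA:
    if which == 0:
        return CodingAlleleA("A1", A1_RECOGNITION_SEQ, EFFECT_A1)
    return CodingAlleleA("A2", A2_RECOGNITION_SEQ, EFFECT_A2)


@dataclass(frozen=True)
class HaplotypeA:
    """An alpha-site + A-coding-allele unit, transmitted without recombination."""

    alpha_site: str
    coding: CodingAlleleA


@dataclass(frozen=True)
class HaplotypeB:
    """A beta-site + B-coding unit; B's coding domain carries no allelic effect."""

    beta_site: str


@dataclass(frozen=True)
class RegNetGenotype:
    """An individual's diploid state of the regulatory network."""

    sex: str
    hapA: tuple[HaplotypeA, HaplotypeA]
    hapB: tuple[HaplotypeB, HaplotypeB]

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if len(self.hapA) != 2 or len(self.hapB) != 2:
            raise ValueError("exactly two haplotypes per gene are required")


@dataclass(frozen=True)
class RegNetParams:
    """Biophysical parameters of the network.

    Parameters
    ----------
    k : float
        Stepwise dissociation-constant multiplier, > 1 so each unit of
        mismatch weakens binding.
    D_concentration : float
        Default stimulus concentration [D] >= 0.
    A_max : float
        Proportionality constant converting occupancy to concentration
        [A_i] (resolves the "proportional to" in the occupancy equation).
    B_max : float or None
        Scale for phi standardization.  ``None`` means: use the analytic
        network maximum, i.e. [B] of an A2A2 genotype with zero mismatches
        everywhere (see :func:`network_max_B`).
    basal_B : float
        Constitutive activity of an unbound beta site, in effect units.
        An A2-bound site produces effect_on_B(A2) (activation above
        basal), an A1-bound site effect_on_B(A1) (repression below it).
    """

    k: float = 2.0
    D_concentration: float = 1.0
    A_max: float = 1.0
    B_max: float | None = None
    basal_B: float = 0.5
    max_effect: float = field(default=EFFECT_A2)

    def __post_init__(self) -> None:
        if self.k <= 1:
            raise ValueError(f"k must be > 1, got {self.k}")
        if self.D_concentration < 0:
            raise ValueError(f"[D] must be >= 0, got {self.D_concentration}")
        if self.A_max <= 0:
            raise ValueError(f"A_max must be > 0, got {self.A_max}")
        if self.B_max is not None and self.B_max <= 0:
            raise ValueError(f"B_max must be > 0, got {self.B_max}")
        if self.basal_B < 0:
            raise ValueError(f"basal_B must be >= 0, got {self.basal_B}")

    @property
    def b_scale(self) -> float:
        """The effective phi-standardization constant."""
        if self.B_max is not None:
            return self.B_max
        return network_max_B(self)


def mismatch_proportion(site, probe) -> float | np.ndarray:
    """Proportion of mismatched nucleotides between two equal-length sequences.

    Symmetric in its arguments; broadcasts over leading axes when given
    code arrays (the last axis is the sequence).
    """
    a = _as_codes(site)
    b = _as_codes(probe)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(
            f"sequence lengths differ: {a.shape[-1]} vs {b.shape[-1]}"
        )
    out = np.mean(a != b, axis=-1)
    return float(out) if out.ndim == 0 else out


def fractional_occupancy(D_conc, k, m):
    """Equilibrium fractional occupancy of an alpha site by the stimulus D.

        occ = (D / k**m) / (1 + 2 * D / k**m)

    The factor 2 in the denominator reflects the two diploid copies of the
    regulated gene competing for stimulus, which caps occupancy at 0.5 as
    [D] grows.  Strictly increasing in ``D_conc`` and, for ``D_conc > 0``,
    strictly decreasing in the mismatch proportion ``m``.  Broadcasts.
    """
    D = np.asarray(D_conc, dtype=float)
    kk = np.asarray(k, dtype=float)
    mm = np.asarray(m, dtype=float)
    if np.any(D < 0):
        raise ValueError("D_conc must be >= 0")
    if np.any(kk <= 1):
        raise ValueError("k must be > 1")
    if np.any((mm < 0) | (mm > 1)):
        raise ValueError("m must lie in [0, 1]")
    w = D / kk**mm
    out = w / (1.0 + 2.0 * w)
    return float(out) if out.ndim == 0 else out


def allele_concentration(
    hap: HaplotypeA, sex: str, stimulus: RegulatoryStimulus, params: RegNetParams
) -> float:
    """Allele-specific concentration [A_i] of the product of one A haplotype.

    [A_i] = A_max * occ([D], k, m) with m the mismatch proportion between
    the stimulus recognition sequence of the individual's sex and the
    haplotype's alpha site.
    """
    m = mismatch_proportion(hap.alpha_site, stimulus.recognition_seq(sex))
    return params.A_max * fractional_occupancy(stimulus.concentration, params.k, m)


def competitive_site_occupancy(beta, tf_list, k) -> np.ndarray:
    """Occupancy of one beta site by each of several competing factors.

        occ_i = (c_i / k**m_i) / (1 + sum_j c_j / k**m_j)

    with ``m_i`` the mismatch proportion between factor i's recognition
    sequence and the site.  Returns one occupancy per factor; the sum over
    factors is strictly below 1.
    """
    if k <= 1:
        raise ValueError(f"k must be > 1, got {k}")
    concs = np.array([c for c, _ in tf_list], dtype=float)
    if np.any(concs < 0):
        raise ValueError("TF concentrations must be >= 0")
    ms = np.array([mismatch_proportion(seq, beta) for _, seq in tf_list])
    w = concs / np.asarray(k, dtype=float) ** ms
    return w / (1.0 + w.sum())


def expression_B(
    g: RegNetGenotype, stimulus: RegulatoryStimulus, params: RegNetParams
) -> float:
    """Expression level [B]: occupancy-weighted activity over both B copies.

    Each A haplotype contributes a transcription factor at its
    allele-specific concentration; the two factors compete for the beta
    site of each B gene copy.  A copy whose site is bound by allele i
    produces effect_on_B(A_i); an unbound site produces the basal
    activity ``basal_B`` -- so A2 (high effect) is an activator and A1
    (low effect) a repressor of constitutive expression.  Deterministic
    given the genotype, stimulus and parameters.
    """
    concs = [allele_concentration(h, g.sex, stimulus, params) for h in g.hapA]
    tf_list = [(c, h.coding.recognition_seq) for c, h in zip(concs, g.hapA)]
    effects = np.array([h.coding.effect_on_B for h in g.hapA])
    total = 0.0
    for hb in g.hapB:
        occ = competitive_site_occupancy(hb.beta_site, tf_list, params.k)
        total += float(np.dot(occ, effects)) + (1.0 - float(occ.sum())) * params.basal_B
    return total


def network_max_B(params: RegNetParams, max_effect: float | None = None) -> float:
    """Analytic maximum of [B] over the network: zero mismatches everywhere.

    With both haplotypes carrying the maximal-effect allele at
    concentration c0 = A_max * occ([D], k, 0), each B copy's site is
    occupied with probability q = 2 c0 / (1 + 2 c0), so

        B_max = 2 copies * (q * max_effect + (1 - q) * basal_B)

    (maximal provided max_effect >= basal_B, which the parameter ranges
    guarantee up to equality).
    """
    if max_effect is None:
        max_effect = params.max_effect
    c0 = params.A_max * fractional_occupancy(params.D_concentration, params.k, 0.0)
    q = 2.0 * c0 / (1.0 + 2.0 * c0)
    b = 2.0 * (q * max_effect + (1.0 - q) * params.basal_B)
    if b == 0.0:
        raise ValueError("network maximum is 0; phi undefined")
    return b


def phi(B_level, params: RegNetParams):
    """Standardized expression level phi = min(1, [B] / B_max) in [0, 1]."""
    B = np.asarray(B_level, dtype=float)
    if np.any(B < 0):
        raise ValueError("B_level must be >= 0")
    out = np.minimum(1.0, B / params.b_scale)
    return float(out) if out.ndim == 0 else out


def default_stimulus(
    equalize: bool = False, concentration: float = 1.0
) -> RegulatoryStimulus:
    """The default sex-limited stimulus; ``equalize=True`` gives both sexes
    the female recognition sequence (network-dependence control)."""
    male = FEMALE_D_SEQ if equalize else MALE_D_SEQ
    return RegulatoryStimulus(FEMALE_D_SEQ, male, concentration)


def default_genotype(
    sex: str = "female",
    a_identities: tuple[int, int] = (0, 1),
    alpha_sites: tuple[str, str] | None = None,
    beta_sites: tuple[str, str] | None = None,
) -> RegNetGenotype:
    """A genotype with the default initial sequence set.

    ``a_identities`` selects the coding alleles (0 -> A1, 1 -> A2);
    the default is an A1A2 heterozygote.
    """
    if alpha_sites is None:
        alpha_sites = (NEUTRAL_ALPHA_SEQ, NEUTRAL_ALPHA_SEQ)
    if beta_sites is None:
        beta_sites = (BETA_INIT_SEQ, BETA_INIT_SEQ)
    hapA = tuple(
        HaplotypeA(alpha_sites[i], _default_coding(a_identities[i])) for i in range(2)
    )
    hapB = tuple(HaplotypeB(beta_sites[i]) for i in range(2))
    return RegNetGenotype(sex=sex, hapA=hapA, hapB=hapB)
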