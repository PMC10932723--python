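"""Detection of dominance reversal in data.

Two procedures:

* **Diallel dominance ordination.**  From a full diallel cross among
  inbred strains, each strain's array covariance W_r -- the covariance,
  across all partners s (self included), between the mean phenotype of
  the r x s crosses and partner s's self (parental) value -- orders the
  strains along a dominant-recessive continuum per context: the more
  dominant strain r's fixed alleles, the more its crosses are buffered
  toward its own value and the *smaller* W_r.  A negative cross-context
  Pearson correlation between the two W vectors indicates that strains'
  fixed variation tends to be dominant in one context but recessive in
  the other -- a polygenic dominance-reversal signal.  Significance is
  assessed by permuting strain labels of one context's W vector.

* **Allele-specific-expression (ASE) reversal calling.**  Per gene and
  context, an exact binomial test of the allele-1 read fraction against
  0.5, adjusted across genes within each context.  A gene is called a
  *reversal* only when the imbalance is significant in both contexts
  independently AND the point estimates fall on opposite sides of 0.5;
  one-sided significance is context-dependent dominance, not reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiallelData",
    "OrdinationResult",
    "AseGeneCounts",
    "AseCallTable",
    "array_covariance",
    "array_covariances",
    "dominance_ordination",
    "ase_imbalance_test",
    "classify_ase_reversal",
]

DIALLEL_COLUMNS = ["strain_a", "strain_b", "context", "replicate", "phenotype"]
ASE_COLUMNS = ["gene", "context", "allele1_count", "allele2_count"]

#: Relative variance below which a W vector is declared degenerate.
DEGENERATE_REL_VAR = 1e-12


@dataclass
class DiallelData:
    """Phenotypes of a full diallel cross (selfs included), per context.

    Wraps a tidy table with columns strain_a, strain_b, context,
    replicate, phenotype; selfs have strain_a == strain_b.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DIALLEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"diallel table missing columns {missing}")
        strains = self.strains
        if len(strains) < 3:
            raise ValueError(f"need >= 3 strains, got {len(strains)}")
        for ctx in self.contexts:
            sub = self.table[self.table["context"] == ctx]
            selfs = set(
                sub.loc[sub["strain_a"] == sub["strain_b"], "strain_a"]
            )
            lacking = [s for s in strains if s not in selfs]
            if lacking:
                raise ValueError(
                    f"selfs missing for strains {lacking} in context {ctx!r}"
                )

    @property
    def strains(self) -> list:
        return sorted(set(self.table["strain_a"]) | set(self.table["strain_b"]))

    @property
    def contexts(self) -> list:
        return sorted(set(self.table["context"]))

    def cross_means(self, context) -> pd.DataFrame:
        """Strain x strain matrix of mean phenotypes, averaging replicates
        and reciprocals."""
        sub = self.table[self.table["context"] == context].copy()
        a = sub["strain_a"].to_numpy()
        b = sub["strain_b"].to_numpy()
        swap = a > b
        sub["_lo"] = np.where(swap, b, a)
        sub["_hi"] = np.where(swap, a, b)
        m = sub.groupby(["_lo", "_hi"])["phenotype"].mean()
        strains = self.strains
        mat = pd.DataFrame(index=strains, columns=strains, dtype=float)
        for (lo, hi), v in m.items():
            mat.loc[lo, hi] = v
            mat.loc[hi, lo] = v
        return mat

    @classmethod
    def from_tsv(cls, path) -> "DiallelData":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def array_covariances(data: DiallelData, context) -> pd.Series:
    """W_r for every strain r in one context.

    W_r = sample covariance (n-1 denominator), over all partners s
    including the self, between the r x s cross mean and s's self value.
    Under pure additivity the r x s mean is the midparent, so W_r equals
    half the variance of the self values -- the same for every strain --
    and the W vector is degenerate.
    """
    mat = data.cross_means(context)
    if mat.isna().any().any():
        missing = int(mat.isna().sum().sum())
        raise ValueError(f"{missing} strain pairs unobserved in context {context!r}")
    selfs = pd.Series(np.diag(mat.to_numpy()), index=mat.index)
    out = {}
    for r in mat.index:
        arr = mat.loc[r]
        out[r] = float(np.cov(arr.to_numpy(), selfs.to_numpy(), ddof=1)[0, 1])
    return pd.Series(out, name=f"W[{context}]")


def array_covariance(data: DiallelData, strain, context) -> float:
    """W_r for a single strain (see :func:`array_covariances`)."""
    W = array_covariances(data, context)
    if strain not in W.index:
        raise KeyError(f"unknown strain {strain!r}; strains are {list(W.index)}")
    if len(W) < 3:
        raise ValueError("array covariance needs >= 3 strains")
    return float(W[strain])


@dataclass
class OrdinationResult:
    """Cross-context dominance-ordination outcome."""

    W_by_context: dict
    correlation: float
    p_value: float
    n_permutations: int
    degenerate: bool

    @property
    def contexts(self) -> tuple:
        return tuple(self.W_by_context)


def dominance_ordination(
    data: DiallelData,
    context_pair: tuple | None = None,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> OrdinationResult:
    """Cross-context correlation of the dominance ordinations.

    Pearson correlation between the two contexts' W vectors across
    strains, with a two-sided permutation p-value obtained by shuffling
    the strain labels of one context's W vector.  When either W vector
    has (relatively) zero variance -- as in perfectly additive data --
    the result is flagged degenerate with NaN correlation rather than
    raising.
    """
    if context_pair is None:
        ctxs = data.contexts
        if len(ctxs) != 2:
            raise ValueError(
                f"context_pair required: data has contexts {ctxs}"
            )
        context_pair = tuple(ctxs)
    if rng is None:
        rng = np.random.default_rng()
    Wa = array_covariances(data, context_pair[0])
    Wb = array_covariances(data, context_pair[1]).reindex(Wa.index)
    W_by_context = {context_pair[0]: Wa, context_pair[1]: Wb}

    a = Wa.to_numpy()
    b = Wb.to_numpy()
    scale = max(np.mean(a**2), np.mean(b**2), 1.0)
    if min(a.var(), b.var()) <= DEGENERATE_REL_VAR * scale:
        return OrdinationResult(W_by_context, float("nan"), float("nan"), 0, True)

    r_obs = float(np.corrcoef(a, b)[0, 1])
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    n = len(a)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    r_null = (az[perms] * bz).mean(axis=1)  # Pearson r per permutation
    exceed = int((np.abs(r_null) >= abs(r_obs) - 1e-12).sum())
    p = (1 + exceed) / (1 + n_perm)
    return OrdinationResult(W_by_context, r_obs, float(p), n_perm, False)


@dataclass
class AseGeneCounts:
    """Per-gene allele read counts in two contexts.

    Tidy table with columns gene, context, allele1_count, allele2_count
    and an optional ``truth`` label column.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ASE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"ASE table missing columns {missing}")
        counts = self.table[["allele1_count", "allele2_count"]].to_numpy()
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("allele counts must be non-negative integers")

    @property
    def contexts(self) -> list:
        return sorted(set(self.table["context"]))

    @classmethod
    def from_tsv(cls, path) -> "AseGeneCounts":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class AseCallTable:
    """Per-gene imbalance estimates, adjusted p-values and classification."""

    table: pd.DataFrame
    alpha: float
    mt_method: str
    contexts: tuple
    skipped: pd.DataFrame

    def counts(self) -> pd.Series:
        return self.table["classification"].value_counts()


def ase_imbalance_test(a1: int, a2: int) -> tuple[float, float]:
    """Allelic-imbalance estimate and exact two-sided binomial p vs 0.5.

    Returns ``(a1/(a1+a2), p)``; zero total depth yields (NaN, NaN).
    """
    if a1 < 0 or a2 < 0:
        raise ValueError("counts must be non-negative")
    n = a1 + a2
    if n == 0:
        return float("nan"), float("nan")
    est = a1 / n
    p = stats.binomtest(int(a1), int(n), 0.5).pvalue
    return est, float(p)


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return pvals
    mapped = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if mapped is None:
        raise ValueError(f"mt_method must be 'none', 'bonferroni' or 'bh', got {method!r}")
    return multipletests(pvals, method=mapped)[1]


def classify_ase_reversal(
    counts: AseGeneCounts,
    alpha: float = 0.05,
    mt_method: str = "bh",
    context_pair: tuple | None = None,
) -> AseCallTable:
    """Call dominance-reversed allele-specific expression per gene.

    Per-context exact binomial p-values are adjusted across genes within
    each context (Benjamini-Hochberg by default).  Classification:

    * ``reversal`` -- significant in both contexts AND the imbalance
      estimates lie on opposite sides of 0.5 (hard rule: same-direction
      imbalances are never a reversal, whatever the p-values);
    * ``consistent_imbalance`` -- significant in both, same direction;
    * ``context_dependent`` -- significant in exactly one context;
    * ``none`` -- otherwise.

    Genes lacking either context or with zero depth in a tested context
    are skipped with a reason (``.skipped``).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if context_pair is None:
        ctxs = counts.contexts
        if len(ctxs) != 2:
            raise ValueError(f"context_pair required: data has contexts {ctxs}")
        context_pair = tuple(ctxs)
    c1, c2 = context_pair

    wide = counts.table.pivot_table(
        index="gene",
        columns="context",
        values=["allele1_count", "allele2_count"],
        aggfunc="sum",
    )
    skipped_rows = []
    rows = []
    for gene in wide.index:
        rec = {"gene": gene}
        ok = True
        for tag, ctx in (("c1", c1), ("c2", c2)):
            try:
                a1 = wide.loc[gene, ("allele1_count", ctx)]
                a2 = wide.loc[gene, ("allele2_count", ctx)]
            except KeyError:
                a1 = a2 = float("nan")
            if np.isnan(a1) or np.isnan(a2):
                skipped_rows.append({"gene": gene, "reason": f"missing context {ctx!r}"})
                ok = False
                break
            if a1 + a2 == 0:
                skipped_rows.append({"gene": gene, "reason": f"zero depth in {ctx!r}"})
                ok = False
                break
            est, p = ase_imbalance_test(int(a1), int(a2))
            rec[f"est_{tag}"], rec[f"p_{tag}"] = est, p
        if ok:
            rows.append(rec)

    out = pd.DataFrame(rows)
    if len(out):
        out["padj_c1"] = _adjust(out["p_c1"].to_numpy(), mt_method)
        out["padj_c2"] = _adjust(out["p_c2"].to_numpy(), mt_method)
        sig1 = out["padj_c1"] < alpha
        sig2 = out["padj_c2"] < alpha
        opposite = ((out["est_c1"] - 0.5) * (out["est_c2"] - 0.5)) < 0
        cls = np.where(
            sig1 & sig2 & opposite,
            "reversal",
            np.where(
                sig1 & sig2,
                "consistent_imbalance",
                np.where(sig1 ^ sig2, "context_dependent", "none"),
            ),
        )
        out["classification"] = cls
    else:
        out = pd.DataFrame(
            columns=[
                "gene", "est_c1", "p_c1", "est_c2", "p_c2",
                "padj_c1", "padj_c2", "classification",
            ]
        )
    skipped = pd.DataFrame(skipped_rows, columns=["gene", "reason"])
    return AseCallTable(
        table=out, alpha=alpha, mt_method=mt_method,
        contexts=context_pair, skipped=skipped,
    )
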