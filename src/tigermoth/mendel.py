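"""Mendelian segregation testing and pedigree genotype inference.

Implements the classic ecological-genetics workflow for a one-locus
two-allele polymorphism with dominance: expected offspring ratios per
cross, Pearson chi-square comparison of observed male phenotype counts
against those expectations, maximum-likelihood back-trace of parental
cross types from F1 phenotype counts, and exact posterior genotype
probabilities over whole pedigrees by enumeration.

Cross inference uses male counts only: male phenotype (white/yellow) is
a deterministic image of genotype through dominance, whereas the female
1-6 colour score carries no information about the locus.  The three
all-white crosses (WW x WW, WW x Wy, WW x yy) all predict zero yellow
males and are therefore never distinguishable from male phenotypes
alone; they are reported as an explicit three-way likelihood tie.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import (
    CROSS_TYPES,
    DOMINANCE,
    GENOTYPES,
    canonical_cross,
    canonical_genotype,
    cross_label,
    male_phenotype_distribution,
    offspring_genotype_distribution,
)

__all__ = [
    "DataError",
    "ImpossibleObservationError",
    "ChiSqResult",
    "CrossInference",
    "chi_square_gof",
    "chi_square_independence",
    "pooled_segregation_test",
    "infer_cross_from_offspring",
    "propagate_pedigree_genotypes",
    "families_from_pedigree",
    "MendelianInheritanceModel",
    "MendelianInheritanceResults",
]


class DataError(ValueError):
    """Input data violates the model's structural assumptions."""


class ImpossibleObservationError(DataError):
    """An observation fell in a cell the model gives probability zero.

    Raised instead of returning a numeric NaN: a yellow male from an
    all-white cross is a model violation signal, not a rounding issue.
    """


_ALL_WHITE = tuple(c for c in CROSS_TYPES if male_phenotype_distribution(c)["yellow"] == 0.0)


@dataclass
class ChiSqResult:
    """Pearson chi-square result with the expectations actually used."""

    statistic: float
    df: int
    p_value: float
    expected: dict

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ChiSqResult(statistic={self.statistic:.4g}, df={self.df}, p={self.p_value:.4g})"


@dataclass
class CrossInference:
    """Maximum-likelihood cross-type set for one family."""

    log_likelihoods: dict[str, float]
    ml_set: tuple[tuple[str, str], ...]
    identifiability_class: str
    posterior: dict[str, float] | None = None
    posterior_mode: str | None = None

    @property
    def ml_labels(self) -> tuple[str, ...]:
        return tuple(cross_label(c) for c in self.ml_set)


def chi_square_gof(observed: dict[str, int], expected_probs: dict[str, float]) -> ChiSqResult:
    """Pearson goodness-of-fit of observed counts to expected proportions.

    Cells with zero expected probability are excluded from the statistic;
    a positive observed count in such a cell raises
    :class:`ImpossibleObservationError`.  ``df`` is the number of cells
    with positive expectation minus one.
    """
    cells = list(expected_probs)
    obs = np.array([float(observed.get(c, 0)) for c in cells])
    probs = np.array([float(expected_probs[c]) for c in cells])
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    total = obs.sum()
    if total < 1:
        raise ValueError("need at least one observation")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("expected probabilities must sum to 1")
    zero = probs == 0
    if np.any(obs[zero] > 0):
        bad = [c for c, z, o in zip(cells, zero, obs) if z and o > 0]
        raise ImpossibleObservationError(
            f"observed counts in zero-expectation cells {bad}: model violation"
        )
    keep = ~zero
    exp = probs[keep] * total
    stat = float(np.sum((obs[keep] - exp) ** 2 / exp))
    df = int(keep.sum()) - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return ChiSqResult(stat, df, p, dict(zip(np.array(cells)[keep], exp)))


def chi_square_independence(table: np.ndarray | pd.DataFrame) -> ChiSqResult:
    """Chi-square test of independence on a contingency table.

    Provided alongside the goodness-of-fit test because the source
    analysis names the independence test while describing a fit to model
    expectations; the GOF form is the package default.
    """
    arr = np.asarray(table, dtype=float)
    stat, p, df, exp = stats.chi2_contingency(arr, correction=False)
    return ChiSqResult(float(stat), int(df), float(p), {"table": exp})


def pooled_segregation_test(families: pd.DataFrame) -> ChiSqResult:
    """Pooled segregation test across families, stratified by cross type.

    Each offspring counts as an independent observation.  Male white and
    yellow counts are pooled within each assumed cross stratum, compared
    against :func:`male_phenotype_distribution`, and the per-stratum
    Pearson statistics and degrees of freedom are summed.  Families
    flagged ``excluded`` are skipped.

    ``families`` needs columns ``cross`` (e.g. ``"WyxWy"``),
    ``n_male_white``, ``n_male_yellow`` and optionally ``excluded``.
    """
    if "cross" not in families.columns or families["cross"].isna().any():
        raise ValueError("every family needs a cross assignment")
    use = families
    if "excluded" in families.columns:
        use = families[~families["excluded"].astype(bool)]
    stat, df = 0.0, 0
    expected: dict = {}
    for cross_lab, grp in use.groupby("cross"):
        g1, g2 = cross_lab.split("x")
        probs = male_phenotype_distribution(canonical_cross(g1, g2))
        obs = {
            "white": int(grp["n_male_white"].sum()),
            "yellow": int(grp["n_male_yellow"].sum()),
        }
        if sum(obs.values()) == 0:
            continue
        res = chi_square_gof(obs, probs)
        stat += res.statistic
        df += res.df
        expected[cross_lab] = res.expected
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return ChiSqResult(stat, df, p, expected)


def infer_cross_from_offspring(counts: dict[str, int],
                               founder_prior: float | None = None) -> CrossInference:
    """Back-trace the parental cross from F1 male phenotype counts.

    Computes the binomial log-likelihood of the yellow count under each
    of the six cross types (yellow probabilities 0, 0, 0, 1/4, 1/2, 1)
    and returns the maximum-likelihood set.  Exact ties are reported as
    sets, never broken: all-white offspring always yield the three-way
    tie {WW x WW, WW x Wy, WW x yy}, labelled ``all-white``.

    With ``founder_prior`` (a W allele frequency) a Hardy-Weinberg prior
    over crosses is applied and the posterior mode also reported.
    """
    n_white = int(counts.get("white", counts.get("white_males", 0)))
    n_yellow = int(counts.get("yellow", counts.get("yellow_males", 0)))
    if n_white < 0 or n_yellow < 0:
        raise ValueError("counts must be non-negative")
    n = n_white + n_yellow
    if n < 1:
        raise ValueError("need at least one male offspring")
    logliks: dict[str, float] = {}
    for cross in CROSS_TYPES:
        p_yel = male_phenotype_distribution(cross)["yellow"]
        with np.errstate(divide="ignore"):
            ll = n_yellow * np.log(p_yel) if n_yellow else 0.0
            ll += n_white * np.log(1.0 - p_yel) if n_white else 0.0
        logliks[cross_label(cross)] = float(ll)
    best = max(logliks.values())
    ml = tuple(c for c in CROSS_TYPES if logliks[cross_label(c)] >= best - 1e-9)
    if set(ml) == set(_ALL_WHITE):
        klass = "all-white"
    elif len(ml) == 1:
        klass = cross_label(ml[0])
    else:
        klass = "tie:" + "|".join(cross_label(c) for c in ml)
    posterior = mode = None
    if founder_prior is not None:
        p = float(founder_prior)
        hw = {g: q for g, q in zip(GENOTYPES, (p * p, 2 * p * (1 - p), (1 - p) ** 2))}
        logpost = {}
        for cross in CROSS_TYPES:
            g1, g2 = cross
            prior = hw[g1] * hw[g2] * (2.0 if g1 != g2 else 1.0)
            lab = cross_label(cross)
            logpost[lab] = logliks[lab] + (np.log(prior) if prior > 0 else -np.inf)
        mx = max(logpost.values())
        if np.isfinite(mx):
            w = {k: np.exp(v - mx) for k, v in logpost.items()}
            z = sum(w.values())
            posterior = {k: v / z for k, v in w.items()}
            mode = max(posterior, key=posterior.get)
    return CrossInference(logliks, ml, klass, posterior, mode)


# ---------------------------------------------------------------------------
# pedigree propagation
# ---------------------------------------------------------------------------

def _transmission_table() -> np.ndarray:
    """T[s, d, c] = P(child genotype c | sire s, dam d), indices in GENOTYPES order."""
    T = np.zeros((3, 3, 3))
    gi = {g: i for i, g in enumerate(GENOTYPES)}
    for g1 in GENOTYPES:
        for g2 in GENOTYPES:
            dist = offspring_genotype_distribution((g1, g2))
            for gc, p in dist.items():
                T[gi[g1], gi[g2], gi[gc]] = p
    return T


_T = _transmission_table()


def propagate_pedigree_genotypes(pedigree: pd.DataFrame,
                                 founder_prior: float = 0.5,
                                 max_component: int = 12) -> pd.DataFrame:
    """Exact genotype posteriors for every pedigree member by enumeration.

    The joint distribution over a connected pedigree component factorises
    into Hardy-Weinberg founder priors (allele frequency
    ``founder_prior``), Mendelian transmission probabilities, and
    phenotype evidence: observed male phenotypes constrain genotypes
    through dominance, female phenotypes are uninformative for the
    locus, and genotypes recorded in the input are conditioned on
    directly.  All ``3**n`` joint configurations of a component are
    enumerated (components larger than ``max_component`` raise), giving
    exact marginals.

    Returns a table with columns ``id, p_WW, p_Wy, p_yy, consistent``;
    a component whose evidence has probability zero gets ``consistent
    False`` and NaN marginals.
    """
    ped = pedigree.copy()
    req = {"id", "sire", "dam"}
    if not req.issubset(ped.columns):
        raise DataError(f"pedigree needs columns {sorted(req)}")
    ids = ped["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise DataError("duplicate individual ids")
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)

    def _ref(v) -> int | None:
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) in ("", "nan", "None"):
            return None
        s = str(v)
        if s not in idx:
            raise DataError(f"parent id {s!r} not present in pedigree")
        return idx[s]

    sires = [_ref(v) for v in ped["sire"]]
    dams = [_ref(v) for v in ped["dam"]]

    # record-level dominance violations + direct evidence
    geno_obs: list[int | None] = [None] * n
    pheno_obs: list[str | None] = [None] * n
    gi = {g: i for i, g in enumerate(GENOTYPES)}
    for k, row in enumerate(ped.to_dict("records")):
        g = row.get("genotype")
        if isinstance(g, str) and g.strip():
            geno_obs[k] = gi[canonical_genotype(g)]
        sex = str(row.get("sex", ""))
        ph = row.get("phenotype")
        if sex == "male" and isinstance(ph, str) and ph.strip() in ("white", "yellow"):
            pheno_obs[k] = ph.strip()
            if geno_obs[k] is not None and DOMINANCE[GENOTYPES[geno_obs[k]]] != pheno_obs[k]:
                raise DataError(
                    f"individual {ids[k]}: phenotype {ph!r} inconsistent with genotype "
                    f"{GENOTYPES[geno_obs[k]]!r} under dominance"
                )

    # cycle check (parent -> child edges must be acyclic)
    indeg = [0] * n
    children: list[list[int]] = [[] for _ in range(n)]
    for k in range(n):
        for par in (sires[k], dams[k]):
            if par is not None:
                children[par].append(k)
                indeg[k] += 1
    queue = [k for k in range(n) if indeg[k] == 0]
    seen = 0
    qi = 0
    deg = list(indeg)
    while qi < len(queue):
        u = queue[qi]
        qi += 1
        seen += 1
        for v in children[u]:
            deg[v] -= 1
            if deg[v] == 0:
                queue.append(v)
    if seen != n:
        raise DataError("cyclic parentage detected")

    # connected components over parent-child links
    parent_uf = list(range(n))

    def find(a: int) -> int:
        while parent_uf[a] != a:
            parent_uf[a] = parent_uf[parent_uf[a]]
            a = parent_uf[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_uf[ra] = rb

    for k in range(n):
        for par in (sires[k], dams[k]):
            if par is not None:
                union(k, par)
    comps: dict[int, list[int]] = {}
    for k in range(n):
        comps.setdefault(find(k), []).append(k)

    p = float(founder_prior)
    prior = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    yellow_mask = np.array([DOMINANCE[g] == "yellow" for g in GENOTYPES])

    out = np.full((n, 3), np.nan)
    consistent = np.ones(n, dtype=bool)
    for members in comps.values():
        m = len(members)
        if m > max_component:
            raise DataError(
                f"pedigree component of size {m} too large for exact enumeration "
                f"(cap {max_component}); partition the pedigree"
            )
        local = {g: j for j, g in enumerate(members)}
        # all 3^m configurations, one row each
        grids = np.meshgrid(*([np.arange(3)] * m), indexing="ij")
        C = np.stack([g.ravel() for g in grids], axis=1)  # (3^m, m)
        w = np.ones(C.shape[0])
        for j, k in enumerate(members):
            gcol = C[:, j]
            if sires[k] is None and dams[k] is None:
                w *= prior[gcol]
            elif sires[k] is not None and dams[k] is not None:
                w *= _T[C[:, local[sires[k]]], C[:, local[dams[k]]], gcol]
            else:
                raise DataError(f"individual {ids[k]} has exactly one recorded parent")
            if geno_obs[k] is not None:
                w *= (gcol == geno_obs[k])
            if pheno_obs[k] is not None:
                is_yel = yellow_mask[gcol]
                w *= is_yel if pheno_obs[k] == "yellow" else ~is_yel
        z = w.sum()
        if z <= 0:
            for k in members:
                consistent[k] = False
            continue
        for j, k in enumerate(members):
            for g in range(3):
                out[k, g] = w[C[:, j] == g].sum() / z
    res = pd.DataFrame(out, columns=[f"p_{g}" for g in GENOTYPES])
    res.insert(0, "id", ids)
    res["consistent"] = consistent
    return res


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

def families_from_pedigree(pedigree: pd.DataFrame,
                           min_male: int = 10, min_female: int = 10) -> pd.DataFrame:
    """Aggregate a pedigree table into per-family male phenotype counts.

    Applies the reliability filter (families need at least ``min_male``
    males and ``min_female`` females) as an ``excluded`` flag.  If parent
    genotypes are recorded the true cross label is carried along.
    """
    off = pedigree[pedigree["sire"].astype(str).str.len() > 0]
    rows = []
    geno = dict(zip(pedigree["id"].astype(str), pedigree.get("genotype", "")))
    for fam, grp in off.groupby("family"):
        males = grp[grp["sex"] == "male"]
        n_white = int((males["phenotype"] == "white").sum())
        n_yellow = int((males["phenotype"] == "yellow").sum())
        n_female = int((grp["sex"] == "female").sum())
        sire = str(grp["sire"].iloc[0])
        dam = str(grp["dam"].iloc[0])
        sg, dg = geno.get(sire, ""), geno.get(dam, "")
        cross = cross_label((sg, dg)) if sg and dg else None
        rows.append(dict(family=fam, sire=sire, dam=dam, cross=cross,
                         n_male_white=n_white, n_male_yellow=n_yellow,
                         n_female=n_female,
                         excluded=(n_white + n_yellow) < min_male or n_female < min_female))
    return pd.DataFrame(rows)


class MendelianInheritanceModel:
    """One-locus two-allele inheritance model for a set of families.

    Built from a per-family count table (columns ``family``,
    ``n_male_white``, ``n_male_yellow``, optional ``cross`` and
    ``excluded``); :meth:`fit` back-traces the maximum-likelihood cross
    of each family and runs the pooled segregation test of the observed
    male phenotype counts against the Mendelian expectations.
    """

    def __init__(self, families: pd.DataFrame, founder_prior: float | None = None):
        need = {"n_male_white", "n_male_yellow"}
        if not need.issubset(families.columns):
            raise ValueError(f"families table needs columns {sorted(need)}")
        self.families = families.reset_index(drop=True)
        self.founder_prior = founder_prior

    @classmethod
    def from_pedigree(cls, pedigree: pd.DataFrame, min_male: int = 10,
                      min_female: int = 10, **kw) -> "MendelianInheritanceModel":
        return cls(families_from_pedigree(pedigree, min_male, min_female), **kw)

    # statsmodels-style alias
    from_dataframe = from_pedigree

    def fit(self) -> "MendelianInheritanceResults":
        fams = self.families
        use = fams if "excluded" not in fams else fams[~fams["excluded"].astype(bool)]
        inferences: dict = {}
        rows = []
        for rec in use.to_dict("records"):
            nw, ny = int(rec["n_male_white"]), int(rec["n_male_yellow"])
            if nw + ny == 0:
                continue
            inf = infer_cross_from_offspring({"white": nw, "yellow": ny}, self.founder_prior)
            inferences[rec["family"]] = inf
            rows.append(dict(family=rec["family"], n_male_white=nw, n_male_yellow=ny,
                             ml_set="|".join(inf.ml_labels),
                             identifiability_class=inf.identifiability_class,
                             **{f"loglik_{k}": v for k, v in inf.log_likelihoods.items()}))
        inference_table = pd.DataFrame(rows)
        # segregation test against the recorded cross if present, else the inferred one
        test_fams = use.copy()
        if "cross" not in test_fams.columns or test_fams["cross"].isna().any():
            ml_single = {f: i.ml_labels[0] for f, i in inferences.items()}
            test_fams["cross"] = test_fams["family"].map(ml_single)
        seg = pooled_segregation_test(test_fams) if len(test_fams) else None
        return MendelianInheritanceResults(self, inference_table, inferences, seg)


@dataclass
class MendelianInheritanceResults:
    """Fitted inheritance results: per-family back-trace + pooled test."""

    model: MendelianInheritanceModel
    inference_table: pd.DataFrame
    inferences: dict = field(repr=False)
    segregation: ChiSqResult | None

    def summary(self) -> str:
        fams = self.model.families
        n_total = len(fams)
        n_used = len(self.inference_table)
        lines = [
            "One-locus two-allele Mendelian inheritance",
            "=" * 46,
            f"families: {n_total} ({n_total - n_used} excluded/empty)",
        ]
        if len(self.inference_table):
            counts = self.inference_table["identifiability_class"].value_counts()
            lines.append("inferred cross classes:")
            for k, v in counts.items():
                lines.append(f"  {k:<12} {v}")
        if self.segregation is not None:
            s = self.segregation
            lines.append(
                f"pooled segregation test: X2 = {s.statistic:.3f}, df = {s.df}, p = {s.p_value:.4f}"
            )
        return "\n".join(lines)
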