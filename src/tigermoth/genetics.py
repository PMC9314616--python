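"""One-locus two-allele genetics of the wood tiger moth hindwing colour.

A single autosomal locus with alleles ``W`` (white, dominant) and ``y``
(yellow, recessive) controls male hindwing colour: ``WW`` and ``Wy`` males
have white hindwings, ``yy`` males yellow ones.  Female hindwing colour
varies continuously and is treated as uninformative for the locus.

This module is the analytic core shared by the simulator and the
inference code: canonical genotype/cross labels, Punnett-square offspring
distributions and their pushforward through the dominance map.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations_with_replacement

__all__ = [
    "ALLELES",
    "GENOTYPES",
    "CROSS_TYPES",
    "DOMINANCE",
    "canonical_genotype",
    "canonical_cross",
    "cross_label",
    "gametes",
    "offspring_genotype_distribution",
    "male_phenotype_distribution",
]

#: Allele order used for canonicalisation (dominant first).
ALLELES = ("W", "y")

#: The three canonical genotype labels.
GENOTYPES = ("WW", "Wy", "yy")

#: Dominance map: phenotype of a male carrying each genotype.
DOMINANCE = {"WW": "white", "Wy": "white", "yy": "yellow"}

_ALLELE_RANK = {a: i for i, a in enumerate(ALLELES)}
_GENOTYPE_RANK = {g: i for i, g in enumerate(GENOTYPES)}


def canonical_genotype(g: str) -> str:
    """Return the canonical label for an allele pair (order-insensitive).

    Accepts any two-character combination of ``W`` and ``y`` (``"yW"`` is
    the same genotype as ``"Wy"``).
    """
    if not isinstance(g, str) or len(g) != 2:
        raise ValueError(f"not a two-allele genotype: {g!r}")
    a, b = g[0], g[1]
    if a not in _ALLELE_RANK or b not in _ALLELE_RANK:
        raise ValueError(f"unknown allele in genotype {g!r}")
    if _ALLELE_RANK[a] > _ALLELE_RANK[b]:
        a, b = b, a
    return a + b


def canonical_cross(g1: str, g2: str) -> tuple[str, str]:
    """Canonical (unordered) parent pair; symmetric in its arguments."""
    g1, g2 = canonical_genotype(g1), canonical_genotype(g2)
    if _GENOTYPE_RANK[g1] > _GENOTYPE_RANK[g2]:
        g1, g2 = g2, g1
    return (g1, g2)


def cross_label(cross: tuple[str, str]) -> str:
    g1, g2 = canonical_cross(*cross)
    return f"{g1}x{g2}"


#: All six distinct unordered parent-genotype pairs.
CROSS_TYPES = tuple(
    combinations_with_replacement(GENOTYPES, 2)
)  # canonical order by construction


def gametes(g: str) -> tuple[str, str]:
    """The two gametes a parent of genotype ``g`` produces (may coincide)."""
    g = canonical_genotype(g)
    return (g[0], g[1])


def offspring_genotype_distribution(cross: tuple[str, str]) -> dict[str, float]:
    """Punnett-square offspring genotype distribution for an unordered cross.

    Each parent contributes one of its two gametes uniformly at random;
    the four gamete combinations are enumerated exactly, so probabilities
    are exact multiples of 1/4 and sum to 1.

    Examples
    --------
    >>> offspring_genotype_distribution(("Wy", "Wy"))
    {'WW': 0.25, 'Wy': 0.5, 'yy': 0.25}
    >>> offspring_genotype_distribution(("WW", "yy"))
    {'Wy': 1.0}
    """
    g1, g2 = canonical_cross(*cross)
    probs: dict[str, Fraction] = {}
    for a in gametes(g1):
        for b in gametes(g2):
            child = canonical_genotype(a + b)
            probs[child] = probs.get(child, Fraction(0)) + Fraction(1, 4)
    return {g: float(p) for g, p in sorted(probs.items(), key=lambda kv: _GENOTYPE_RANK[kv[0]])}


def male_phenotype_distribution(cross: tuple[str, str]) -> dict[str, float]:
    """Male offspring phenotype distribution (white/yellow) for a cross.

    Pushforward of :func:`offspring_genotype_distribution` through the
    dominance map; the classic 3:1 white:yellow ratio for ``Wy x Wy``.
    Phenotypes with zero probability are included with probability 0 so
    the support is always ``{white, yellow}``.
    """
    geno = offspring_genotype_distribution(cross)
    out = {"white": 0.0, "yellow": 0.0}
    for g, p in geno.items():
        out[DOMINANCE[g]] += p
    return out
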