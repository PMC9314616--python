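"""Seeded synthetic pedigrees and multichannel specimen images.

The generator emulates the statistical structure of a wood tiger moth
laboratory rearing + multispectral photography study so that every
downstream stage (Mendelian inference, feature extraction, genotype
classification, vision modelling) is testable without external data:

* single-locus two-allele autosomal inheritance, W dominant over y;
* discrete male hindwing phenotypes (white/yellow) given by dominance;
* continuous female hindwing phenotypes scored on a 1-6
  yellow-orange-red scale whose category marginals default to
  3% yellow / 68% orange / 29% red independent of genotype;
* genotype-dependent per-ROI channel reflectances, including the UV
  differences that separate the two white genotypes (WW vs Wy);
* within-image pattern texture as markings of a configurable scale.

Every generator is a pure function of (config, seed): identical seeds
give byte-identical output.  Per-individual randomness is derived by
hashing (parent seed, index) through :class:`numpy.random.SeedSequence`
spawn keys, so output for specimen *i* does not depend on cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import DOMINANCE, GENOTYPES, canonical_cross, canonical_genotype, cross_label, gametes
from .specimen import CHANNELS, ROI_LABELS, ROI_NAMES, MultichannelSpecimen

__all__ = [
    "SimConfig",
    "AppearanceConfig",
    "default_appearance",
    "draw_founder_genotypes",
    "mate_pair",
    "assign_phenotype",
    "female_bin_edges",
    "simulate_families",
    "simulate_specimen",
    "generate_cohort",
]

_GIDX = {g: i for i, g in enumerate(GENOTYPES)}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, (np.random.SeedSequence, np.random.Generator)):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def _child_seed(seed: int, *index: int) -> np.random.SeedSequence:
    """Hash (seed, index path) into an independent stream."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(i) for i in index))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Pedigree simulation settings.

    ``offspring_per_family`` is either a fixed count or ``("poisson", lam)``
    for Poisson-distributed brood sizes.  ``female_genotype_shift`` moves the
    latent mean of the female colour score by ``-s, 0, +s`` for WW, Wy, yy;
    the default 0 encodes the observed decoupling of female hindwing colour
    from the male locus.
    """

    allele_freq_W: float = 0.5
    families: int = 50
    offspring_per_family: int | tuple = 40
    min_male_offspring: int = 10
    min_female_offspring: int = 10
    female_category_probs: tuple[float, float, float] = (0.03, 0.68, 0.29)
    female_genotype_shift: float = 0.0
    generations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_freq_W <= 1.0:
            raise ValueError(f"allele_freq_W must be in [0, 1], got {self.allele_freq_W}")
        if self.families < 1 or self.generations < 1:
            raise ValueError("families and generations must be positive")
        if self.min_male_offspring < 0 or self.min_female_offspring < 0:
            raise ValueError("minimum offspring counts must be non-negative")
        p = np.asarray(self.female_category_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("female_category_probs must be a 3-vector summing to 1")
        if isinstance(self.offspring_per_family, (int, np.integer)):
            if self.offspring_per_family < 1:
                raise ValueError("offspring_per_family must be positive")
        else:
            kind, lam = self.offspring_per_family
            if kind != "poisson" or lam <= 0:
                raise ValueError("offspring_per_family must be a count or ('poisson', lam)")

    def n_offspring(self, rng: np.random.Generator) -> int:
        if isinstance(self.offspring_per_family, (int, np.integer)):
            return int(self.offspring_per_family)
        _, lam = self.offspring_per_family
        return max(1, int(rng.poisson(lam)))


from functools import lru_cache


@lru_cache(maxsize=64)
def _female_bin_edges_cached(probs: tuple[float, float, float]) -> np.ndarray:
    py, po, pr = probs
    cum = np.array([py / 2, py, py + po / 2, py + po, py + po + pr / 2])
    return stats.norm.ppf(cum)


def female_bin_edges(category_probs: Sequence[float]) -> np.ndarray:
    """Latent-normal cut points for the six female colour scores.

    The female score is a standard-normal latent value binned into scores
    1-6 (yellows 1-2, oranges 3-4, reds 5-6).  Edges are placed by quantile
    matching so that at zero genotype shift the three category marginals
    equal ``category_probs``, with each category split evenly between its
    two scores.
    """
    py, po, pr = (float(p) for p in category_probs)
    return _female_bin_edges_cached((py, po, pr))


# ---------------------------------------------------------------------------
# genetics draws
# ---------------------------------------------------------------------------

def draw_founder_genotypes(n: int, p_W: float, seed) -> list[str]:
    """Draw ``n`` founder genotypes at Hardy-Weinberg proportions.

    Genotype probabilities are ``p_W**2, 2 p_W (1-p_W), (1-p_W)**2`` for
    WW, Wy, yy.
    """
    if not 0.0 <= p_W <= 1.0:
        raise ValueError(f"p_W must be in [0, 1], got {p_W}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _rng(seed)
    probs = [p_W**2, 2 * p_W * (1 - p_W), (1 - p_W) ** 2]
    idx = rng.choice(3, size=n, p=probs)
    return [GENOTYPES[i] for i in idx]


def mate_pair(g1: str, g2: str, n_offspring: int, seed) -> list[str]:
    """Mendelian offspring genotypes: one uniform gamete per parent each."""
    if n_offspring < 1:
        raise ValueError(f"n_offspring must be >= 1, got {n_offspring}")
    gam1, gam2 = gametes(canonical_genotype(g1)), gametes(canonical_genotype(g2))
    rng = _rng(seed)
    a = rng.integers(0, 2, size=n_offspring)
    b = rng.integers(0, 2, size=n_offspring)
    return [canonical_genotype(gam1[i] + gam2[j]) for i, j in zip(a, b)]


def assign_phenotype(g: str, sex: str, cfg: SimConfig, seed) -> str | int:
    """Phenotype of one individual.

    Males are deterministic through dominance (WW/Wy white, yy yellow).
    Females draw a latent normal value with mean shifted by genotype
    (``-s, 0, +s`` for WW, Wy, yy) and bin it to the 1-6 colour score.
    """
    g = canonical_genotype(g)
    if sex == "male":
        return DOMINANCE[g]
    if sex != "female":
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    rng = _rng(seed)
    shift = cfg.female_genotype_shift * (g.count("y") - 1)
    latent = rng.normal(loc=shift)
    edges = female_bin_edges(cfg.female_category_probs)
    return int(np.searchsorted(edges, latent) + 1)


def _female_scores(genotypes: Sequence[str], cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    shifts = np.array([cfg.female_genotype_shift * (g.count("y") - 1) for g in genotypes])
    latent = rng.normal(size=len(genotypes)) + shifts
    edges = female_bin_edges(cfg.female_category_probs)
    return np.searchsorted(edges, latent) + 1


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_families(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-generation pedigree of laboratory families.

    Returns ``(pedigree, families)``.  ``pedigree`` has one row per
    individual (id, family, sire, dam, generation, sex, genotype,
    phenotype, excluded); ``families`` one row per brood with parent
    genotypes, the cross label, male phenotype counts, female score
    counts and the exclusion flag.  Families with fewer than
    ``min_male_offspring`` males or ``min_female_offspring`` females are
    flagged ``excluded`` (never dropped), mirroring the >=10-offspring
    reliability filter used for segregation testing.

    With ``generations > 1`` each later generation mates offspring of the
    previous one (sire and dam drawn from different broods when possible),
    linking the generations for pedigree back-trace.
    """
    master = _rng(cfg.seed)
    ped_rows: list[dict] = []
    fam_rows: list[dict] = []
    # previous-generation offspring available as parents: (id, genotype, sex, family)
    prev_pool: list[tuple[str, str, str, str]] = []
    fam_counter = 0
    for gen in range(cfg.generations):
        next_pool: list[tuple[str, str, str, str]] = []
        for f in range(cfg.families):
            fam_counter += 1
            fam_id = f"F{fam_counter:04d}"
            fam_seed = _child_seed(cfg.seed, gen, f)
            rng = np.random.default_rng(fam_seed)
            if gen == 0 or not prev_pool:
                sire_g, dam_g = draw_founder_genotypes(2, cfg.allele_freq_W, rng)
                sire_id, dam_id = f"{fam_id}_P1", f"{fam_id}_P2"
                for pid, pg, psex in ((sire_id, sire_g, "male"), (dam_id, dam_g, "female")):
                    ped_rows.append(
                        dict(id=pid, family=fam_id, sire="", dam="", generation=gen,
                             sex=psex, genotype=pg,
                             phenotype=DOMINANCE[pg] if psex == "male" else "",
                             excluded=False)
                    )
            else:
                males = [p for p in prev_pool if p[2] == "male"]
                females = [p for p in prev_pool if p[2] == "female"]
                if not males or not females:
                    raise ValueError("previous generation lacks parents of both sexes")
                sire = males[rng.integers(len(males))]
                # prefer a dam from a different brood to avoid full-sib matings
                other = [p for p in females if p[3] != sire[3]] or females
                dam = other[rng.integers(len(other))]
                sire_id, sire_g = sire[0], sire[1]
                dam_id, dam_g = dam[0], dam[1]
            n = cfg.n_offspring(rng)
            kid_g = mate_pair(sire_g, dam_g, n, rng)
            kid_sex = np.where(rng.integers(0, 2, size=n) == 0, "male", "female")
            fem_idx = np.flatnonzero(kid_sex == "female")
            fem_scores = _female_scores([kid_g[i] for i in fem_idx], cfg, rng)
            score_of = dict(zip(fem_idx, fem_scores))
            n_male = int(np.sum(kid_sex == "male"))
            n_female = n - n_male
            excluded = (n_male < cfg.min_male_offspring) or (n_female < cfg.min_female_offspring)
            counts = {"white": 0, "yellow": 0}
            fem_counts = dict.fromkeys(range(1, 7), 0)
            for i in range(n):
                if kid_sex[i] == "male":
                    ph = DOMINANCE[kid_g[i]]
                    counts[ph] += 1
                else:
                    ph = int(score_of[i])
                    fem_counts[ph] += 1
                kid_id = f"{fam_id}_O{i:03d}"
                ped_rows.append(
                    dict(id=kid_id, family=fam_id, sire=sire_id, dam=dam_id,
                         generation=gen, sex=str(kid_sex[i]), genotype=kid_g[i],
                         phenotype=str(ph), excluded=excluded)
                )
                next_pool.append((kid_id, kid_g[i], str(kid_sex[i]), fam_id))
            fam_rows.append(
                dict(family=fam_id, generation=gen, sire=sire_id, dam=dam_id,
                     sire_genotype=sire_g, dam_genotype=dam_g,
                     cross=cross_label((sire_g, dam_g)),
                     n_male_white=counts["white"], n_male_yellow=counts["yellow"],
                     n_female=n_female,
                     **{f"female_{s}": fem_counts[s] for s in range(1, 7)},
                     excluded=excluded)
            )
        prev_pool = next_pool
        _ = master  # master stream reserved for future cross designs
    return pd.DataFrame(ped_rows), pd.DataFrame(fam_rows)


# ---------------------------------------------------------------------------
# specimen image simulation
# ---------------------------------------------------------------------------

def _default_roi_boxes(shape: tuple[int, int]) -> dict[str, tuple[int, int, int, int]]:
    """Fixed single-specimen layout: wings left, body (TH over AB) right."""
    h, w = shape
    r = lambda a, b: (int(a * h), int(b * h))
    c = lambda a, b: (int(a * w), int(b * w))
    return {
        "FW": r(0.08, 0.46) + c(0.04, 0.38),
        "HW": r(0.54, 0.92) + c(0.04, 0.38),
        "TH": r(0.08, 0.42) + c(0.42, 0.58),
        "AB": r(0.50, 0.92) + c(0.42, 0.58),
    }


#: Per-(genotype, sex) mean reflectances per ROI and channel.  Defaults encode
#: the study-system effects: lower thorax/abdomen UV in WW than Wy, a hindwing
#: UV difference between the two white genotypes, and yy hindwings with high
#: long-wave / low short-wave reflectance.  Female hindwing colour is common
#: to all genotypes (orange) — the locus is phenotypically silent in females.
_DEFAULT_MEANS = {
    ("WW", "male"): {
        "FW": {"uv": 0.10, "sw": 0.55, "mw": 0.60, "lw": 0.65},
        "HW": {"uv": 0.12, "sw": 0.60, "mw": 0.65, "lw": 0.70},
        "TH": {"uv": 0.08, "sw": 0.30, "mw": 0.35, "lw": 0.40},
        "AB": {"uv": 0.10, "sw": 0.35, "mw": 0.40, "lw": 0.45},
    },
    ("Wy", "male"): {
        "FW": {"uv": 0.10, "sw": 0.55, "mw": 0.60, "lw": 0.65},
        "HW": {"uv": 0.22, "sw": 0.60, "mw": 0.65, "lw": 0.70},
        "TH": {"uv": 0.18, "sw": 0.30, "mw": 0.35, "lw": 0.40},
        "AB": {"uv": 0.20, "sw": 0.35, "mw": 0.40, "lw": 0.45},
    },
    ("yy", "male"): {
        "FW": {"uv": 0.10, "sw": 0.50, "mw": 0.58, "lw": 0.66},
        "HW": {"uv": 0.10, "sw": 0.25, "mw": 0.55, "lw": 0.80},
        "TH": {"uv": 0.12, "sw": 0.25, "mw": 0.40, "lw": 0.55},
        "AB": {"uv": 0.12, "sw": 0.30, "mw": 0.50, "lw": 0.65},
    },
}
for _g in GENOTYPES:  # females: orange hindwing regardless of genotype
    _f = {roi: dict(ch) for roi, ch in _DEFAULT_MEANS[(_g, "male")].items()}
    _f["HW"] = {"uv": 0.15, "sw": 0.35, "mw": 0.60, "lw": 0.75}
    _DEFAULT_MEANS[(_g, "female")] = _f

_DEFAULT_MARKINGS = {
    ("WW", "male"): dict(scale=8, count=6, reflectance=0.15),
    ("Wy", "male"): dict(scale=8, count=6, reflectance=0.15),
    ("yy", "male"): dict(scale=12, count=8, reflectance=0.15),
}
for _g in GENOTYPES:
    _DEFAULT_MARKINGS[(_g, "female")] = dict(_DEFAULT_MARKINGS[(_g, "male")])


@dataclass
class AppearanceConfig:
    """Appearance of simulated specimens.

    ``means[(genotype, sex)][roi][channel]`` is the target mean reflectance
    (0-1).  ``pixel_sd`` is independent per-pixel Gaussian noise;
    ``specimen_sd`` is the between-specimen biological scatter of each
    ROI x channel mean (one offset drawn per specimen).  ``markings``
    gives per-(genotype, sex) forewing marking scale (px), count and
    reflectance; markings provide the pattern texture the granularity
    analysis measures.
    """

    image_shape: tuple[int, int] = (96, 96)
    means: dict = field(default_factory=lambda: {k: {r: dict(c) for r, c in v.items()} for k, v in _DEFAULT_MEANS.items()})
    markings: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MARKINGS.items()})
    pixel_sd: float = 0.02
    specimen_sd: float = 0.04
    background: float = 0.05
    roi_boxes: dict | None = None

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 16 or w < 16:
            raise ValueError("image too small for the ROI layout")
        if self.roi_boxes is None:
            self.roi_boxes = _default_roi_boxes(self.image_shape)
        if set(self.roi_boxes) != set(ROI_NAMES):
            raise ValueError(f"roi_boxes must define exactly {ROI_NAMES}")
        boxes = []
        for roi, (r0, r1, c0, c1) in self.roi_boxes.items():
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"ROI {roi} box {(r0, r1, c0, c1)} does not fit the image")
            boxes.append((roi, r0, r1, c0, c1))
        for i, (ra, a0, a1, b0, b1) in enumerate(boxes):
            for rb, c0, c1, d0, d1 in (x for x in boxes[i + 1:]):
                if a0 < c1 and c0 < a1 and b0 < d1 and d0 < b1:
                    raise ValueError(f"ROI boxes {ra} and {rb} overlap")
        for key, rois in self.means.items():
            for roi, chans in rois.items():
                for ch, m in chans.items():
                    if not 0.0 <= m <= 1.0:
                        raise ValueError(f"mean reflectance out of [0,1] for {key}/{roi}/{ch}")
        if not (0.0 <= self.pixel_sd <= 1.0 and 0.0 <= self.specimen_sd <= 1.0):
            raise ValueError("pixel_sd and specimen_sd must be in [0, 1]")
        for key, mk in self.markings.items():
            if mk["scale"] < 2 or mk["scale"] > min(h, w):
                raise ValueError(f"marking scale for {key} must be in [2, image size]")


def default_appearance(**overrides) -> AppearanceConfig:
    """The default appearance configuration, optionally with field overrides."""
    return AppearanceConfig(**overrides)


def simulate_specimen(g: str, sex: str, app: AppearanceConfig, seed,
                      specimen_id: str | None = None) -> MultichannelSpecimen:
    """Render one specimen: four channel rasters + ROI mask + truth labels.

    Per ROI and channel the reflectance is ``mean + specimen offset +
    pixel noise`` (clipped to [0, 1]); square markings of the configured
    scale are stamped into the forewing across all channels.  With both
    noise terms zero and no markings, ROI means equal the configured
    means exactly.
    """
    g = canonical_genotype(g)
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    key = (g, sex)
    if key not in app.means:
        raise ValueError(f"appearance config has no entry for {key}")
    rng = _rng(seed)
    h, w = app.image_shape
    mask = np.zeros((h, w), dtype=np.int64)
    for roi in ROI_NAMES:
        r0, r1, c0, c1 = app.roi_boxes[roi]
        mask[r0:r1, c0:c1] = ROI_LABELS[roi]
    channels = {c: np.full((h, w), app.background, dtype=float) for c in CHANNELS}
    floored = False
    for roi in ROI_NAMES:  # fixed order -> deterministic draw sequence
        r0, r1, c0, c1 = app.roi_boxes[roi]
        for ch in CHANNELS:
            base = app.means[key][roi][ch]
            if app.specimen_sd > 0:
                base = base + rng.normal(0.0, app.specimen_sd)
            tile = np.full((r1 - r0, c1 - c0), base)
            if app.pixel_sd > 0:
                tile = tile + rng.normal(0.0, app.pixel_sd, size=tile.shape)
            channels[ch][r0:r1, c0:c1] = tile
    mk = app.markings.get(key)
    if mk and mk["count"] > 0:
        r0, r1, c0, c1 = app.roi_boxes["FW"]
        s = int(mk["scale"])
        for _ in range(int(mk["count"])):
            rr = int(rng.integers(r0, max(r0 + 1, r1 - s)))
            cc = int(rng.integers(c0, max(c0 + 1, c1 - s)))
            val = mk["reflectance"]
            for ch in CHANNELS:
                patch = np.full((min(rr + s, r1) - rr, min(cc + s, c1) - cc), val)
                if app.pixel_sd > 0:
                    patch = patch + rng.normal(0.0, app.pixel_sd, size=patch.shape)
                channels[ch][rr:min(rr + s, r1), cc:min(cc + s, c1)] = patch
    for ch in CHANNELS:
        lo, hi = channels[ch].min(), channels[ch].max()
        if lo < 0 or hi > 1:
            floored = True
        np.clip(channels[ch], 0.0, 1.0, out=channels[ch])
    sid = specimen_id if specimen_id is not None else f"{g}_{sex}"
    return MultichannelSpecimen(
        sid, channels, mask,
        meta=dict(genotype=g, sex=sex, clipped=floored),
    )


def generate_cohort(n_per_genotype, sex: str, app: AppearanceConfig, seed: int
                    ) -> tuple[list[MultichannelSpecimen], pd.DataFrame]:
    """Simulate a cohort of specimens plus its truth table.

    ``n_per_genotype`` is a ``(n_WW, n_Wy, n_yy)`` triple or a mapping
    genotype -> count.  Each specimen gets an independent stream hashed
    from ``(seed, index)``, so adding specimens never changes earlier ones.
    """
    if isinstance(n_per_genotype, dict):
        counts = [(g, int(n_per_genotype.get(g, 0))) for g in GENOTYPES]
    else:
        counts = list(zip(GENOTYPES, (int(n) for n in n_per_genotype)))
    if any(n < 0 for _, n in counts):
        raise ValueError("specimen counts must be non-negative")
    cohort, rows = [], []
    idx = 0
    for g, n in counts:
        for _ in range(n):
            sid = f"{g}_{idx:04d}"
            spec = simulate_specimen(g, sex, app, _child_seed(seed, idx), specimen_id=sid)
            cohort.append(spec)
            rows.append(dict(id=sid, genotype=g, sex=sex, seed_index=idx))
            idx += 1
    return cohort, pd.DataFrame(rows)
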