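import numpy as np
import pandas as pd
import pytest

from tigermoth.simulate import AppearanceConfig, default_appearance, generate_cohort


def noiseless_appearance(**overrides) -> AppearanceConfig:
    """Appearance config with every stochastic term switched off."""
    app = default_appearance(pixel_sd=0.0, specimen_sd=0.0, **overrides)
    for key in app.markings:
        app.markings[key] = dict(scale=8, count=0, reflectance=0.15)
    return app


@pytest.fixture(scope="session")
def app_noiseless() -> AppearanceConfig:
    return noiseless_appearance()


@pytest.fixture(scope="session")
def app_default() -> AppearanceConfig:
    return default_appearance()


@pytest.fixture(scope="session")
def small_cohort(app_default):
    """A tiny mixed-genotype male cohort with its truth table."""
    return generate_cohort((4, 4, 4), "male", app_default, seed=11)


def random_pedigree(rng: np.random.Generator, n_max: int = 8) -> pd.DataFrame:
    """Random acyclic pedigree of <= n_max individuals with simulated truth.

    Founder pairs mate and produce offspring; male phenotypes are
    observed through dominance, genotypes are hidden.  Used to compare
    exact enumeration against the brute-force oracle.
    """
    from tigermoth.genetics import DOMINANCE, gametes

    n_founders = int(rng.integers(2, 5)) // 2 * 2  # even: 2 or 4
    rows = []
    genos = {}
    for i in range(n_founders):
        g = ["WW", "Wy", "yy"][rng.choice(3, p=[0.25, 0.5, 0.25])]
        sex = "male" if i % 2 == 0 else "female"
        pid = f"P{i}"
        genos[pid] = g
        observe = sex == "male" and rng.random() < 0.7
        rows.append(dict(id=pid, family="F0", sire="", dam="", sex=sex,
                         genotype="", phenotype=DOMINANCE[g] if observe else ""))
    n_kids = int(rng.integers(1, n_max - n_founders + 1))
    for k in range(n_kids):
        pair = int(rng.integers(n_founders // 2))
        sire, dam = f"P{2 * pair}", f"P{2 * pair + 1}"
        a = gametes(genos[sire])[rng.integers(2)]
        b = gametes(genos[dam])[rng.integers(2)]
        g = "".join(sorted(a + b))  # 'Wy' sorts correctly, 'yW' -> 'Wy'
        g = {"WW": "WW", "Wy": "Wy", "yy": "yy", "yW": "Wy"}.get(g, g)
        sex = "male" if rng.random() < 0.5 else "female"
        observe = sex == "male" and rng.random() < 0.8
        rows.append(dict(id=f"K{k}", family="F0", sire=sire, dam=dam, sex=sex,
                         genotype="", phenotype=DOMINANCE[g] if observe else ""))
    return pd.DataFrame(rows)


def brute_force_marginals(ped: pd.DataFrame, founder_prior: float = 0.5) -> dict:
    """Naive pure-Python genotype posterior by looping over all assignments.

    Independent oracle for propagate_pedigree_genotypes: dict-based
    Punnett transmission, explicit product over individuals, no numpy
    vectorisation.
    """
    from itertools import product as iproduct

    G = ("WW", "Wy", "yy")
    p = founder_prior
    prior = {"WW": p * p, "Wy": 2 * p * (1 - p), "yy": (1 - p) ** 2}

    def trans(s, d, c):
        tot = 0.0
        for a in (s[0], s[1]):
            for b in (d[0], d[1]):
                child = "".join(sorted(a + b, key=lambda x: {"W": 0, "y": 1}[x]))
                if child == c:
                    tot += 0.25
        return tot

    ids = ped["id"].tolist()
    recs = ped.set_index("id").to_dict("index")
    weights = {i: {g: 0.0 for g in G} for i in ids}
    total = 0.0
    for assign in iproduct(G, repeat=len(ids)):
        conf = dict(zip(ids, assign))
        w = 1.0
        for i in ids:
            r = recs[i]
            g = conf[i]
            if str(r["sire"]):
                w *= trans(conf[str(r["sire"])], conf[str(r["dam"])], g)
            else:
                w *= prior[g]
            ph = str(r.get("phenotype", ""))
            if r.get("sex") == "male" and ph in ("white", "yellow"):
                is_yellow = g == "yy"
                if (ph == "yellow") != is_yellow:
                    w = 0.0
            if w == 0.0:
                break
        total += w
        for i in ids:
            weights[i][conf[i]] += w
    if total == 0:
        return {}
    return {i: {g: weights[i][g] / total for g in G} for i in ids}
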