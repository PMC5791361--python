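"""Synthetic mass-spawning populations for offline pipeline testing.

The generator emulates a single-generation aquaculture breeding design:
a set of sires and dams spawn in tanks of three males × three females,
producing full-sib families with a long-tailed size distribution;
offspring genotypes arise by Mendelian gene dropping of unlinked
biallelic SNPs from Hardy-Weinberg founders; quantitative traits are
polygenic with a stock-origin fixed effect; genotype calls are masked
missing-completely-at-random.  Defaults reproduce the study design this
package targets: 35 families from 16 sires × 31 dams, 752 genotyped
offspring, 14,448 SNPs with mean MAF ≈ 0.28 and 14.8% missingness, and
growth traits with pedigree heritabilities 0.11-0.42.

Because loci are unlinked and effects are drawn i.i.d., predictive
ability on these populations reflects capture of family relationships,
not marker-QTL linkage disequilibrium — the generator is a testbed for
the machinery, not a surrogate for the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import GenotypeMatrix, Pedigree, PhenotypeTable

__all__ = ["TraitConfig", "SimConfig", "simulate_pedigree", "simulate_genotypes",
           "simulate_phenotypes", "apply_missingness", "simulate_dataset"]


@dataclass
class TraitConfig:
    mean: float
    sd: float
    h2: float
    stock_effect: float = 0.0  # additive shift applied to F1-origin fish

    def __post_init__(self):
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")


@dataclass
class BinaryTraitConfig:
    incidence: float
    h2_liability: float = 0.10

    def __post_init__(self):
        if not 0 < self.incidence < 1:
            raise ValueError("incidence must lie in (0, 1)")


def _default_traits() -> dict:
    # stock effects sized at ~0.3 phenotypic SD: a visible but minor
    # fixed effect, as expected between wild and F1 broodstock origins
    return {
        "weight": TraitConfig(mean=3.0, sd=0.35, h2=0.42, stock_effect=0.10),
        "length": TraitConfig(mean=58.2, sd=2.10, h2=0.42, stock_effect=0.60),
        "condition_index": TraitConfig(mean=15.0, sd=1.02, h2=0.11, stock_effect=0.30),
    }


def _default_binary() -> dict:
    return {
        "skin_fluke": BinaryTraitConfig(incidence=0.043),
        "deformity": BinaryTraitConfig(incidence=0.176),
    }


@dataclass
class SimConfig:
    """Design parameters of the simulated population.

    ``n_offspring`` is the total number of genotyped/phenotyped
    offspring; family sizes follow a log-normal distribution truncated
    to ``family_size_range`` and rescaled to that total.
    """

    n_sires: int = 16
    n_dams: int = 31
    n_families: int = 35
    n_offspring: int = 752
    family_size_range: tuple[int, int] = (3, 108)
    n_markers: int = 14448
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.148
    traits: dict = field(default_factory=_default_traits)
    binary_traits: dict = field(default_factory=_default_binary)
    genetic_mode: str = "marker"  # or "pedigree" (infinitesimal model)
    derive_condition: bool = False  # condition index from W/L^3 instead of own trait
    tank_size: int = 3  # males and females per spawning tank

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_families > self.n_sires * self.n_dams:
            raise ValueError("more families than possible sire×dam pairs")
        if self.n_families < max(self.n_sires, self.n_dams):
            raise ValueError(
                "n_families must be >= max(n_sires, n_dams) so every "
                "parent can produce at least one family"
            )
        if self.genetic_mode not in ("marker", "pedigree"):
            raise ValueError(f"unknown genetic_mode {self.genetic_mode!r}")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def _family_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.family_size_range
    # log-normal sigma ~0.8 gives the heavy right tail seen in
    # mass-spawning (a few dominant pairs); rescale to the exact total
    raw = rng.lognormal(mean=0.0, sigma=0.8, size=cfg.n_families)
    sizes = raw / raw.sum() * cfg.n_offspring
    sizes = np.clip(np.round(sizes).astype(int), lo, hi)
    # repair rounding drift toward the exact configured total
    diff = cfg.n_offspring - sizes.sum()
    order = rng.permutation(cfg.n_families)
    i = 0
    while diff != 0:
        j = order[i % cfg.n_families]
        step = 1 if diff > 0 else -1
        if lo <= sizes[j] + step <= hi:
            sizes[j] += step
            diff -= step
        i += 1
    return sizes


def simulate_pedigree(cfg: SimConfig, seed: int | None = None) -> Pedigree:
    """Founders plus full-sib families from 3×3 spawning tanks.

    Every configured sire and dam produces at least one family; families
    are distinct sire×dam pairs whose members share a tank.
    """
    rng = np.random.default_rng(seed)
    sires = [f"S{i+1}" for i in range(cfg.n_sires)]
    dams = [f"D{i+1}" for i in range(cfg.n_dams)]
    # founders are wild or F1 broodstock
    origin = {
        p: ("wild" if rng.random() < 0.5 else "F1") for p in sires + dams
    }

    # tanks: consecutive groups of `tank_size` dams; sires cycle through
    # a shuffled list so each appears in >=1 tank
    dam_order = rng.permutation(cfg.n_dams)
    sire_cycle = list(rng.permutation(cfg.n_sires))
    while len(sire_cycle) < cfg.n_dams:  # enough to staff all tanks
        sire_cycle += list(rng.permutation(cfg.n_sires))
    tanks = []
    si = 0
    for t in range(0, cfg.n_dams, cfg.tank_size):
        tank_dams = [dams[i] for i in dam_order[t: t + cfg.tank_size]]
        tank_sires: list[str] = []
        while len(tank_sires) < min(cfg.tank_size, cfg.n_sires):
            cand = sires[sire_cycle[si % len(sire_cycle)]]
            si += 1
            if cand not in tank_sires:
                tank_sires.append(cand)
        tanks.append((tank_sires, tank_dams))

    # one family per dam, sire chosen from her tank; extra families pair
    # unused combinations within a tank
    pairs: list[tuple[str, str]] = []
    used_sires: set[str] = set()
    for tank_sires, tank_dams in tanks:
        for j, dam in enumerate(tank_dams):
            # favour sires not yet used anywhere to cover all 16
            unused = [s for s in tank_sires if s not in used_sires]
            sire = unused[0] if unused else tank_sires[int(rng.integers(len(tank_sires)))]
            pairs.append((sire, dam))
            used_sires.add(sire)
    # repair: any globally unused sire replaces a sire that has >=2 families,
    # within a tank containing both
    def sire_counts():
        c: dict[str, int] = {}
        for s, _ in pairs:
            c[s] = c.get(s, 0) + 1
        return c

    for tank_sires, tank_dams in tanks:
        counts = sire_counts()
        for s in tank_sires:
            if counts.get(s, 0) == 0:
                for idx, (ps, pd_) in enumerate(pairs):
                    if pd_ in tank_dams and counts.get(ps, 0) >= 2:
                        pairs[idx] = (s, pd_)
                        counts = sire_counts()
                        break

    extra = cfg.n_families - len(pairs)
    attempts = 0
    existing = set(pairs)
    while extra > 0 and attempts < 10000:
        tank_sires, tank_dams = tanks[int(rng.integers(len(tanks)))]
        cand = (
            tank_sires[int(rng.integers(len(tank_sires)))],
            tank_dams[int(rng.integers(len(tank_dams)))],
        )
        if cand not in existing:
            pairs.append(cand)
            existing.add(cand)
            extra -= 1
        attempts += 1
    if extra > 0:
        raise ValueError("could not place the configured number of families")

    sizes = _family_sizes(cfg, rng)
    rows = [
        {"id": p, "sire": None, "dam": None, "stock_origin": origin[p]}
        for p in sires + dams
    ]
    child = 0
    for (sire, dam), size in zip(pairs, sizes):
        child_origin = "wild" if origin[sire] == origin[dam] == "wild" else "F1"
        for _ in range(size):
            child += 1
            rows.append(
                {
                    "id": f"O{child}",
                    "sire": sire,
                    "dam": dam,
                    "stock_origin": child_origin,
                }
            )
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# genotypes (gene dropping)
# ---------------------------------------------------------------------------


def simulate_genotypes(
    p: Pedigree, cfg: SimConfig, seed: int | None = None
) -> GenotypeMatrix:
    """Gene-drop unlinked biallelic SNPs down the pedigree.

    Founder allele frequencies are uniform on [maf_low, maf_high] per
    marker; founders are Hardy-Weinberg draws; each offspring inherits
    one uniformly chosen allele per parent per locus.
    """
    rng = np.random.default_rng(seed)
    m = cfg.n_markers
    freq = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)
    order = p.topological_order()
    pos = {ind: i for i, ind in enumerate(order)}
    parents = {r.id: (r.sire, r.dam) for r in p.records.itertuples()}
    n = len(order)
    # two gametes per individual, 0/1 allele codes
    gam = np.zeros((n, 2, m), dtype=np.int8)
    for ind in order:
        i = pos[ind]
        s, d = parents[ind]
        for slot, par in enumerate((s, d)):
            if par is None:
                gam[i, slot] = rng.random(m) < freq
            else:
                pick = rng.integers(0, 2, size=m)
                gam[i, slot] = gam[pos[par], pick, np.arange(m)]
    dosages = gam.sum(axis=1).astype(float)
    # return in pedigree record order
    perm = np.array([pos[i] for i in p.ids])
    dosages = dosages[perm]
    marker_ids = [f"M{j+1}" for j in range(m)]
    return GenotypeMatrix(
        p.ids, marker_ids, dosages, np.zeros_like(dosages, dtype=bool)
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _breeding_values_pedigree(
    p: Pedigree, sigma2_g: float, rng: np.random.Generator
) -> pd.Series:
    """Infinitesimal-model additive values: founders N(0, σ²g), offspring
    mid-parent plus Mendelian sampling (half σ²g for non-inbred parents)."""
    order = p.topological_order()
    parents = {r.id: (r.sire, r.dam) for r in p.records.itertuples()}
    a: dict[str, float] = {}
    for ind in order:
        s, d = parents[ind]
        if s is None and d is None:
            a[ind] = rng.normal(0.0, np.sqrt(sigma2_g))
        else:
            mid = 0.5 * ((a[s] if s else 0.0) + (a[d] if d else 0.0))
            n_known = (s is not None) + (d is not None)
            seg_var = sigma2_g * (1.0 - 0.25 * n_known)
            a[ind] = mid + rng.normal(0.0, np.sqrt(seg_var))
    return pd.Series({i: a[i] for i in p.ids})


def _breeding_values_marker(
    g: GenotypeMatrix, ids, sigma2_g: float, rng: np.random.Generator
) -> tuple[pd.Series, np.ndarray]:
    """Additive values Wα with i.i.d. marker effects of equal variance.

    Effects are drawn α_j ~ N(0, σ²g·φ) with φ = 1/Σ2pq from the
    realized sample frequencies, so the genetic variance of Wα matches
    σ²g in expectation.
    """
    gpos = {v: i for i, v in enumerate(g.individual_ids)}
    rows = np.array([gpos[i] for i in ids])
    X = g.dosages[rows]
    pfreq = X.mean(axis=0) / 2.0
    poly = (pfreq > 0) & (pfreq < 1)
    W = X[:, poly] - 2.0 * pfreq[poly]
    phi = 1.0 / float(np.sum(2.0 * pfreq[poly] * (1.0 - pfreq[poly])))
    alpha = rng.normal(0.0, np.sqrt(sigma2_g * phi), size=int(poly.sum()))
    bv = W @ alpha
    full_alpha = np.zeros(g.n_markers)
    full_alpha[poly] = alpha
    return pd.Series(bv, index=list(ids)), full_alpha


def simulate_phenotypes(
    g: GenotypeMatrix,
    p: Pedigree,
    cfg: SimConfig,
    seed: int | None = None,
) -> PhenotypeTable:
    """Polygenic traits for the offspring generation.

    Marker mode draws per-locus effects of equal variance (the gBLUP
    generative model); pedigree mode uses the infinitesimal model.
    σ²g = h²·sd², σ²e = (1−h²)·sd²; the stock-origin effect shifts
    F1-origin fish; binary traits arise from a liability threshold at
    the configured incidence.
    """
    rng = np.random.default_rng(seed)
    offspring = [
        r.id for r in p.records.itertuples() if r.sire is not None or r.dam is not None
    ]
    origin = p.records.set_index("id")["stock_origin"]
    is_f1 = np.array([origin[i] != "wild" for i in offspring], dtype=float)
    data: dict = {"id": offspring, "stock_origin": origin[offspring].to_numpy()}
    true_bv: dict = {}
    for name, tc in cfg.traits.items():
        if cfg.derive_condition and name == "condition_index":
            continue
        s2g = tc.h2 * tc.sd**2
        s2e = (1.0 - tc.h2) * tc.sd**2
        if cfg.genetic_mode == "pedigree" or s2g == 0:
            bv_all = _breeding_values_pedigree(p, max(s2g, 0.0), rng)
            bv = bv_all[offspring].to_numpy()
        else:
            bv_series, _ = _breeding_values_marker(g, offspring, s2g, rng)
            bv = bv_series.to_numpy()
        y = tc.mean + bv + rng.normal(0.0, np.sqrt(s2e), size=len(offspring))
        y = y + tc.stock_effect * is_f1
        data[name] = y
        true_bv[name] = bv
    if cfg.derive_condition and "condition_index" in cfg.traits:
        from .data_model import condition_index as _ci

        data["condition_index"] = _ci(
            np.maximum(np.asarray(data["weight"]), 1e-3),
            np.maximum(np.asarray(data["length"]), 1e-3),
        )
    for name, bc in cfg.binary_traits.items():
        s2g = bc.h2_liability
        bv_all = _breeding_values_pedigree(p, s2g, rng)
        liab = bv_all[offspring].to_numpy() + rng.normal(
            0.0, np.sqrt(1.0 - s2g), size=len(offspring)
        )
        from scipy.stats import norm

        thr = norm.ppf(1.0 - bc.incidence)
        data[name] = (liab > thr).astype(int)
    table = PhenotypeTable(pd.DataFrame(data))
    table.true_breeding_values = pd.DataFrame(true_bv, index=offspring)
    return table


def apply_missingness(
    g: GenotypeMatrix, rate: float, seed: int | None = None
) -> GenotypeMatrix:
    """Mask calls i.i.d. Bernoulli(rate) (missing completely at random)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return g
    rng = np.random.default_rng(seed)
    mask = g.missing_mask | (rng.random(g.dosages.shape) < rate)
    return GenotypeMatrix(
        g.individual_ids, g.marker_ids, g.dosages, mask, g.real_valued
    )


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # with missingness applied
    genotypes_complete: GenotypeMatrix  # pre-missingness truth
    phenotypes: PhenotypeTable
    config: SimConfig
    seed: int | None


def simulate_dataset(cfg: SimConfig, seed: int | None = None) -> SimulatedDataset:
    """Full pipeline: pedigree → genotypes → phenotypes → missingness.

    Deterministic: the same config and seed give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4 = rng.integers(0, 2**31 - 1, size=4)
    ped = simulate_pedigree(cfg, seed=int(s1))
    geno = simulate_genotypes(ped, cfg, seed=int(s2))
    pheno = simulate_phenotypes(geno, ped, cfg, seed=int(s3))
    geno_missing = apply_missingness(geno, cfg.missing_rate, seed=int(s4))
    # analyses consume offspring rows only
    off = [r.id for r in ped.records.itertuples() if r.sire is not None]
    gpos = {v: i for i, v in enumerate(geno.individual_ids)}
    rows = np.array([gpos[i] for i in off])
    return SimulatedDataset(
        pedigree=ped,
        genotypes=geno_missing.select_individuals(rows),
        genotypes_complete=geno.select_individuals(rows),
        phenotypes=pheno,
        config=cfg,
        seed=seed,
    )
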