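"""Closed-nucleus multi-tier population simulator.

Emulates the data structure the updating method is exact for: a nucleus
tier under truncation selection whose selected animals supply both
parents of a commercial tier, which never contributes descendants back
to the nucleus.  Breeding values follow the infinitesimal model
(founders N(0, σ²_u); offspring mid-parent plus Mendelian sampling with
variance ½σ²_u(1 − (F_s + F_d)/2)); an optional marker-effect mode makes
true breeding values the sum of additive marker effects instead.
Phenotypes are y = μ + (shared covariate · coefficient) + u + e.

Everything is deterministic given the seed; exported files round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree, TierPartition, build_pedigree, partition_tiers


@dataclass
class SimulationConfig:
    n_founders: int = 40
    generations_nucleus: int = 3
    generations_commercial: int = 1
    n_matings_nucleus: int = 40
    n_matings_commercial: int = 50
    offspring_per_mating: int = 3
    offspring_per_mating_commercial: int = 4
    n_markers: int = 0
    sigma_u: float = 0.3
    sigma_e: float = 0.7
    mean: float = 10.0
    covariate_coef: float | None = None  # shared fixed-effect slope, None = absent
    selection: str = "phenotype"  # none | phenotype | ebv
    selected_proportion: float = 0.5
    marker_effects: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.sigma_u <= 0 or self.sigma_e <= 0:
            raise ValueError("variance components must be positive")
        if not (0 < self.selected_proportion <= 1):
            raise ValueError("selected proportion must lie in (0, 1]")
        if self.selection not in ("none", "phenotype", "ebv"):
            raise ValueError(f"unknown selection rule {self.selection!r}")


@dataclass
class SimulatedPopulation:
    ped: Pedigree
    tiers: dict            # label -> "nucleus" | "commercial"
    tbv: np.ndarray        # true breeding values, internal order
    phenotypes: pd.DataFrame  # animal, covariate (optional), trait
    genotypes: pd.DataFrame | None  # animals × markers, index = labels
    config: SimulationConfig
    part: TierPartition = field(init=False)

    def __post_init__(self):
        current = [lab for lab, t in self.tiers.items() if t == "commercial"]
        self.part = partition_tiers(self.ped, current)

    def data_split(self):
        """(external PhenotypeData, current PhenotypeData) per the tier labels."""
        from .updating import PhenotypeData

        df = self.phenotypes
        is_cur = df["animal"].map(self.tiers).eq("commercial").to_numpy()
        has_cov = "covariate" in df.columns

        def mk(mask, mean_name):
            sub = df[mask]
            cols = [np.ones(len(sub))]
            names = [mean_name]
            if has_cov:
                cols.append(sub["covariate"].to_numpy())
                names.append("covariate")
            return PhenotypeData(
                y=sub["trait"].to_numpy(),
                X=np.column_stack(cols),
                x_names=names,
                animals=sub["animal"].tolist(),
            )

        return mk(~is_cur, "mean_ext"), mk(is_cur, "mean_cur")


def _quick_ebv(records, sigma_u, sigma_e):
    """Mean-corrected P-BLUP on the data so far, for selection='ebv'."""
    from . import mme
    from .relatedness import build_A_inverse

    ped, y, animals = records
    Ainv = build_A_inverse(ped)
    rows = np.arange(len(animals))
    cols = np.array([ped.index[a] for a in animals])
    Z = sp.csr_matrix((np.ones(len(animals)), (rows, cols)), shape=(len(animals), ped.n))
    X = np.ones((len(animals), 1))
    sys = mme.build_joint_mme(y, X, Z, Ainv, sigma_u, sigma_e,
                              fixed_names=["mu"], animal_labels=ped.labels)
    res = mme.solve(sys)
    return dict(zip(ped.labels, res.solution[1:]))


def simulate_population(cfg: SimulationConfig) -> SimulatedPopulation:
    rng = np.random.default_rng(cfg.seed)
    su, se = cfg.sigma_u, cfg.sigma_e

    records = []          # (label, sire_label|None, dam_label|None)
    tiers = {}
    tbv = {}
    inb = {}              # inbreeding, tracked recursively via kinship table
    kinship = {}          # (lab1,lab2) sorted tuple -> kinship coefficient
    sex = {}
    pheno_rows = []
    geno = {}

    use_markers = cfg.n_markers > 0
    if use_markers:
        freqs = rng.uniform(0.05, 0.95, size=cfg.n_markers)
        if cfg.marker_effects:
            scale = np.sqrt(su / np.sum(2 * freqs * (1 - freqs)))
            alpha = rng.standard_normal(cfg.n_markers) * scale

    def kin(x, y):
        if x is None or y is None:
            return 0.0
        key = (x, y) if x <= y else (y, x)
        return kinship.get(key, 0.0)

    def set_kin(x, y, v):
        if v == 0.0:
            return
        key = (x, y) if x <= y else (y, x)
        kinship[key] = v

    def register(lab, s, d, tier, gen_pool):
        """Add animal, draw its breeding value/genotype, update kinship."""
        records.append((lab, s, d))
        tiers[lab] = tier
        if s is None:
            f = 0.0
            if use_markers:
                g = rng.binomial(2, freqs)
            if cfg.marker_effects and use_markers:
                u = float((g - 2 * freqs) @ alpha)
            else:
                u = rng.standard_normal() * np.sqrt(su)
        else:
            f = kin(s, d)
            if use_markers:
                g = _mendel(geno[s], rng) + _mendel(geno[d], rng)
            if cfg.marker_effects and use_markers:
                u = float((g - 2 * freqs) @ alpha)
            else:
                msv = 0.5 * su * (1.0 - 0.5 * (inb[s] + inb[d]))
                u = 0.5 * (tbv[s] + tbv[d]) + rng.standard_normal() * np.sqrt(msv)
        inb[lab] = f
        tbv[lab] = u
        if use_markers:
            geno[lab] = g
        # kinship bookkeeping against all previous animals (small populations)
        for other in gen_pool:
            if other == lab:
                continue
            v = 0.5 * (kin(s, other) + kin(d, other)) if s is not None else 0.0
            set_kin(lab, other, v)
        set_kin(lab, lab, 0.5 * (1.0 + f))
        gen_pool.append(lab)

    all_labels = []

    def phenotype(lab):
        cov = rng.standard_normal() if cfg.covariate_coef is not None else None
        mu = cfg.mean
        y = mu + tbv[lab] + rng.standard_normal() * np.sqrt(se)
        if cov is not None:
            y += cfg.covariate_coef * cov
        row = {"animal": lab, "trait": y}
        if cov is not None:
            row["covariate"] = cov
        pheno_rows.append(row)
        return y

    # --- founders -----------------------------------------------------
    counter = 0

    def newlab(prefix):
        nonlocal counter
        counter += 1
        return f"{prefix}{counter}"

    current_gen = []
    phen = {}
    for _ in range(cfg.n_founders):
        lab = newlab("N")
        register(lab, None, None, "nucleus", all_labels)
        sex[lab] = "M" if rng.random() < 0.5 else "F"
        phen[lab] = phenotype(lab)
        current_gen.append(lab)

    def select(pool, prop):
        """Truncation-select, guaranteeing at least one parent of each sex."""
        if cfg.selection == "none" or prop >= 1.0:
            chosen = list(pool)
        else:
            k = max(2, int(round(len(pool) * prop)))
            if cfg.selection == "phenotype":
                score = {lab: phen[lab] for lab in pool}
            else:  # ebv
                ped_now = build_pedigree(
                    [(a, s or "0", d or "0") for a, s, d in records]
                )
                ys = [r["trait"] for r in pheno_rows]
                ans = [r["animal"] for r in pheno_rows]
                ebv = _quick_ebv((ped_now, np.array(ys), ans), su, se)
                score = {lab: ebv[lab] for lab in pool}
            ranked = sorted(pool, key=lambda l: -score[l])
            chosen = ranked[:k]
            for sx in ("M", "F"):
                if not any(sex[l] == sx for l in chosen):
                    extra = next((l for l in ranked if sex[l] == sx), None)
                    if extra is not None:
                        chosen.append(extra)
        if not any(sex[l] == "M" for l in chosen) or \
           not any(sex[l] == "F" for l in chosen):
            raise ValueError("selected proportion leaves no parents of one sex")
        return chosen

    def split_sexes(pool):
        sires = [l for l in pool if sex[l] == "M"]
        dams = [l for l in pool if sex[l] == "F"]
        if len(sires) < 1 or len(dams) < 1:
            raise ValueError("selected proportion leaves no parents of one sex")
        return sires, dams

    # --- nucleus generations ------------------------------------------
    for _ in range(cfg.generations_nucleus):
        chosen = select(current_gen, cfg.selected_proportion)
        sires, dams = split_sexes(chosen)
        nxt = []
        for _ in range(cfg.n_matings_nucleus):
            s = sires[rng.integers(len(sires))]
            d = dams[rng.integers(len(dams))]
            for _ in range(cfg.offspring_per_mating):
                lab = newlab("N")
                register(lab, s, d, "nucleus", all_labels)
                sex[lab] = "M" if rng.random() < 0.5 else "F"
                phen[lab] = phenotype(lab)
                nxt.append(lab)
        current_gen = nxt

    # --- commercial tier ----------------------------------------------
    nucleus_pool = select(current_gen, cfg.selected_proportion)
    nsires, ndams = split_sexes(nucleus_pool)
    prev_comm = []
    for gen in range(cfg.generations_commercial):
        nxt = []
        comm_dams = [l for l in prev_comm if sex[l] == "F"]
        for _ in range(cfg.n_matings_commercial):
            s = nsires[rng.integers(len(nsires))]
            if gen > 0 and comm_dams:
                d = comm_dams[rng.integers(len(comm_dams))]
            else:
                d = ndams[rng.integers(len(ndams))]
            for _ in range(cfg.offspring_per_mating_commercial):
                lab = newlab("C")
                register(lab, s, d, "commercial", all_labels)
                sex[lab] = "M" if rng.random() < 0.5 else "F"
                phen[lab] = phenotype(lab)
                nxt.append(lab)
        prev_comm = nxt

    ped = build_pedigree([(a, s or "0", d or "0") for a, s, d in records])
    order = ped.labels
    tbv_arr = np.array([tbv[l] for l in order])
    pheno = pd.DataFrame(pheno_rows)
    cols = ["animal"] + (["covariate"] if "covariate" in pheno.columns else []) + ["trait"]
    pheno = pheno[cols]
    gdf = None
    if use_markers:
        nuc = [l for l in order if tiers[l] == "nucleus"]
        gdf = pd.DataFrame(
            np.vstack([geno[l] for l in nuc]).astype(np.int64),
            index=pd.Index(nuc, name="animal"),
            columns=[f"m{k+1}" for k in range(cfg.n_markers)],
        )
    return SimulatedPopulation(
        ped=ped, tiers=tiers, tbv=tbv_arr, phenotypes=pheno,
        genotypes=gdf, config=cfg,
    )


def _mendel(g: np.ndarray, rng) -> np.ndarray:
    """Gamete from an unlinked 0/1/2 genotype vector."""
    out = np.where(g == 2, 1, 0).astype(np.int64)
    het = g == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()))
    return out


def export_population(pop: SimulatedPopulation, outdir) -> dict:
    """Write pedigree.tsv, phenotypes.tsv, tiers.tsv (+ genotypes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    pop.ped.write(outdir / "pedigree.tsv")
    paths["pedigree"] = outdir / "pedigree.tsv"
    pop.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    tiers = pd.DataFrame(
        {"animal": pop.ped.labels,
         "tier": [pop.tiers[l] for l in pop.ped.labels]}
    )
    tiers.to_csv(outdir / "tiers.tsv", sep="\t", index=False)
    paths["tiers"] = outdir / "tiers.tsv"
    if pop.genotypes is not None and pop.genotypes.shape[1] > 0:
        pop.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
        paths["genotypes"] = outdir / "genotypes.tsv"
    return paths
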