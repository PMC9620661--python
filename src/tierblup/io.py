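"""File formats shared by the CLI and library: TSV tables, MatrixMarket
sparse matrices, the posterior-package directory, and run configuration.

The posterior package is the only artifact that crosses the
external-to-current boundary:

    posterior_means.tsv   effect-or-animal label, value
    posterior_cov.tsv     dense labeled covariance of (common β, u_a)
    eaa.mtx               sparse aa-block of the external-pedigree A-inverse
    meta.toml             σ²_u, σ²_e, id order, common-effect names
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .updating import ExternalPosterior, PhenotypeData


def write_posterior(ext: ExternalPosterior, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = list(ext.common_effect_names) + list(ext.a_ids)
    means = np.concatenate([ext.mean_beta, ext.mean_ua])
    pd.DataFrame({"label": labels, "value": means}).to_csv(
        outdir / "posterior_means.tsv", sep="\t", index=False, float_format="%.12g"
    )
    pd.DataFrame(ext.C, index=labels, columns=labels).to_csv(
        outdir / "posterior_cov.tsv", sep="\t", float_format="%.12g"
    )
    sio.mmwrite(outdir / "eaa.mtx", sp.coo_matrix(ext.Eaa))
    meta = [
        f"sigma_u = {ext.sigma_u!r}",
        f"sigma_e = {ext.sigma_e!r}",
        "common_effects = [" + ", ".join(f'"{n}"' for n in ext.common_effect_names) + "]",
        "a_ids = [" + ", ".join(f'"{a}"' for a in ext.a_ids) + "]",
    ]
    (outdir / "meta.toml").write_text("\n".join(meta) + "\n")


def read_posterior(indir) -> ExternalPosterior:
    indir = Path(indir)
    with open(indir / "meta.toml", "rb") as fh:
        meta = tomllib.load(fh)
    common = [str(x) for x in meta["common_effects"]]
    a_ids = [str(x) for x in meta["a_ids"]]
    labels = common + a_ids
    means = pd.read_csv(indir / "posterior_means.tsv", sep="\t", dtype={"label": str})
    mvals = means.set_index("label").loc[labels, "value"].to_numpy()
    cov = pd.read_csv(indir / "posterior_cov.tsv", sep="\t", index_col=0)
    cov.index = cov.index.map(str)
    cov.columns = cov.columns.map(str)
    C = cov.loc[labels, labels].to_numpy(dtype=float)
    Eaa = sp.csr_matrix(sio.mmread(indir / "eaa.mtx"))
    nb = len(common)
    return ExternalPosterior(
        a_ids=a_ids,
        common_effect_names=common,
        mean_beta=mvals[:nb],
        mean_ua=mvals[nb:],
        C=C,
        Eaa=Eaa,
        sigma_u=float(meta["sigma_u"]),
        sigma_e=float(meta["sigma_e"]),
    )


def read_phenotypes(path, factors: list, covariates: list,
                    trait: str = "trait") -> PhenotypeData:
    """Read a phenotype TSV into a design with named columns.

    Factor columns become one dummy column per level named
    ``<factor>:<level>`` (full dummy coding; supply disjoint factors or
    drop a level upstream to keep the design full rank); covariate
    columns are used as-is under their own names.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal": str})
    cols, names = [], []
    for f in factors:
        for lev in sorted(df[f].astype(str).unique()):
            cols.append((df[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}:{lev}")
    for c in covariates:
        cols.append(df[c].to_numpy(float))
        names.append(c)
    if not cols:
        cols = [np.ones(len(df))]
        names = ["intercept"]
    return PhenotypeData(
        y=df[trait].to_numpy(float),
        X=np.column_stack(cols),
        x_names=names,
        animals=df["animal"].tolist(),
    )


def read_genotypes(path):
    """Genotype TSV (first column animal, remaining marker ids) -> (matrix, ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.map(str)
    return df.to_numpy(dtype=float), df.index.tolist()


def write_result(result, outdir, pev_diag: np.ndarray | None = None) -> None:
    """Write ebv.tsv and fixed_effects.tsv with user labels, 12 sig. digits."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sys = result.system
    rows = []
    for bname in sys.blocks:
        if not bname.startswith(("u_", "animals")):
            continue
        labs = sys.labels.get(bname, [])
        vals = result.block_solution(bname)
        rows += list(zip(labs, vals))
    if rows:
        df = pd.DataFrame(rows, columns=["animal", "ebv"])
        if pev_diag is not None:
            df["pev"] = pev_diag
        df.to_csv(outdir / "ebv.tsv", sep="\t", index=False, float_format="%.12g")
    frows = []
    for bname in sys.blocks:
        if bname.startswith(("u_", "animals")):
            continue
        labs = sys.labels.get(bname, [])
        vals = result.block_solution(bname)
        frows += list(zip(labs, vals))
    if frows:
        pd.DataFrame(frows, columns=["effect", "estimate"]).to_csv(
            outdir / "fixed_effects.tsv", sep="\t", index=False, float_format="%.12g"
        )


@dataclass
class RunConfig:
    """Parsed key-value run configuration for the CLI."""

    sigma_u: float = 0.3
    sigma_e: float = 0.7
    factors: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    common_effects: list = field(default_factory=list)
    solver: str = "direct"
    tol: float = 1e-10
    max_iter: int = 20000
    gibbs_iters: int = 0
    gibbs_burn_in: int = 0
    gibbs_thin: int = 1
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kv = parse_keyvalue(path)
        kwargs = {}
        for f in ("sigma_u", "sigma_e", "tol"):
            if f in kv:
                kwargs[f] = float(kv[f])
        for f in ("max_iter", "gibbs_iters", "gibbs_burn_in", "gibbs_thin", "seed"):
            if f in kv:
                kwargs[f] = int(kv[f])
        for f in ("factors", "covariates", "common_effects"):
            if f in kv:
                kwargs[f] = [s for s in kv[f].split(",") if s]
        if "solver" in kv:
            kwargs["solver"] = kv["solver"]
        if kwargs.get("sigma_u", 1) <= 0 or kwargs.get("sigma_e", 1) <= 0:
            raise ValueError("variance components must be positive")
        return cls(**kwargs)


def parse_keyvalue(path) -> dict:
    """Plain-text ``key = value`` config, ``#`` comments allowed."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
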