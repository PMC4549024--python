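"""File formats: genotype TSV / PLINK .raw dialect, pedigree CSV, phenotype
TSV, truth TSV, YAML configs, HDF5 chain store, JSON fit summaries.

Conventions: dosage coding 0/1/2 (count of the reference allele); locus
indices are 0-based in memory and 1-based in files; pedigree files use id 0
for an unknown parent (founder).  Every artifact written here carries a
comment/attribute header naming the generating seed and a configuration
hash.  Missing genotypes are not supported: the simulator never emits them
and an explicit error names the offending cell on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "config_hash",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_raw",
    "read_raw",
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_truth_tsv",
    "save_config_yaml",
    "load_config_yaml",
    "save_chain_h5",
    "load_chain_h5",
    "write_fit_json",
    "read_fit_json",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))


def _marker_ids(n: int) -> list[str]:
    return [f"M{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_genotypes_tsv(path, dosages, marker_ids=None, meta: dict | None = None):
    """Dosage matrix as TSV: rows = individuals, columns = markers."""
    dosages = np.asarray(dosages)
    ids = marker_ids or _marker_ids(dosages.shape[1])
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, row in enumerate(dosages, start=1):
            fh.write(str(i) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_genotypes_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    mat = df.iloc[:, 1:].to_numpy()
    _validate_dosages(mat, path)
    return mat.astype(np.uint8)


def _validate_dosages(mat, path):
    bad = ~np.isin(mat, [0, 1, 2]) | pd.isna(mat)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: invalid or missing genotype at row {i + 1}, marker column "
            f"{j + 1} (missing genotypes are not supported)"
        )


def write_raw(path, dosages, phenotypes=None, marker_ids=None, meta: dict | None = None):
    """PLINK .raw dialect: FID IID PAT MAT SEX PHENOTYPE then <marker>_A dosages."""
    dosages = np.asarray(dosages)
    ids = marker_ids or _marker_ids(dosages.shape[1])
    y = phenotypes if phenotypes is not None else np.full(dosages.shape[0], -9)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(f"{m}_A" for m in ids) + "\n")
        for i, row in enumerate(dosages, start=1):
            fh.write(
                f"0 {i} 0 0 0 {y[i - 1]} " + " ".join(str(int(v)) for v in row) + "\n"
            )


def read_raw(path) -> np.ndarray:
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    mat = df.iloc[:, 6:].apply(pd.to_numeric, errors="coerce").to_numpy()
    _validate_dosages(mat, path)
    return mat.astype(np.uint8)


# ---------------------------------------------------------------------------
# Pedigree, phenotypes, truth
# ---------------------------------------------------------------------------

def write_pedigree_csv(path, sire, dam, family_id=None, meta: dict | None = None):
    """Pedigree CSV (id, sire, dam, family); ids 1-based, 0 = unknown parent."""
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    fam = np.asarray(family_id) if family_id is not None else np.full(sire.size, -1)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        fh.write("id,sire,dam,family\n")
        for i in range(sire.size):
            fh.write(f"{i + 1},{sire[i] + 1},{dam[i] + 1},{fam[i] + 1}\n")


def read_pedigree_csv(path):
    """Returns 0-based (sire, dam, family) arrays, -1 for unknown/founder."""
    df = pd.read_csv(path, comment="#")
    order = np.argsort(df["id"].to_numpy())
    sire = df["sire"].to_numpy()[order] - 1
    dam = df["dam"].to_numpy()[order] - 1
    fam = (df["family"].to_numpy()[order] - 1) if "family" in df else None
    return sire.astype(np.int64), dam.astype(np.int64), fam


def write_phenotypes_tsv(path, y, meta: dict | None = None):
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        fh.write("id\ty\n")
        for i, v in enumerate(np.asarray(y, dtype=float), start=1):
            fh.write(f"{i}\t{float(v)!r}\n")


def read_phenotypes_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df["y"].to_numpy(dtype=float)


def write_truth_tsv(path, u_a, u_d, g, meta: dict | None = None):
    """True breeding values, dominance deviations and genotypic values."""
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        fh.write("id\tu_a\tu_d\tg\n")
        for i in range(len(g)):
            fh.write(f"{i + 1}\t{float(u_a[i])!r}\t{float(u_d[i])!r}\t{float(g[i])!r}\n")


def write_qtl_tsv(path, qtl_indices, a, d, meta: dict | None = None):
    """Per-QTL effect file (1-based locus ids)."""
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        fh.write("locus\ta\td\n")
        for j in range(len(a)):
            fh.write(f"{qtl_indices[j] + 1}\t{float(a[j])!r}\t{float(d[j])!r}\n")


# ---------------------------------------------------------------------------
# Configs, chains, fit summaries
# ---------------------------------------------------------------------------

def save_config_yaml(path, config: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_chain_h5(path, chain, meta: dict | None = None):
    """Persist an :class:`~addomgs.mcmc.MCMCChain` to HDF5."""
    with h5py.File(path, "w") as h5:
        for name in ("sigma_e2", "sigma_a2", "sigma_d2", "mean_ma", "mean_md",
                     "mean_ta2", "mean_td2", "p"):
            h5.create_dataset(name, data=getattr(chain, name))
        if chain.ma_samples is not None:
            h5.create_dataset("ma_samples", data=chain.ma_samples)
            h5.create_dataset("md_samples", data=chain.md_samples)
        cfg = chain.config
        h5.attrs["method"] = cfg.method
        for k in ("df1", "df2", "n_iter", "burn_in", "thin", "seed"):
            h5.attrs[k] = getattr(cfg, k)
        for k, v in (meta or {}).items():
            h5.attrs[k] = v


def load_chain_h5(path):
    from .mcmc import MCMCChain, model_config

    with h5py.File(path, "r") as h5:
        cfg = model_config(
            h5.attrs["method"],
            n_iter=int(h5.attrs["n_iter"]),
            burn_in=int(h5.attrs["burn_in"]),
            thin=int(h5.attrs["thin"]),
            seed=int(h5.attrs["seed"]),
        )
        data = {name: h5[name][...] for name in
                ("sigma_e2", "sigma_a2", "sigma_d2", "mean_ma", "mean_md",
                 "mean_ta2", "mean_td2", "p")}
        ma_s = h5["ma_samples"][...] if "ma_samples" in h5 else None
        md_s = h5["md_samples"][...] if "md_samples" in h5 else None
    return MCMCChain(config=cfg, ma_samples=ma_s, md_samples=md_s, **data)


def write_fit_json(path, summary: dict, meta: dict | None = None):
    payload = {**(meta or {}), **summary}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def read_fit_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
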