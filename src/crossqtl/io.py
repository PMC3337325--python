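"""Readers, writers and run configuration for the pipeline's text formats.

All inputs are plain delimited text: a 3-column map TSV, a pedigree TSV, a
genotype TSV with two allele columns per marker ("0"/"NA" = missing), a
phenotype TSV, and optionally PLINK-style .ped/.map pairs for biallelic SNP
sets.  Readers enforce cross-file referential integrity (every phenotyped id
in the pedigree, every genotyped marker on the map) and raise errors that
name the offending file, id or column.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .linkage import LinkageMap

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_map",
    "read_pedigree",
    "read_genotypes",
    "read_phenotypes",
    "read_plink",
    "read_tables",
]


class ValidationError(ValueError):
    """Input file failed validation; message carries file and id context."""


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_map(path) -> LinkageMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["chromosome", "marker", "position_cM"], path)
    if df["chromosome"].nunique() > 1:
        raise ValidationError(f"{path}: expected a single chromosome")
    try:
        pos = df["position_cM"].astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric position_cM") from exc
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise ValidationError(f"{path}: duplicated marker {dup!r}")
    return LinkageMap(tuple(df["marker"]), pos)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["id", "sire", "dam", "generation", "breed"], path)
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"{path}: duplicated individual {dup!r}")
    df["generation"] = df["generation"].astype(int)
    known = set(df["id"])
    for col in ("sire", "dam"):
        dangling = set(df[col]) - known - {"", "0"}
        if dangling:
            raise ValidationError(
                f"{path}: {col} id {sorted(dangling)[0]!r} not in pedigree")
    return df


def read_genotypes(path, gmap: LinkageMap | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["id"], path)
    markers = sorted({c[:-2] for c in df.columns if c.endswith("_1")})
    for m in markers:
        if f"{m}_2" not in df.columns:
            raise ValidationError(f"{path}: marker {m} lacks a second allele column")
    if gmap is not None:
        off_map = [m for m in markers if m not in gmap.markers]
        if off_map:
            raise ValidationError(
                f"{path}: genotyped marker {off_map[0]!r} absent from the map")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"{path}: duplicated individual {dup!r}")
    return df


def read_phenotypes(path, pedigree: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "batch": str,
                                            "sex": str, "ppard_genotype": str})
    _require_columns(df, ["id", "ear_size_cm2"], path)
    if pedigree is not None:
        known = set(pedigree["id"])
        dangling = set(df["id"]) - known
        if dangling:
            raise ValidationError(
                f"{path}: phenotyped id {sorted(dangling)[0]!r} not in pedigree")
    return df


def read_plink(ped_path, map_path) -> tuple:
    """PLINK .ped/.map dialect for biallelic SNP sets.

    Returns ``(genotype_frame, marker_names)`` in the native two-column
    layout; missing alleles stay "0".
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "marker", "cm", "bp"], dtype=str)
    markers = list(mp["marker"])
    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    expected = 6 + 2 * len(markers)
    if ped.shape[1] != expected:
        raise ValidationError(
            f"{ped_path}: expected {expected} columns for {len(markers)} "
            f"markers, found {ped.shape[1]}")
    out = {"id": ped.iloc[:, 1]}
    for j, m in enumerate(markers):
        out[f"{m}_1"] = ped.iloc[:, 6 + 2 * j]
        out[f"{m}_2"] = ped.iloc[:, 7 + 2 * j]
    return pd.DataFrame(out), markers


def read_tables(map_path, pedigree_path, genotype_path, phenotype_path,
                candidate_path=None) -> dict:
    """Read and cross-validate the full input bundle."""
    gmap = read_map(map_path)
    ped = read_pedigree(pedigree_path)
    geno = read_genotypes(genotype_path, gmap)
    pheno = read_phenotypes(phenotype_path, ped)
    missing_geno = set(pheno["id"]) - set(geno["id"])
    if missing_geno:
        raise ValidationError(
            f"{phenotype_path}: phenotyped id {sorted(missing_geno)[0]!r} "
            "has no genotype record")
    out = {"map": gmap, "pedigree": ped, "genotypes": geno, "phenotypes": pheno}
    if candidate_path is not None:
        p = Path(candidate_path)
        if p.suffix == ".ped":
            out["candidates"], _ = read_plink(p, p.with_suffix(".map"))
        else:
            out["candidates"] = read_genotypes(candidate_path)
    return out


@dataclass
class RunConfig:
    """Configuration of one pipeline run; everything reproducibility needs."""

    map_path: str = ""
    pedigree_path: str = ""
    genotype_path: str = ""
    phenotype_path: str = ""
    candidate_path: str | None = None
    out_dir: str = "results"
    scenario: str | None = None      # simulate instead of reading inputs
    step: float = 1.0
    n_perm: int = 1000
    n_boot: int = 2000
    alpha: float = 0.05
    heritability: float = 0.4
    seed: int = 1
    candidate_snps: tuple = ()
    haplotype_window: tuple = ()
    fdrop_mode: str = "at_peak"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("candidate_snps", "haplotype_window"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        if cfg.scenario is None:
            for key in ("map_path", "pedigree_path", "genotype_path",
                        "phenotype_path"):
                p = getattr(cfg, key)
                if not p or not Path(p).exists():
                    raise ValidationError(f"{path}: {key} {p!r} does not exist")
        return cfg

    def digest(self) -> str:
        # out_dir does not affect the analysis, so it is not part of the hash
        keys = sorted(set(self.__dataclass_fields__) - {"out_dir"})
        payload = json.dumps({k: getattr(self, k) for k in keys},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
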