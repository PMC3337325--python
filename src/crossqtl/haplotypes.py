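"""Pedigree phasing of tight candidate-gene SNP windows and haplotype
association with pre-corrected phenotypes.

The SNP windows of interest span well under a centiMorgan, so within a
three-generation pedigree recombination inside the window can be ignored
and phase follows from Mendelian transmission: each allele of a child is
assigned to a parent wherever that assignment is unique, and the remaining
ambiguities are resolved by requiring the transmitted allele strings to
match one of the parent's own haplotypes (a minimum-recombination rule).
Individuals whose phase still is not unique are flagged and excluded, never
imputed.

The association stage regresses infinitesimal-corrected residuals on the
copy number (0/1/2) of each haplotype separately, with a Bonferroni
correction over the number of haplotypes, and estimates the variance
explained jointly by all haplotypes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeAssignment",
    "HaplotypeEffect",
    "phase_f2",
    "haplotype_copy_matrix",
    "haplotype_regression",
    "haplotype_variance_explained",
]

MISSING = ("0", "NA", "nan", "")


@dataclass(frozen=True)
class HaplotypeAssignment:
    """Phased haplotype pair (paternal, maternal) for one individual."""

    id: str
    paternal: str           # allele string, e.g. "A/C/G"
    maternal: str
    method: str             # "deterministic" | "rule"

    @property
    def pair(self) -> tuple:
        return (self.paternal, self.maternal)


@dataclass(frozen=True)
class HaplotypeEffect:
    haplotype: str
    frequency: float
    effect: float
    se: float
    p_raw: float
    p_corrected: float


def _geno_tuples(genotypes: pd.DataFrame, snps):
    """id -> list of (a1, a2) per SNP, or None if any genotype is missing."""
    out = {}
    for r in genotypes.itertuples(index=False):
        d = r._asdict()
        g = []
        ok = True
        for s in snps:
            a1, a2 = str(d[f"{s}_1"]).strip(), str(d[f"{s}_2"]).strip()
            if a1 in MISSING or a2 in MISSING:
                ok = False
                break
            g.append((a1, a2))
        out[str(d["id"])] = g if ok else None
    return out


def _per_snp_options(child, sire, dam):
    """Feasible (from_sire, from_dam) orderings per SNP; None = Mendelian fail."""
    opts = []
    for (cx, cy), ps, pd_ in zip(child, sire, dam):
        site = set()
        for a, b in (((cx, cy)), ((cy, cx))):
            if a in ps and b in pd_:
                site.add((a, b))
        if not site:
            return None
        opts.append(sorted(site))
    return opts


def _matches(hap: tuple, known_pair) -> bool:
    """Does ``hap`` match either haplotype of a (possibly unknown) parent?"""
    if known_pair is None:
        return True
    return hap in known_pair


def phase_f2(pedigree: pd.DataFrame, snp_genotypes: pd.DataFrame,
             snps) -> dict:
    """Phase every pedigree member over a tight SNP window.

    Returns ``{id: HaplotypeAssignment}`` containing only resolved
    individuals; unresolved or ungenotyped individuals are excluded (their
    count is logged).  Founders heterozygous at more than one SNP cannot be
    phased without offspring information and are left unresolved.  Raises on
    Mendelian inconsistency.
    """
    snps = list(snps)
    geno = _geno_tuples(snp_genotypes, snps)
    ped = pedigree.set_index("id")
    order = sorted(ped.index, key=lambda i: int(ped.at[i, "generation"]))

    resolved: dict[str, HaplotypeAssignment] = {}
    pairs: dict[str, tuple | None] = {}
    n_unresolved = 0

    for ind in order:
        g = geno.get(ind)
        if g is None:
            pairs[ind] = None
            n_unresolved += 1
            continue
        sire = ped.at[ind, "sire"]
        dam = ped.at[ind, "dam"]
        has_parents = (isinstance(sire, str) and sire not in ("", "0")
                       and sire in geno and isinstance(dam, str)
                       and dam not in ("", "0") and dam in geno)
        if not has_parents:
            het = [k for k, (a, b) in enumerate(g) if a != b]
            if len(het) <= 1:
                pat = tuple(a for a, _ in g)
                mat = tuple(b for _, b in g)
                resolved[ind] = HaplotypeAssignment(
                    ind, "/".join(pat), "/".join(mat), "deterministic")
                pairs[ind] = (pat, mat)
            else:
                pairs[ind] = None
                n_unresolved += 1
            continue

        gs, gd = geno.get(sire), geno.get(dam)
        if gs is None or gd is None:
            pairs[ind] = None
            n_unresolved += 1
            continue
        opts = _per_snp_options(g, gs, gd)
        if opts is None:
            raise ValueError(
                f"Mendelian inconsistency at individual {ind!r} in window {snps}")
        combos = set()
        n_enumerated = 0
        for combo in itertools.product(*opts):
            n_enumerated += 1
            hp = tuple(a for a, _ in combo)
            hm = tuple(b for _, b in combo)
            combos.add((hp, hm))
        consistent = {
            (hp, hm) for hp, hm in combos
            if _matches(hp, pairs.get(sire)) and _matches(hm, pairs.get(dam))
        }
        pool = consistent if consistent else combos
        if len(pool) == 1:
            hp, hm = next(iter(pool))
            method = "deterministic" if n_enumerated == 1 else "rule"
            resolved[ind] = HaplotypeAssignment(
                ind, "/".join(hp), "/".join(hm), method)
            pairs[ind] = (hp, hm)
        else:
            pairs[ind] = None
            n_unresolved += 1

    if n_unresolved:
        logger.info("phase unresolved for %d individuals (excluded)",
                    n_unresolved)
    return resolved


def haplotype_copy_matrix(assignments: dict) -> pd.DataFrame:
    """Individuals x haplotypes copy counts (entries 0/1/2, rows sum to 2)."""
    if not assignments:
        raise ValueError("no phased individuals")
    haps = sorted({h for a in assignments.values() for h in a.pair})
    ids = sorted(assignments)
    M = pd.DataFrame(0, index=pd.Index(ids, name="id"), columns=haps)
    for i in ids:
        for h in assignments[i].pair:
            M.loc[i, h] += 1
    return M


def haplotype_regression(corrected_residuals: pd.Series,
                         copies: pd.DataFrame) -> pd.DataFrame:
    """One simple regression of corrected residuals per haplotype copy count.

    Each haplotype is tested separately (intercept + its 0/1/2 copy count);
    raw P-values are Bonferroni-corrected by the number of haplotypes and
    capped at 1.  Returns a frame with frequency, effect +- se and corrected P.
    """
    common = copies.index.intersection(corrected_residuals.index)
    if len(common) == 0:
        raise ValueError("no overlap between residuals and phased individuals")
    C = copies.loc[common]
    absent = [h for h in C.columns if (C[h] == 0).all()]
    if absent:
        logger.info("haplotypes absent from the analysed subset dropped: %s",
                    absent)
        C = C.drop(columns=absent)
    y = corrected_residuals.loc[common].to_numpy(dtype=float)
    n = len(common)
    n_hap = C.shape[1]
    freqs = C.to_numpy().mean(axis=0) / 2.0
    rows = []
    for j, hap in enumerate(C.columns):
        x = C.iloc[:, j].to_numpy(dtype=float)
        if np.var(x) == 0:
            raise ValueError(f"haplotype {hap!r} copy count has zero variance")
        xc = x - x.mean()
        yc = y - y.mean()
        beta = float(xc @ yc / (xc @ xc))
        resid = yc - beta * xc
        df = n - 2
        sigma2 = float(resid @ resid) / df
        se = float(np.sqrt(sigma2 / (xc @ xc)))
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append({
            "haplotype": hap,
            "frequency": float(freqs[j]),
            "effect": beta,
            "se": se,
            "p_raw": p,
            "p_corrected": min(1.0, p * n_hap),
        })
    return pd.DataFrame(rows)


def haplotype_variance_explained(corrected_residuals: pd.Series,
                                 copies: pd.DataFrame) -> tuple:
    """Percent of residual phenotypic variance explained by all haplotypes.

    Joint regression on all copy-number columns (one dropped internally to
    break the rows-sum-to-2 aliasing with the intercept); returns
    ``(percent, p_value)`` with the P from the joint F test.
    """
    common = copies.index.intersection(corrected_residuals.index)
    sub = copies.loc[common]
    sub = sub.loc[:, (sub != 0).any(axis=0)]
    C = sub.to_numpy(dtype=float)
    y = corrected_residuals.loc[common].to_numpy(dtype=float)
    n, k = C.shape
    if k < 2:
        raise ValueError("need at least two haplotypes")
    X = np.column_stack([np.ones(n), C[:, :-1]])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1] - 1:
        raise ValueError("copy matrix rank-deficient beyond the expected aliasing")
    fitted = X @ beta
    yc = y - y.mean()
    tss = float(yc @ yc)
    rss = float((y - fitted) @ (y - fitted))
    ess = tss - rss
    df_num = rank - 1
    df_den = n - rank
    f = (ess / df_num) / (rss / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return 100.0 * ess / tss, p
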