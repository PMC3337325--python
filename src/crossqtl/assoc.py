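"""Candidate-gene dissection of a line-cross QTL: the four-model framework.

An F2 between divergent lines carries massive between-line linkage
disequilibrium: any line-differentiated SNP anywhere near the QTL associates
with the trait.  The framework separates that confounding from real
candidate-gene signal with four nested models on a common base (batch, sex,
carcass weight, unlinked-QTL genotype):

* standard association test  — model 3 (base + SNP genotype) vs model 1
  (base): significant when the SNP is in LD with the QTL at all;
* marker-assisted test       — model 4 (base + SNP + c_a + c_d) vs model 2
  (base + c_a + c_d): the line-origin terms absorb the between-line LD, so
  significance points at the QTN itself or something tightly linked to it;
* F-drop test                — how far the line-origin QTL F falls when the
  SNP genotype is held as a fixed effect: F_qtl (model 2 vs 1) against
  F_drop (model 4 vs 3); a near-total drop means the SNP captures the QTL.

Also here: the discovery-panel minor-allele-frequency filter, per-SNP
additive-effect estimation, RSS ratios for ranking candidate genes, and the
genotype ANCOVA used for outbred validation populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import OriginGrid
from .linmod import (FTest, FitResult, ModelSpec, design_matrix,
                     drop_incomplete, f_ratio, fit_ls, _solve_ls)
from .scan import CurveEngine

logger = logging.getLogger(__name__)

__all__ = [
    "AssocTestResult",
    "FDropResult",
    "SnpEffect",
    "OutbredAssocResult",
    "maf_filter",
    "genotype_classes",
    "standard_assoc",
    "marker_assisted_assoc",
    "f_drop_test",
    "drop_fraction",
    "estimate_snp_effects",
    "rss_ratio",
    "outbred_assoc",
    "candidate_table",
]

MISSING = ("0", "NA", "nan", "")


# ---------------------------------------------------------------------------
# genotype handling
# ---------------------------------------------------------------------------

def genotype_classes(candidates: pd.DataFrame, snp: str) -> pd.Series:
    """Genotype class per individual ("A/G" with alleles sorted); NaN = missing."""
    a1 = candidates[f"{snp}_1"].astype(str).str.strip()
    a2 = candidates[f"{snp}_2"].astype(str).str.strip()
    miss = a1.isin(MISSING) | a2.isin(MISSING)
    swap = a1 > a2
    lo = a1.where(~swap, a2)
    hi = a2.where(~swap, a1)
    out = pd.Series((lo + "/" + hi).to_numpy(),
                    index=candidates["id"].to_numpy(), name=snp)
    out[miss.to_numpy()] = np.nan
    return out


def maf_filter(panel: pd.DataFrame, variants=None,
               threshold: float = 0.25) -> pd.DataFrame:
    """Discovery-panel informativeness filter: keep MAF >= ``threshold``.

    ``panel`` holds the genotypes of a small discovery panel (by default the
    semantics of 4 animals = 8 alleles) with two allele columns per variant.
    The minor-allele frequency is computed over non-missing panel alleles;
    an all-missing variant raises.
    """
    if variants is None:
        variants = sorted({c[:-2] for c in panel.columns if c.endswith("_1")})
    rows = []
    for v in variants:
        alleles = pd.concat([panel[f"{v}_1"], panel[f"{v}_2"]],
                            ignore_index=True).astype(str).str.strip()
        alleles = alleles[~alleles.isin(MISSING)]
        if alleles.empty:
            raise ValueError(f"variant {v!r} is missing in the whole panel")
        freqs = alleles.value_counts(normalize=True)
        maf = 1.0 - freqs.max() if len(freqs) == 1 else float(freqs.min())
        if len(freqs) > 2:
            maf = float(1.0 - freqs.max())
        rows.append({"variant": v, "maf": maf,
                     "keep": bool(maf >= threshold - 1e-12)})
    return pd.DataFrame(rows).set_index("variant")


def _merge_snp(records: pd.DataFrame, snp_genotypes, snp: str | None = None):
    """Attach a genotype-class column named ``__snp`` to the records."""
    if isinstance(snp_genotypes, pd.DataFrame):
        if snp is None:
            raise ValueError("snp name required with a candidate table")
        classes = genotype_classes(snp_genotypes, snp)
    else:
        classes = snp_genotypes
    out = records.copy()
    out["__snp"] = out["id"].map(classes)
    return out


def _check_polymorphic(records: pd.DataFrame):
    k = records["__snp"].nunique()
    if k < 2:
        raise ValueError("candidate SNP is monomorphic in the phenotyped set")
    return k


def _check_not_aliased(fit: FitResult):
    if not any(str(ix).startswith("__snp[") for ix in fit.params.index):
        raise ValueError(
            "candidate genotype is aliased with the base model "
            "(all its design columns were dropped)")


# ---------------------------------------------------------------------------
# the three tests
# ---------------------------------------------------------------------------

def standard_assoc(records: pd.DataFrame, snp_genotypes,
                   base_spec: ModelSpec | None = None,
                   snp: str | None = None) -> FTest:
    """Standard association test: model 3 (base + genotype) vs model 1 (base).

    Significance means the SNP is in LD with the QTL or is the QTL, but in a
    line cross this is heavily confounded by between-line LD.
    """
    base_spec = base_spec or ModelSpec()
    data = _merge_snp(records, snp_genotypes, snp)
    m1 = base_spec
    m3 = base_spec.with_candidate("__snp")
    data = drop_incomplete(data, m3)
    _check_polymorphic(data)
    fit1 = fit_ls(data, m1)
    fit3 = fit_ls(data, m3)
    _check_not_aliased(fit3)
    return f_ratio(fit1, fit3)


def _origin_at(states: OriginGrid, ids, position: float | None):
    aligned = states.reindex(list(ids))
    if position is None:
        raise ValueError("a QTL peak position is required")
    j = int(np.argmin(np.abs(aligned.positions - position)))
    return aligned.c_a[:, j], aligned.c_d[:, j]


def marker_assisted_assoc(records: pd.DataFrame, snp_genotypes,
                          peak_states, base_spec: ModelSpec | None = None,
                          snp: str | None = None,
                          position: float | None = None) -> FTest:
    """Marker-assisted association test: model 4 vs model 2.

    The line-origin coefficients at the QTL peak are in both models, so the
    between-line LD signal is absorbed and the test asks what the SNP
    genotype explains beyond it.  ``peak_states`` is either an
    :class:`OriginGrid` (with ``position`` giving the peak) or a ready
    ``(c_a, c_d)`` pair aligned to the records.
    """
    base_spec = base_spec or ModelSpec()
    data = _merge_snp(records, snp_genotypes, snp)
    m2 = base_spec.with_line_origin()
    m4 = m2.with_candidate("__snp")
    data = drop_incomplete(data, m4)
    _check_polymorphic(data)
    if isinstance(peak_states, OriginGrid):
        origin = _origin_at(peak_states, data["id"], position)
    else:
        origin = peak_states
    fit2 = fit_ls(data, m2, origin=origin)
    fit4 = fit_ls(data, m4, origin=origin)
    _check_not_aliased(fit4)
    return f_ratio(fit2, fit4)


@dataclass
class FDropResult:
    f_qtl: float
    f_drop: float
    drop_fraction: float
    peak_position: float
    drop_position: float
    curve_qtl: np.ndarray
    curve_drop: np.ndarray
    positions: np.ndarray


def drop_fraction(f_qtl: float, f_drop: float) -> float:
    """(F_qtl - F_drop) / F_qtl; NaN (flagged) when F_qtl is ~0."""
    if abs(f_qtl) < 1e-12:
        logger.warning("F_qtl ~ 0: drop fraction undefined")
        return float("nan")
    return (f_qtl - f_drop) / f_qtl


def f_drop_test(records: pd.DataFrame, snp_genotypes, states: OriginGrid,
                base_spec: ModelSpec | None = None, snp: str | None = None,
                mode: str = "at_peak") -> FDropResult:
    """F-drop test: how much of the QTL F survives the SNP genotype.

    F_qtl is the peak of the model 2 vs model 1 scan curve.  The same
    line-origin terms are then tested with the SNP genotype held as a fixed
    effect (model 4 vs model 3); with ``mode="at_peak"`` (default) F_drop is
    that curve's value at the F_qtl peak position — the drop compares like
    with like at the mapped QTL — while ``mode="peak"`` takes the adjusted
    curve's own maximum, which for a SNP that fully captures the QTL
    measures only the chromosome-wide extreme of a null profile.
    """
    if mode not in ("at_peak", "peak"):
        raise ValueError("mode must be 'at_peak' or 'peak'")
    base_spec = base_spec or ModelSpec()
    data = _merge_snp(records, snp_genotypes, snp)
    m3 = base_spec.with_candidate("__snp")
    data = drop_incomplete(data, m3)
    _check_polymorphic(data)
    aligned = states.reindex(list(data["id"]))

    X1, _, y = design_matrix(data, base_spec)
    eng1 = CurveEngine(X1, y, aligned.c_a, aligned.c_d)
    curve1 = eng1.f_curve()
    j = int(np.argmax(curve1))
    f_qtl = float(curve1[j])

    X3, _, _ = design_matrix(data, m3)
    eng3 = CurveEngine(X3, y, aligned.c_a, aligned.c_d)
    curve3 = eng3.f_curve()
    if mode == "peak":
        jd = int(np.argmax(curve3))
    else:
        jd = j
    f_drop = float(curve3[jd])
    return FDropResult(
        f_qtl=f_qtl, f_drop=f_drop,
        drop_fraction=drop_fraction(f_qtl, f_drop),
        peak_position=float(aligned.positions[j]),
        drop_position=float(aligned.positions[jd]),
        curve_qtl=curve1, curve_drop=curve3,
        positions=aligned.positions.copy(),
    )


# ---------------------------------------------------------------------------
# effects, RSS ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpEffect:
    """Additive effect of a reference allele: half the adjusted difference
    between the two homozygote classes, signed toward the reference."""

    snp: str
    reference_allele: str
    effect: float
    se: float
    dominance: float | None = None


def estimate_snp_effects(records: pd.DataFrame, snp_genotypes,
                         base_spec: ModelSpec | None = None,
                         snp: str | None = None,
                         reference_allele: str | None = None) -> SnpEffect:
    """Additive effect (cm^2) of a biallelic candidate SNP within model 3.

    Model 3 is re-parameterised on allele dosage plus a heterozygote
    indicator, so the dosage coefficient is half the adjusted difference
    between the two homozygote means; the sign refers to the declared
    ``reference_allele`` (lexicographically first allele by default).
    """
    base_spec = base_spec or ModelSpec()
    if isinstance(snp_genotypes, pd.DataFrame):
        if snp is None:
            raise ValueError("snp name required with a candidate table")
        a1 = snp_genotypes[f"{snp}_1"].astype(str).str.strip()
        a2 = snp_genotypes[f"{snp}_2"].astype(str).str.strip()
        gdf = pd.DataFrame({"id": snp_genotypes["id"], "a1": a1, "a2": a2})
    else:
        raise TypeError("snp_genotypes must be a candidate genotype table")
    miss = gdf["a1"].isin(MISSING) | gdf["a2"].isin(MISSING)
    gdf = gdf[~miss]
    alleles = sorted(set(gdf["a1"]) | set(gdf["a2"]))
    if len(alleles) != 2:
        raise ValueError(f"SNP {snp!r} is not biallelic: alleles {alleles}")
    if reference_allele is None:
        reference_allele = alleles[0]
    elif reference_allele not in alleles:
        raise ValueError(f"reference allele {reference_allele!r} not observed")

    dosage = ((gdf["a1"] == reference_allele).astype(int)
              + (gdf["a2"] == reference_allele).astype(int))
    data = records.merge(
        pd.DataFrame({"id": gdf["id"].to_numpy(), "__dosage": dosage.to_numpy()}),
        on="id", how="inner")
    data = drop_incomplete(data, base_spec).dropna(subset=["__dosage"])
    counts = data["__dosage"].value_counts()
    if counts.get(0, 0) == 0 or counts.get(2, 0) == 0:
        raise ValueError(
            f"additive effect undefined: a homozygote class of {snp!r} "
            "is unobserved")
    X, names, y = design_matrix(data, base_spec)
    het = (data["__dosage"].to_numpy() == 1).astype(float)
    X = np.column_stack([X, data["__dosage"].to_numpy(dtype=float), het])
    names = names + ["__dosage", "__het"]
    beta, kept, dropped, rss, fitted, resid, rank, covu = _solve_ls(X, y, names)
    if "__dosage" not in kept:
        raise ValueError("dosage term aliased with the base model")
    df = len(data) - rank
    sigma2 = rss / df
    i = kept.index("__dosage")
    effect = float(beta[i])
    se = float(np.sqrt(sigma2 * covu[i, i]))
    dom = None
    if "__het" in kept:
        dom = float(beta[kept.index("__het")])
    return SnpEffect(snp or "snp", reference_allele, effect, se, dom)


def rss_ratio(fit_a: FitResult, fit_b: FitResult) -> float:
    """RSS_a / RSS_b for two model-3 fits of different candidate genes.

    Both fits must use the same records; a ratio below 1 ranks gene a closer
    to the QTL.
    """
    if fit_a.n != fit_b.n:
        raise ValueError("fits use different record sets")
    if (fit_a.row_index is not None and fit_b.row_index is not None
            and not fit_a.row_index.equals(fit_b.row_index)):
        raise ValueError("fits use different record sets")
    return fit_a.rss / fit_b.rss


# ---------------------------------------------------------------------------
# outbred validation populations
# ---------------------------------------------------------------------------

@dataclass
class OutbredAssocResult:
    table: pd.DataFrame        # genotype, n, lsmean, sd, letter
    overall: FTest
    pairwise: pd.DataFrame     # genotype pair, difference, se, q, p_adj


def _significance_letters(order, nsd) -> list:
    """Compact letter display: means sorted; maximal runs of pairwise-NSD
    classes share a letter."""
    k = len(order)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and all(nsd[order[i]][order[m]]
                                for m in range(i + 1, j + 2)):
            j += 1
        intervals.append((i, j))
    keep = [iv for iv in intervals
            if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                       for o in intervals)]
    letters = {g: "" for g in order}
    for lab, (i, j) in zip("abcdefghijklmnopqrstuvwxyz", keep):
        for m in range(i, j + 1):
            letters[order[m]] += lab
    return letters


def outbred_assoc(records: pd.DataFrame, genotype_col: str = "genotype",
                  factors=(), covariates=(),
                  response: str = "ear_size_cm2") -> OutbredAssocResult:
    """Genotype ANCOVA for a single outbred validation line.

    One-way analysis of the response on genotype class with any declared
    covariates/factors; pairwise genotype contrasts are Tukey-adjusted
    (studentized range) and summarised as significance letters (classes not
    sharing a letter differ).
    """
    full_spec = ModelSpec(response=response,
                          factors=tuple(factors) + (genotype_col,),
                          covariates=tuple(covariates))
    red_spec = ModelSpec(response=response, factors=tuple(factors),
                         covariates=tuple(covariates))
    records = drop_incomplete(records, full_spec)
    classes = sorted(records[genotype_col].astype(str).unique())
    if len(classes) < 2:
        raise ValueError("only one genotype class observed")
    fit_full = fit_ls(records, full_spec)
    fit_red = fit_ls(records, red_spec)
    overall = f_ratio(fit_red, fit_full)

    # least-squares means: average prediction with genotype forced to class g
    X, names, y = design_matrix(records, full_spec)
    beta, kept, dropped, rss, fitted, resid, rank, covu = _solve_ls(X, y, names)
    df = len(records) - rank
    sigma2 = rss / df
    kept_idx = {nm: i for i, nm in enumerate(kept)}
    Xk = X[:, [names.index(nm) for nm in kept]]
    base_row = Xk.mean(axis=0)
    gcols = {g: kept_idx.get(f"{genotype_col}[{g}]") for g in classes}
    contrast = {}
    for g in classes:
        c = base_row.copy()
        for h, i in gcols.items():
            if i is not None:
                c[i] = 1.0 if h == g else 0.0
        contrast[g] = c
    lsmean = {g: float(contrast[g] @ beta) for g in classes}

    k = len(classes)
    rows, nsd = [], {g: {} for g in classes}
    alpha = 0.05
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = classes[i], classes[j]
            c = contrast[gi] - contrast[gj]
            se = float(np.sqrt(sigma2 * c @ covu @ c))
            diff = lsmean[gi] - lsmean[gj]
            q = abs(diff) / (se / np.sqrt(2.0))
            p = float(stats.studentized_range.sf(q, k, df))
            rows.append({"pair": f"{gi} vs {gj}", "difference": diff,
                         "se": se, "q": q, "p_adj": min(p, 1.0)})
            nsd[gi][gj] = nsd[gj][gi] = p >= alpha
    for g in classes:
        nsd[g][g] = True
    pairwise = pd.DataFrame(rows)

    order = sorted(classes, key=lambda g: -lsmean[g])
    letters = _significance_letters(order, nsd)
    grp = records.groupby(records[genotype_col].astype(str))[response]
    table = pd.DataFrame({
        "genotype": classes,
        "n": [int(grp.count()[g]) for g in classes],
        "lsmean": [lsmean[g] for g in classes],
        "sd": [float(grp.std()[g]) if grp.count()[g] > 1 else np.nan
               for g in classes],
        "letter": [letters[g] for g in classes],
    })
    return OutbredAssocResult(table, overall, pairwise)


# ---------------------------------------------------------------------------
# the Table-1-like summary
# ---------------------------------------------------------------------------

def candidate_table(records: pd.DataFrame, candidates: pd.DataFrame,
                    snps, states: OriginGrid,
                    base_spec: ModelSpec | None = None,
                    mode: str = "at_peak") -> pd.DataFrame:
    """Per-SNP summary: P_sa, P_ma, additive effect, F_qtl/F_drop and RSS.

    One row per candidate SNP, mirroring the published association-table
    layout; the marker-assisted test uses the line-origin states at the
    model-2-vs-1 peak of each SNP's own record set.
    """
    base_spec = base_spec or ModelSpec()
    rows = []
    for snp in snps:
        fdrop = f_drop_test(records, candidates, states, base_spec, snp=snp,
                            mode=mode)
        p_sa = standard_assoc(records, candidates, base_spec, snp=snp)
        p_ma = marker_assisted_assoc(records, candidates, states, base_spec,
                                     snp=snp, position=fdrop.peak_position)
        eff = estimate_snp_effects(records, candidates, base_spec, snp=snp)
        data = _merge_snp(records, candidates, snp)
        data = drop_incomplete(data, base_spec.with_candidate("__snp"))
        fit3 = fit_ls(data, base_spec.with_candidate("__snp"))
        rows.append({
            "snp": snp,
            "P_sa": p_sa.p_value,
            "P_ma": p_ma.p_value,
            "allele": eff.reference_allele,
            "additive_effect": eff.effect,
            "se": eff.se,
            "F_qtl": fdrop.f_qtl,
            "F_drop": fdrop.f_drop,
            "drop_fraction": fdrop.drop_fraction,
            "rss_model3": fit3.rss,
        })
    return pd.DataFrame(rows)
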