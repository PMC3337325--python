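"""Forward simulator of a White Duroc x Erhualian-style F2 resource population.

No raw data from the original cross were ever deposited, so every pipeline
stage is exercised on synthetic crosses that emulate the study design: 2
founder-line sires mated to 17 founder-line dams, 9 F1 boars x 59 F1 sows
(full-sib matings avoided), 1912 F2 of which 1029 are phenotyped.  Meiosis is
simulated without interference (per-interval crossover indicators with
Haldane-consistent probabilities), microsatellites carry 4-8 alleles with
line-divergent frequencies, and the phenotype is generated by the mirror of
the analysis model: overall mean, 6 batch levels, 2 sexes, a carcass-weight
covariate, a planted QTN with additive/dominance effects by line origin, an
unlinked second-QTL genotype effect, a pedigree-correlated polygenic term and
a Gaussian residual.  Everything needed to check any stage against the truth
is recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .linkage import LinkageMap, build_map, haldane_d_to_r

__all__ = [
    "Locus",
    "BreedSpec",
    "CrossDesign",
    "PhenotypeModel",
    "SimTruth",
    "SimulatedCross",
    "Fixture",
    "STUDY_MAP_STRING",
    "study_map",
    "study_loci",
    "simulate_meiosis",
    "simulate_cross",
    "simulate_phenotypes",
    "simulate_outbred_line",
    "make_fixture",
]

# the SSC5 linkage map used throughout, written as marker - distance - marker
STUDY_MAP_STRING = (
    "Acr - 3.0 - SW413 - 40.0 - SWR453 - 5.4 - SSC5P3 - 12.3 - SW1904 - "
    "10.3 - SW2003 - 2.7 - SSC5P13 - 1.6 - SSC5P16 - 10.9 - SW1987 - "
    "21.1 - SW986 - 7.9 - SW995"
)

QTN_POSITION = 60.7  # cM, at SW1904 in the middle of the mapped QTL


def study_map() -> LinkageMap:
    """The 11-microsatellite SSC5 linkage map (cumulative cM from Acr)."""
    return build_map(STUDY_MAP_STRING)


@dataclass(frozen=True)
class Locus:
    """One simulated locus: name, cM position and per-line allele frequencies."""

    name: str
    position: float
    kind: str               # "msat" | "snp" | "qtn"
    alleles: tuple
    freq_a: tuple           # line-A allele frequencies
    freq_b: tuple

    def __post_init__(self):
        for fr in (self.freq_a, self.freq_b):
            if abs(sum(fr) - 1.0) > 1e-9 or len(fr) != len(self.alleles):
                raise ValueError(f"bad frequency vector for locus {self.name}")


@dataclass(frozen=True)
class BreedSpec:
    """Founder-line label plus its allele-frequency column of every locus."""

    label: str
    allele_freqs: dict

    def freq(self, locus: str):
        return np.asarray(self.allele_freqs[locus], dtype=float)


def _msat_freqs(n_alleles: int, conc: float = 0.35):
    """Line-divergent microsatellite frequencies: geometric weights for line A,
    the reverse ordering for line B.  ``conc`` sets how concentrated (and so
    how divergent between lines) the distributions are."""
    w = conc ** np.arange(n_alleles)
    fa = w / w.sum()
    return tuple(fa), tuple(fa[::-1])


def study_loci(divergence: float = 0.35) -> list:
    """Default chromosome loci: the 11 mapped microsatellites, a candidate-gene
    SNP window (snp_a, qtn, snp_b) around 60.7 cM, and a line-diagnostic SNP.

    The QTN is fixed for alternative alleles in the two founder lines (A in
    line W, G in line E), so its genotype coincides with its line-origin
    genotype; the flanking window SNPs are divergent but still segregate
    within lines, which is what makes several haplotypes appear in the F2.
    """
    gmap = study_map()
    n_alleles = [6, 4, 8, 5, 7, 4, 6, 5, 8, 6, 4]
    loci = []
    for name, pos, na in zip(gmap.markers, gmap.positions, n_alleles):
        fa, fb = _msat_freqs(na, divergence)
        alleles = tuple(str(k + 1) for k in range(na))
        loci.append(Locus(name, float(pos), "msat", alleles, fa, fb))
    loci.append(Locus("snp_a", 60.45, "snp", ("C", "T"), (0.85, 0.15), (0.15, 0.85)))
    loci.append(Locus("qtn", QTN_POSITION, "qtn", ("A", "G"), (1.0, 0.0), (0.0, 1.0)))
    loci.append(Locus("snp_b", 60.95, "snp", ("G", "A"), (0.8, 0.2), (0.2, 0.8)))
    loci.append(Locus("diag_snp", 80.0, "snp", ("T", "C"), (1.0, 0.0), (0.0, 1.0)))
    return sorted(loci, key=lambda l: l.position)


@dataclass(frozen=True)
class CrossDesign:
    """Counts and mating-scheme flags of the three-generation cross."""

    n_f0_sires: int = 2
    n_f0_dams: int = 17
    n_f1_boars: int = 9
    n_f1_sows: int = 59
    n_f2: int = 1912
    n_phenotyped: int = 1029
    avoid_fullsib: bool = True

    def __post_init__(self):
        if min(self.n_f0_sires, self.n_f0_dams, self.n_f1_boars,
               self.n_f1_sows, self.n_f2, self.n_phenotyped) <= 0:
            raise ValueError("design counts must be positive")
        if self.n_phenotyped > self.n_f2:
            raise ValueError("cannot phenotype more animals than exist")


@dataclass(frozen=True)
class PhenotypeModel:
    """Generative mirror of the analysis model (all effects in cm^2).

    Defaults place the QTN at 60.7 cM with additive effect a = -32.84 (line-W
    allele shrinks the ear), no dominance, and a polygenic/residual split of
    h2 = 0.4, which makes the QTN responsible for ~20% of the phenotypic
    variance that remains after the fixed effects.
    """

    mu: float = 290.0
    batch_effects: tuple = (0.0, 8.0, -6.0, 12.0, -10.0, 4.0)
    sex_effects: tuple = (0.0, 12.0)
    beta_cw: float = 0.9
    cw_mean: float = 75.0
    cw_sd: float = 8.0
    qtn_name: str = "qtn"
    a: float = -32.84
    d: float = 0.0
    ppard_effects: tuple = (-60.0, -30.0, 0.0)   # (WW, WE, EE) at the unlinked QTL
    sigma2_a: float = 862.7
    sigma2_e: float = 1294.1

    def __post_init__(self):
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be non-negative")

    @property
    def qtn_variance(self) -> float:
        """Variance contributed by the QTN in an F2 (origin frequencies 1/2)."""
        return self.a ** 2 / 2.0 + self.d ** 2 / 4.0


@dataclass
class SimTruth:
    """Everything needed to check pipeline output against the generator."""

    qtn_position: float
    a: float
    d: float
    heritability: float
    qtn_w_copies: dict        # F2 id -> copies of the line-W QTN allele (0/1/2)
    breeding_values: dict     # id -> polygenic value
    phenotyped_ids: list
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "schema_version": 1,
            "qtn_position": self.qtn_position,
            "a": self.a, "d": self.d,
            "heritability": self.heritability,
            "qtn_w_copies": self.qtn_w_copies,
            "breeding_values": {k: round(v, 6) for k, v in self.breeding_values.items()},
            "phenotyped_ids": self.phenotyped_ids,
            "seed": self.seed,
            "params": self.params,
        }
        return json.dumps(payload, indent=1)


@dataclass
class SimulatedCross:
    """In-memory cross: pedigree plus per-individual alleles and origins."""

    pedigree: pd.DataFrame
    loci: list
    ids: list
    alleles: np.ndarray        # (n, n_loci, 2) allele codes
    origins: np.ndarray        # (n, n_loci, 2); 1 = line A, 0 = line B
    ppard_w_copies: np.ndarray  # per individual, copies of the line-A allele
    line_a: str
    line_b: str
    seed: int

    @property
    def f2_ids(self) -> list:
        gen = self.pedigree.set_index("id")["generation"]
        return [i for i in self.ids if gen[i] == 2]

    def locus_index(self, name: str) -> int:
        return [l.name for l in self.loci].index(name)

    def genotype_frame(self, loci_names) -> pd.DataFrame:
        """Two allele columns per locus for every individual (TSV layout)."""
        cols = {"id": self.ids}
        for name in loci_names:
            j = self.locus_index(name)
            al = np.array(self.loci[j].alleles)
            cols[f"{name}_1"] = al[self.alleles[:, j, 0]]
            cols[f"{name}_2"] = al[self.alleles[:, j, 1]]
        return pd.DataFrame(cols)

    def origin_matrix(self, gmap: LinkageMap) -> tuple:
        """True (paternal, maternal) line origins of every F2 at map markers."""
        rows = [self.ids.index(i) for i in self.f2_ids]
        cols = [self.locus_index(m) for m in gmap.markers]
        O = self.origins[np.ix_(rows, cols)].astype(float)
        # (n, markers, 2) -> (n, 2, markers) to match linkage conventions
        return self.f2_ids, np.transpose(O, (0, 2, 1))


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _meiosis_batch(alleles, origins, parent_rows, r_int, rng):
    """One gamete per entry of ``parent_rows``; vectorised, no interference."""
    ng = len(parent_rows)
    nloci = alleles.shape[1]
    start = rng.integers(0, 2, ng, dtype=np.int8)
    if nloci > 1:
        flips = (rng.random((ng, nloci - 1)) < r_int).astype(np.int8)
        cum = np.concatenate(
            [np.zeros((ng, 1), dtype=np.int8), np.cumsum(flips, axis=1, dtype=np.int8)],
            axis=1)
        chrom = (start[:, None] + cum) % 2
    else:
        chrom = start[:, None]
    ar = np.arange(nloci)[None, :]
    gam_alleles = alleles[parent_rows[:, None], ar, chrom]
    gam_origins = origins[parent_rows[:, None], ar, chrom]
    return gam_alleles, gam_origins


def simulate_meiosis(parent_alleles, parent_origins, positions, rng):
    """Simulate one gamete from a parent chromosome pair.

    ``parent_alleles`` and ``parent_origins`` are (n_loci, 2); crossover
    indicators are drawn independently per interval with probability equal to
    the Haldane recombination fraction of the interval.
    """
    positions = np.asarray(positions, dtype=float)
    r_int = haldane_d_to_r(np.diff(positions))
    a = np.asarray(parent_alleles)[None, :, :]
    o = np.asarray(parent_origins)[None, :, :]
    ga, go = _meiosis_batch(a, o, np.zeros(1, dtype=int), r_int, rng)
    return ga[0], go[0]


# ---------------------------------------------------------------------------
# the cross
# ---------------------------------------------------------------------------

def simulate_cross(design: CrossDesign, loci: list, seed: int,
                   line_a: str = "W", line_b: str = "E") -> SimulatedCross:
    """Simulate the full three-generation cross with truth recorded.

    Line-A founders are the sires, line-B founders the dams (mirroring the
    White Duroc sires x Erhualian dams design).  F1 parents are drawn at
    random for each F2, resampling any pairing that would be a full-sib
    mating when ``design.avoid_fullsib`` is set.
    """
    rng = np.random.default_rng(seed)
    positions = np.array([l.position for l in loci])
    if np.any(np.diff(positions) < 0):
        raise ValueError("loci must be ordered by position")
    r_int = haldane_d_to_r(np.diff(positions))
    nloci = len(loci)

    n_sires, n_dams = design.n_f0_sires, design.n_f0_dams
    n_f1 = design.n_f1_boars + design.n_f1_sows
    n0 = n_sires + n_dams
    n = n0 + n_f1 + design.n_f2

    sire_ids = [f"{line_a}{k + 1}" for k in range(n_sires)]
    dam_ids = [f"{line_b}{k + 1:02d}" for k in range(n_dams)]
    f1_ids = [f"F1_{k + 1:02d}" for k in range(n_f1)]
    f2_ids = [f"F2_{k + 1:04d}" for k in range(design.n_f2)]
    ids = sire_ids + dam_ids + f1_ids + f2_ids

    alleles = np.zeros((n, nloci, 2), dtype=np.int16)
    origins = np.zeros((n, nloci, 2), dtype=np.int8)

    # founders: alleles from their line's frequencies, origins fixed
    for j, loc in enumerate(loci):
        fa = np.asarray(loc.freq_a)
        fb = np.asarray(loc.freq_b)
        alleles[:n_sires, j, :] = rng.choice(len(fa), size=(n_sires, 2), p=fa)
        alleles[n_sires:n0, j, :] = rng.choice(len(fb), size=(n_dams, 2), p=fb)
    origins[:n_sires] = 1
    origins[n_sires:n0] = 0

    # F1: each from a random founder sire and dam; paternal gamete first
    f1_sire = rng.integers(0, n_sires, n_f1)
    f1_dam = n_sires + rng.integers(0, n_dams, n_f1)
    pa, po = _meiosis_batch(alleles, origins, f1_sire, r_int, rng)
    ma, mo = _meiosis_batch(alleles, origins, f1_dam, r_int, rng)
    sl = slice(n0, n0 + n_f1)
    alleles[sl, :, 0], origins[sl, :, 0] = pa, po
    alleles[sl, :, 1], origins[sl, :, 1] = ma, mo

    # F2: random boar x sow pairs, avoiding full-sib matings
    boars = np.arange(n0, n0 + design.n_f1_boars)
    sows = np.arange(n0 + design.n_f1_boars, n0 + n_f1)
    f2_sire = rng.choice(boars, design.n_f2)
    f2_dam = rng.choice(sows, design.n_f2)
    if design.avoid_fullsib:
        for _ in range(1000):
            bad = ((f1_sire[f2_sire - n0] == f1_sire[f2_dam - n0])
                   & (f1_dam[f2_sire - n0] == f1_dam[f2_dam - n0]))
            if not bad.any():
                break
            f2_dam[bad] = rng.choice(sows, int(bad.sum()))
        else:
            raise ValueError("could not realise a mating scheme without full sibs")
    pa, po = _meiosis_batch(alleles, origins, f2_sire, r_int, rng)
    ma, mo = _meiosis_batch(alleles, origins, f2_dam, r_int, rng)
    sl = slice(n0 + n_f1, n)
    alleles[sl, :, 0], origins[sl, :, 0] = pa, po
    alleles[sl, :, 1], origins[sl, :, 1] = ma, mo

    # unlinked second QTL (PPARD-like): line-fixed alleles, independent drop
    ppard = np.zeros((n, 2), dtype=np.int8)
    ppard[:n_sires] = 1
    pp = ppard[f1_sire, rng.integers(0, 2, n_f1)]
    pm = ppard[f1_dam, rng.integers(0, 2, n_f1)]
    ppard[n0:n0 + n_f1, 0], ppard[n0:n0 + n_f1, 1] = pp, pm
    pp = ppard[f2_sire, rng.integers(0, 2, design.n_f2)]
    pm = ppard[f2_dam, rng.integers(0, 2, design.n_f2)]
    ppard[n0 + n_f1:, 0], ppard[n0 + n_f1:, 1] = pp, pm

    f1_sex = ["M"] * design.n_f1_boars + ["F"] * design.n_f1_sows
    f2_sex = np.where(rng.random(design.n_f2) < 0.5, "M", "F")
    pedigree = pd.DataFrame({
        "id": ids,
        "sire": [""] * n0 + [ids[k] for k in f1_sire] + [ids[k] for k in f2_sire],
        "dam": [""] * n0 + [ids[k] for k in f1_dam] + [ids[k] for k in f2_dam],
        "generation": [0] * n0 + [1] * n_f1 + [2] * design.n_f2,
        "sex": ["M"] * n_sires + ["F"] * n_dams + f1_sex + list(f2_sex),
        "breed": [line_a] * n_sires + [line_b] * n_dams + [""] * (n_f1 + design.n_f2),
    })
    return SimulatedCross(pedigree, list(loci), ids, alleles, origins,
                          ppard.sum(axis=1), line_a, line_b, seed)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

_PPARD_CLASS = {2: "11", 1: "12", 0: "22"}


def simulate_phenotypes(cross: SimulatedCross, model: PhenotypeModel,
                        seed: int, n_phenotyped: int | None = None):
    """Phenotype records for a random F2 subset, plus the SimTruth.

    y = mu + batch + sex + ppard + beta*cw + qtn(a, d by line-origin genotype)
        + polygenic + residual.

    The polygenic values are generated recursively (parent average plus a
    Mendelian-sampling deviation of variance sigma2_a/2), which makes their
    covariance exactly proportional to the pedigree A matrix here because no
    inbred animal is itself a parent.
    """
    rng = np.random.default_rng(seed)
    ped = cross.pedigree
    n_all = len(ped)
    idx = {i: k for k, i in enumerate(cross.ids)}

    # recursive polygenic values over the whole pedigree
    u = np.zeros(n_all)
    sa = np.sqrt(model.sigma2_a)
    gen = ped["generation"].to_numpy()
    sires = ped["sire"].to_numpy()
    dams = ped["dam"].to_numpy()
    founders = gen == 0
    u[founders] = rng.normal(0.0, sa, founders.sum())
    for g in (1, 2):
        rows = np.nonzero(gen == g)[0]
        si = np.array([idx[s] for s in sires[rows]])
        di = np.array([idx[d] for d in dams[rows]])
        u[rows] = 0.5 * (u[si] + u[di]) + rng.normal(
            0.0, np.sqrt(0.5 * model.sigma2_a), len(rows))

    f2 = cross.f2_ids
    if n_phenotyped is None:
        n_phenotyped = min(len(f2), 1029)
    chosen = sorted(rng.choice(len(f2), n_phenotyped, replace=False))
    ph_ids = [f2[k] for k in chosen]
    rows = np.array([idx[i] for i in ph_ids])

    jq = cross.locus_index(model.qtn_name)
    w_copies = (cross.origins[rows, jq, :] == 1).sum(axis=1)
    qtn_eff = model.a * (w_copies - 1.0) + model.d * (w_copies == 1)

    batch = rng.integers(1, len(model.batch_effects) + 1, n_phenotyped)
    sex = ped["sex"].to_numpy()[rows]
    sex_code = (sex == "F").astype(int)
    cw = rng.normal(model.cw_mean, model.cw_sd, n_phenotyped)
    pp_copies = cross.ppard_w_copies[rows]
    pp_eff = np.array(model.ppard_effects)[2 - pp_copies]

    y = (model.mu
         + np.array(model.batch_effects)[batch - 1]
         + np.array(model.sex_effects)[sex_code]
         + pp_eff
         + model.beta_cw * cw
         + qtn_eff
         + u[rows]
         + rng.normal(0.0, np.sqrt(model.sigma2_e), n_phenotyped))

    records = pd.DataFrame({
        "id": ph_ids,
        "ear_size_cm2": y,
        "batch": batch.astype(str),
        "sex": sex,
        "carcass_weight": cw,
        "ppard_genotype": [_PPARD_CLASS[c] for c in pp_copies],
    })

    h2 = (model.sigma2_a / (model.sigma2_a + model.sigma2_e)
          if model.sigma2_a + model.sigma2_e > 0 else 0.0)
    all_f2_rows = np.array([idx[i] for i in f2])
    truth = SimTruth(
        qtn_position=[l.position for l in cross.loci][jq],
        a=model.a, d=model.d, heritability=h2,
        qtn_w_copies={i: int(c) for i, c in zip(
            f2, (cross.origins[all_f2_rows, jq, :] == 1).sum(axis=1))},
        breeding_values={i: float(u[idx[i]]) for i in cross.ids},
        phenotyped_ids=ph_ids,
        seed=seed,
        params={"mu": model.mu, "sigma2_a": model.sigma2_a,
                "sigma2_e": model.sigma2_e, "beta_cw": model.beta_cw,
                "qtn_variance": model.qtn_variance},
    )
    return records, truth


def simulate_outbred_line(seed: int, n: int = 173,
                          class_probs=(0.52, 0.44, 0.04),
                          class_means=(258.57, 292.60, 323.50),
                          residual_sd: float = 42.0,
                          sex_effect: float = 8.0,
                          alleles=("A", "G")) -> pd.DataFrame:
    """A single synthetic commercial line segregating one candidate SNP.

    Genotype classes (ref hom, het, alt hom) are drawn with ``class_probs``
    and phenotypes from class means plus a sex shift and Gaussian noise,
    emulating the structure of a Sutai-like validation population.
    """
    rng = np.random.default_rng(seed)
    cls = rng.choice(3, n, p=np.asarray(class_probs, dtype=float))
    a, b = alleles
    geno = np.array([a + a, a + b, b + b])[cls]
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    y = (np.asarray(class_means)[cls]
         + np.where(sex == "F", sex_effect, 0.0)
         + rng.normal(0.0, residual_sd, n))
    return pd.DataFrame({
        "id": [f"OB_{k + 1:03d}" for k in range(n)],
        "ear_size_cm2": y,
        "sex": sex,
        "genotype": geno,
    })


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SCENARIOS = ("null", "paper_like", "qtn_genotyped", "outbred_line")

CANDIDATE_SNPS = ("snp_a", "qtn", "snp_b", "diag_snp")


@dataclass
class Fixture:
    """A complete on-disk-shaped dataset for one scenario."""

    scenario: str
    gmap: LinkageMap
    pedigree: pd.DataFrame | None
    genotypes: pd.DataFrame | None
    phenotypes: pd.DataFrame
    candidates: pd.DataFrame | None
    truth: SimTruth | None
    cross: SimulatedCross | None = None

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _save(name, frame):
            p = out / name
            frame.to_csv(p, sep="\t", index=False, na_rep="NA")
            paths[name] = p

        _save("map.tsv", self.gmap.to_frame("5"))
        _save("phenotypes.tsv", self.phenotypes)
        if self.pedigree is not None:
            _save("pedigree.tsv", self.pedigree)
        if self.genotypes is not None:
            _save("genotypes.tsv", self.genotypes)
        if self.candidates is not None:
            _save("candidates.tsv", self.candidates)
        if self.truth is not None:
            p = out / "truth.json"
            p.write_text(self.truth.to_json())
            paths["truth.json"] = p
        return paths


def make_fixture(scenario: str, seed: int,
                 design: CrossDesign | None = None,
                 model: PhenotypeModel | None = None,
                 divergence: float = 0.35) -> Fixture:
    """Generate a complete dataset for one named scenario.

    ``null``            scaled-down cross (400 F2, all phenotyped) with a = d = 0
                        and no polygenic variance: phenotypes carry fixed effects
                        and noise only.
    ``paper_like``      the full study design with the default phenotype model.
    ``qtn_genotyped``   paper_like, with the causal QTN among the candidate SNPs.
    ``outbred_line``    a single synthetic commercial line (no pedigree).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    gmap = study_map()

    if scenario == "outbred_line":
        pheno = simulate_outbred_line(seed)
        return Fixture(scenario, gmap, None, None, pheno, None, None)

    if scenario == "null":
        if design is None:
            design = CrossDesign(n_f2=400, n_phenotyped=400)
        if model is None:
            model = PhenotypeModel(a=0.0, d=0.0, sigma2_a=0.0, sigma2_e=2156.9)
    else:
        if design is None:
            design = CrossDesign()
        if model is None:
            model = PhenotypeModel()

    loci = study_loci(divergence)
    cross = simulate_cross(design, loci, seed)
    records, truth = simulate_phenotypes(cross, model, seed + 1,
                                         n_phenotyped=design.n_phenotyped)
    truth.params["scenario"] = scenario
    genotypes = cross.genotype_frame(gmap.markers)
    candidates = cross.genotype_frame(CANDIDATE_SNPS)
    return Fixture(scenario, gmap, cross.pedigree, genotypes, records,
                   candidates, truth, cross)
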