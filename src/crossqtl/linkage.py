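"""Linkage-map arithmetic and breed-line-origin probabilities for F2 crosses.

In a line cross between two divergent founder breeds, every F2 chromosome is a
mosaic of segments inherited from one founder line or the other.  At any scan
position x the genotype of interest is not the marker allele itself but the
pair of *line origins* of the two chromosomes, summarised as the probabilities
(p_ww, p_we, p_ee) that the individual carries two line-A alleles, one of
each, or two line-B alleles.  The regression coefficients used by the scan are
the classical line-cross codes

    c_a = p_ww - p_ee          (expected additive dosage, in [-1, 1])
    c_d = p_we                 (heterosis/dominance probability, in [0, 1])

computed from the nearest informative flanking markers under a no-interference
(Haldane) meiosis model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageMap",
    "LineOriginState",
    "GameteOriginTrack",
    "OriginGrid",
    "MendelianError",
    "haldane_d_to_r",
    "haldane_r_to_d",
    "build_map",
    "gamete_origin_probability",
    "line_origin_state_f2",
    "tracks_from_genotypes",
    "origin_matrix_from_genotypes",
    "origin_grid",
]


# ---------------------------------------------------------------------------
# map function
# ---------------------------------------------------------------------------

def haldane_d_to_r(d):
    """Map distance (cM) -> recombination fraction, Haldane (no interference).

    r = 0.5 * (1 - exp(-2 d / 100)).  Accepts scalars or arrays; rejects
    negative distances.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def haldane_r_to_d(r):
    """Recombination fraction -> map distance in cM (inverse Haldane)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# linkage map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageMap:
    """Ordered markers with cM positions from the first mapped marker."""

    markers: tuple
    positions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.markers) < 2:
            raise ValueError("a linkage map needs at least 2 markers")
        if len(self.markers) != len(pos):
            raise ValueError("markers and positions differ in length")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker identifiers")
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be non-decreasing")

    def __len__(self):
        return len(self.markers)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def position_of(self, marker: str) -> float:
        try:
            return float(self.positions[self.markers.index(marker)])
        except ValueError:
            raise KeyError(f"marker {marker!r} not on map") from None

    def scan_positions(self, step: float) -> np.ndarray:
        """Scan grid at a fixed step, including both map ends."""
        if step <= 0:
            raise ValueError("step must be positive")
        lo, hi = self.span
        pos = np.arange(lo, hi, step)
        if pos.size == 0 or pos[-1] < hi:
            pos = np.append(pos, hi)
        return pos

    def to_frame(self, chromosome: str = "1") -> pd.DataFrame:
        return pd.DataFrame(
            {"chromosome": chromosome, "marker": list(self.markers),
             "position_cM": self.positions}
        )


def build_map(segments) -> LinkageMap:
    """Build a LinkageMap from an alternating name/distance description.

    ``segments`` is either a string like ``"Acr - 3.0 - SW413 - 40.0 - SWR453"``
    or a flat sequence ``["Acr", 3.0, "SW413", 40.0, "SWR453"]``.  Cumulative
    positions start at 0 at the first marker.
    """
    if isinstance(segments, str):
        parts = [p.strip() for p in segments.split("-")]
        parts = [p for p in parts if p != ""]
    else:
        parts = list(segments)
    if len(parts) % 2 == 0 or len(parts) < 3:
        raise ValueError("expected alternating marker, distance, marker, ...")
    names = [str(p) for p in parts[0::2]]
    dists = [float(p) for p in parts[1::2]]
    if any(d < 0 for d in dists):
        raise ValueError("negative inter-marker distance")
    positions = np.concatenate([[0.0], np.cumsum(dists)])
    return LinkageMap(tuple(names), positions)


# ---------------------------------------------------------------------------
# origin states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineOriginState:
    """Line-origin genotype probabilities at one position for one individual."""

    position: float
    p_ww: float
    p_we: float
    p_ee: float

    def __post_init__(self):
        s = self.p_ww + self.p_we + self.p_ee
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"origin probabilities sum to {s}, not 1")

    @property
    def c_a(self) -> float:
        return self.p_ww - self.p_ee

    @property
    def c_d(self) -> float:
        return self.p_we


@dataclass(frozen=True)
class GameteOriginTrack:
    """Breed-origin labels of one transmitted gamete at informative markers."""

    positions: np.ndarray
    origins: tuple  # founder-breed labels, parallel to positions

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "origins", tuple(self.origins))
        if len(pos) != len(self.origins):
            raise ValueError("positions and origins differ in length")
        if np.any(np.diff(pos) < 0):
            raise ValueError("track positions must be non-decreasing")

    def __len__(self):
        return len(self.origins)


def gamete_origin_probability(track: GameteOriginTrack, gmap: LinkageMap,
                              position: float, line: str) -> float:
    """Probability that the transmitted allele at ``position`` is of ``line`` origin.

    Conditions on the nearest informative flanking markers only, assuming no
    interference: for flanks with origins (O_L, O_R) at recombination fractions
    r_L, r_R from the position, the two crossover configurations compatible
    with each candidate origin are weighted by their Haldane probabilities.
    Beyond the outermost informative marker, conditioning is on that single
    marker; a scan position coinciding with an informative marker is its own
    (degenerate) flank.
    """
    if len(track) == 0:
        raise ValueError("empty gamete origin track")
    lo, hi = gmap.span
    if not (lo <= position <= hi):
        raise ValueError(f"position {position} outside map span [{lo}, {hi}]")
    pos = track.positions
    left = np.nonzero(pos <= position)[0]
    right = np.nonzero(pos >= position)[0]
    iL = left[-1] if left.size else None
    iR = right[0] if right.size else None
    if iL is not None and iR is not None and np.isclose(pos[iL], pos[iR]):
        # degenerate flank: the marker itself
        return 1.0 if track.origins[iL] == line else 0.0
    if iL is not None and iR is not None:
        rL = haldane_d_to_r(position - pos[iL])
        rR = haldane_d_to_r(pos[iR] - position)
        pL = (1.0 - rL) if track.origins[iL] == line else rL
        pR = (1.0 - rR) if track.origins[iR] == line else rR
        return pL * pR / (pL * pR + (1.0 - pL) * (1.0 - pR))
    if iL is not None:
        r = haldane_d_to_r(position - pos[iL])
        return (1.0 - r) if track.origins[iL] == line else r
    r = haldane_d_to_r(pos[iR] - position)
    return (1.0 - r) if track.origins[iR] == line else r


def line_origin_state_f2(maternal_track: GameteOriginTrack,
                         paternal_track: GameteOriginTrack,
                         gmap: LinkageMap, position: float,
                         line: str) -> LineOriginState:
    """Combine the two gametes' origin probabilities into a LineOriginState.

    The two transmitted gametes are independent given the parental marker
    data, so p_ww is the product of the per-gamete probabilities, p_ee the
    product of their complements, and p_we the remainder.
    """
    pm = gamete_origin_probability(maternal_track, gmap, position, line)
    pp = gamete_origin_probability(paternal_track, gmap, position, line)
    p_ww = pm * pp
    p_ee = (1.0 - pm) * (1.0 - pp)
    return LineOriginState(position, p_ww, 1.0 - p_ww - p_ee, p_ee)


# ---------------------------------------------------------------------------
# origin tracks from pedigree + genotypes
# ---------------------------------------------------------------------------

class MendelianError(ValueError):
    """Genotypes inconsistent with the pedigree; carries (individual, marker)."""

    def __init__(self, failures):
        self.failures = list(failures)
        ind, marker = self.failures[0]
        more = f" (+{len(self.failures) - 1} more)" if len(self.failures) > 1 else ""
        super().__init__(
            f"Mendelian inconsistency at individual {ind!r}, marker {marker!r}{more}"
        )


def _allele_codes(genotypes: pd.DataFrame, markers) -> np.ndarray:
    """(n, n_markers, 2) integer allele codes; -1 encodes missing."""
    n = len(genotypes)
    G = np.empty((n, len(markers), 2), dtype=np.int32)
    for j, m in enumerate(markers):
        # factorize both allele columns jointly so they share a code space
        both = pd.concat(
            [genotypes[f"{m}_1"].astype(str).str.strip(),
             genotypes[f"{m}_2"].astype(str).str.strip()], ignore_index=True)
        missing = both.isin(("0", "NA", "nan", ""))
        codes, _ = pd.factorize(both)
        codes = codes.copy()
        codes[missing.to_numpy()] = -1
        G[:, j, 0] = codes[:n]
        G[:, j, 1] = codes[n:]
    return G


def _resolve_transmission(cx, cy, pa, pb, qa, qb):
    """Which child allele came from parent P ({pa,pb}) vs parent Q ({qa,qb}).

    All arguments are integer code arrays of the same shape.  Returns
    (known, from_p, from_q, bad): ``known`` marks entries with a unique
    assignment, ``bad`` marks Mendelian inconsistencies.  Missing codes (-1)
    make an entry unknown, never bad.
    """
    miss = (cx < 0) | (cy < 0) | (pa < 0) | (pb < 0) | (qa < 0) | (qb < 0)
    x_in_p = (cx == pa) | (cx == pb)
    y_in_p = (cy == pa) | (cy == pb)
    x_in_q = (cx == qa) | (cx == qb)
    y_in_q = (cy == qa) | (cy == qb)
    v1 = x_in_p & y_in_q          # cx from P, cy from Q
    v2 = y_in_p & x_in_q          # cy from P, cx from Q
    bad = ~miss & ~v1 & ~v2
    known = ~miss & (v1 ^ v2 | (v1 & v2 & (cx == cy)))
    from_p = np.where(v1, cx, cy)
    from_q = np.where(v1, cy, cx)
    return known, from_p, from_q, bad


def origin_matrix_from_genotypes(pedigree: pd.DataFrame,
                                 genotypes: pd.DataFrame,
                                 gmap: LinkageMap,
                                 line: str | None = None):
    """Vectorised origin resolution for every F2 gamete at every map marker.

    Returns ``(f2_ids, O, line)`` where ``O`` has shape (n_f2, 2, n_markers)
    with entries 1.0 (origin = focal line), 0.0 (other line) or NaN
    (uninformative in that family); axis 1 is (paternal, maternal).

    Origins are resolved by Mendelian transmission logic: each F1 allele is
    assigned to its founder (breed-labelled) parent where the assignment is
    unique, and each F2 allele is traced to one of its F1 parent's two alleles
    the same way.  Markers where the trace is ambiguous, or where the F1 is
    homozygous, are uninformative for that gamete and dropped.
    """
    ped = pedigree.set_index("id")
    breeds = ped["breed"].dropna()
    breeds = breeds[breeds.astype(str) != ""]
    labels = sorted(set(breeds))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 founder breed labels, got {labels}")
    if line is None:
        # default focal line: the founder sires' breed (the line whose allele
        # dosage c_a counts positively), falling back to alphabetical order
        sires = set(ped["sire"]) - {"", "0"}
        sire_breeds = sorted({str(ped.at[s, "breed"]) for s in sires
                              if s in ped.index} & set(labels))
        line = sire_breeds[0] if len(sire_breeds) == 1 else labels[0]
    elif line not in labels:
        raise ValueError(f"line {line!r} not among founder breeds {labels}")

    markers = list(gmap.markers)
    gt = genotypes.set_index("id")
    gt = gt.loc[:, [f"{m}_{k}" for m in markers for k in (1, 2)]]
    ids = gt.index.to_list()
    idx = {i: k for k, i in enumerate(ids)}
    G = _allele_codes(gt.reset_index(), markers)

    gen = ped["generation"].astype(int)
    f1_ids = [i for i in ids if i in gen.index and gen[i] == 1]
    f2_ids = [i for i in ids if i in gen.index and gen[i] == 2]

    failures = []

    # --- phase F1s against their founder parents -------------------------
    n1 = len(f1_ids)
    nm = len(markers)
    f1_row = np.array([idx[i] for i in f1_ids])
    f1_sire = np.array([idx[ped.at[i, "sire"]] for i in f1_ids])
    f1_dam = np.array([idx[ped.at[i, "dam"]] for i in f1_ids])
    sire_is_line = np.array(
        [str(ped.at[ped.at[i, "sire"], "breed"]) == line for i in f1_ids])

    C = G[f1_row]
    S = G[f1_sire]
    D = G[f1_dam]
    known, from_s, from_d, bad = _resolve_transmission(
        C[:, :, 0], C[:, :, 1], S[:, :, 0], S[:, :, 1], D[:, :, 0], D[:, :, 1])
    if bad.any():
        for a, b in zip(*np.nonzero(bad)):
            failures.append((f1_ids[a], markers[b]))
        raise MendelianError(failures)
    # allele of the focal line in each F1 (and of the other line)
    line_allele = np.where(sire_is_line[:, None], from_s, from_d)
    other_allele = np.where(sire_is_line[:, None], from_d, from_s)
    f1_informative = known & (line_allele != other_allele)
    f1_pos = {i: k for k, i in enumerate(f1_ids)}

    # --- trace each F2 allele to an F1 parental allele -------------------
    n2 = len(f2_ids)
    f2_row = np.array([idx[i] for i in f2_ids])
    f2_sire = np.array([idx[ped.at[i, "sire"]] for i in f2_ids])
    f2_dam = np.array([idx[ped.at[i, "dam"]] for i in f2_ids])
    sire_k = np.array([f1_pos[ped.at[i, "sire"]] for i in f2_ids])
    dam_k = np.array([f1_pos[ped.at[i, "dam"]] for i in f2_ids])

    C = G[f2_row]
    S = G[f2_sire]
    D = G[f2_dam]
    known2, from_s2, from_d2, bad2 = _resolve_transmission(
        C[:, :, 0], C[:, :, 1], S[:, :, 0], S[:, :, 1], D[:, :, 0], D[:, :, 1])
    if bad2.any():
        for a, b in zip(*np.nonzero(bad2)):
            failures.append((f2_ids[a], markers[b]))
        raise MendelianError(failures)

    O = np.full((n2, 2, nm), np.nan)
    for g, (trans, par_k) in enumerate(((from_s2, sire_k), (from_d2, dam_k))):
        par_line = line_allele[par_k]
        par_other = other_allele[par_k]
        par_inf = f1_informative[par_k]
        ok = known2 & par_inf & ((trans == par_line) | (trans == par_other))
        val = np.where(trans == par_line, 1.0, 0.0)
        O[:, g, :] = np.where(ok, val, np.nan)
    return f2_ids, O, line


def tracks_from_genotypes(pedigree: pd.DataFrame, genotypes: pd.DataFrame,
                          gmap: LinkageMap, line: str | None = None,
                          other: str | None = None) -> dict:
    """Per-F2 ``(paternal, maternal)`` GameteOriginTrack pairs.

    Thin object layer over :func:`origin_matrix_from_genotypes`; markers that
    are uninformative for a gamete are absent from its track.
    """
    f2_ids, O, line = origin_matrix_from_genotypes(pedigree, genotypes, gmap, line)
    ped = pedigree.set_index("id")
    breeds = ped["breed"].dropna()
    labels = sorted(set(breeds[breeds.astype(str) != ""]))
    other = [b for b in labels if b != line][0]
    pos = gmap.positions
    out = {}
    for k, ind in enumerate(f2_ids):
        pair = []
        for g in (0, 1):
            keep = ~np.isnan(O[k, g])
            origins = tuple(line if v == 1.0 else other for v in O[k, g, keep])
            pair.append(GameteOriginTrack(pos[keep], origins))
        out[ind] = tuple(pair)
    return out


# ---------------------------------------------------------------------------
# origin-state grids for scanning
# ---------------------------------------------------------------------------

@dataclass
class OriginGrid:
    """Line-origin probabilities for many individuals on a scan grid.

    Arrays are (n_individuals, n_positions); ``ids`` gives the row order and
    ``line`` names the founder breed whose dosage c_a counts positively.
    """

    ids: list
    positions: np.ndarray
    p_ww: np.ndarray
    p_we: np.ndarray
    p_ee: np.ndarray
    line: str = "A"

    def __post_init__(self):
        s = self.p_ww + self.p_we + self.p_ee
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("origin probabilities do not sum to 1")

    @property
    def c_a(self) -> np.ndarray:
        return self.p_ww - self.p_ee

    @property
    def c_d(self) -> np.ndarray:
        return self.p_we

    def state(self, ind, position) -> LineOriginState:
        i = self.ids.index(ind)
        j = int(np.argmin(np.abs(self.positions - position)))
        return LineOriginState(float(self.positions[j]),
                               float(self.p_ww[i, j]),
                               float(self.p_we[i, j]),
                               float(self.p_ee[i, j]))

    def reindex(self, ids) -> "OriginGrid":
        rows = [self.ids.index(i) for i in ids]
        return OriginGrid(list(ids), self.positions, self.p_ww[rows],
                          self.p_we[rows], self.p_ee[rows], self.line)


def _gamete_probability_grid(O: np.ndarray, marker_pos: np.ndarray,
                             scan_pos: np.ndarray) -> np.ndarray:
    """P(focal-line origin) for each gamete row of ``O`` at each scan position.

    ``O`` is (n_gametes, n_markers) with entries 1/0/NaN.  Vectorised
    nearest-informative-flank conditioning.
    """
    ng, nm = O.shape
    inf = ~np.isnan(O)
    ar = np.arange(nm)
    # prev[k] = index of last informative marker <= k; next_[k] = first >= k
    prev = np.where(inf, ar[None, :], -1)
    np.maximum.accumulate(prev, axis=1, out=prev)
    next_ = np.where(inf, ar[None, :], nm)
    next_ = np.flip(np.minimum.accumulate(np.flip(next_, axis=1), axis=1), axis=1)

    P = np.full((ng, len(scan_pos)), 0.5)
    Ofill = np.nan_to_num(O, nan=0.0)
    for j, x in enumerate(scan_pos):
        k = np.searchsorted(marker_pos, x, side="right") - 1
        kR = np.searchsorted(marker_pos, x, side="left")
        iL = prev[:, k] if k >= 0 else np.full(ng, -1)
        iR = next_[:, kR] if kR < nm else np.full(ng, nm)
        hasL = iL >= 0
        hasR = iR < nm
        iLs = np.where(hasL, iL, 0)
        iRs = np.where(hasR, iR, 0)
        rL = haldane_d_to_r(np.maximum(x - marker_pos[iLs], 0.0))
        rR = haldane_d_to_r(np.maximum(marker_pos[iRs] - x, 0.0))
        oL = np.take_along_axis(Ofill, iLs[:, None], axis=1)[:, 0]
        oR = np.take_along_axis(Ofill, iRs[:, None], axis=1)[:, 0]
        pL = np.where(oL == 1.0, 1.0 - rL, rL)
        pR = np.where(oR == 1.0, 1.0 - rR, rR)
        both = hasL & hasR
        num = pL * pR
        den = num + (1.0 - pL) * (1.0 - pR)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_both = np.where(den > 0, num / den, 0.5)
        P[:, j] = np.where(both, p_both,
                           np.where(hasL, pL, np.where(hasR, pR, 0.5)))
    return P


def origin_grid(pedigree: pd.DataFrame, genotypes: pd.DataFrame,
                gmap: LinkageMap, step: float = 1.0,
                positions: np.ndarray | None = None,
                line: str | None = None) -> OriginGrid:
    """Compute the OriginGrid for all F2s straight from pedigree + genotypes."""
    f2_ids, O, line = origin_matrix_from_genotypes(pedigree, genotypes, gmap, line)
    if positions is None:
        positions = gmap.scan_positions(step)
    positions = np.asarray(positions, dtype=float)
    return origin_grid_from_matrix(f2_ids, O, gmap, positions, line)


def origin_grid_from_matrix(f2_ids, O: np.ndarray, gmap: LinkageMap,
                            positions: np.ndarray, line: str) -> OriginGrid:
    n = len(f2_ids)
    Pp = _gamete_probability_grid(O[:, 0, :], gmap.positions, positions)
    Pm = _gamete_probability_grid(O[:, 1, :], gmap.positions, positions)
    p_ww = Pp * Pm
    p_ee = (1.0 - Pp) * (1.0 - Pm)
    p_we = 1.0 - p_ww - p_ee
    return OriginGrid(list(f2_ids), positions, p_ww, p_we, p_ee, line)
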