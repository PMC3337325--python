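"""Map arithmetic, origin probabilities, and the crossover-enumeration oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossqtl.linkage import (GameteOriginTrack, LineOriginState, LinkageMap,
                              build_map, gamete_origin_probability,
                              haldane_d_to_r, haldane_r_to_d,
                              line_origin_state_f2,
                              origin_matrix_from_genotypes, origin_grid,
                              tracks_from_genotypes)
from crossqtl.simulate import (STUDY_MAP_STRING, make_fixture, study_map,
                               simulate_cross, CrossDesign, study_loci)


# ---------------------------------------------------------------------------
# map function
# ---------------------------------------------------------------------------

def test_haldane_closed_form_values():
    assert haldane_d_to_r(0.0) == 0.0
    assert haldane_d_to_r(10.0) == pytest.approx(0.090635, abs=1e-6)
    assert haldane_r_to_d(0.25) == pytest.approx(34.657, abs=1e-3)


def test_haldane_monotone_and_bounded():
    d = np.linspace(0, 500, 200)
    r = haldane_d_to_r(d)
    assert np.all(np.diff(r) > 0)
    assert np.all((r >= 0) & (r < 0.5))


def test_haldane_rejects_negative():
    with pytest.raises(ValueError):
        haldane_d_to_r(-1.0)


# ---------------------------------------------------------------------------
# building the map
# ---------------------------------------------------------------------------

def test_study_map_cumulative_positions():
    gmap = study_map()
    assert gmap.position_of("SWR453") == pytest.approx(43.0)
    assert gmap.position_of("SSC5P3") == pytest.approx(48.4)
    assert gmap.position_of("SW1904") == pytest.approx(60.7)
    assert gmap.position_of("SW2003") == pytest.approx(71.0)
    assert gmap.position_of("SW995") == pytest.approx(115.2)


def test_build_map_degenerate_interval():
    gmap = build_map(["A", 0.0, "B"])
    assert list(gmap.positions) == [0.0, 0.0]


def test_build_map_rejects_bad_input():
    with pytest.raises(ValueError):
        build_map(["A", 3.0, "A"])      # duplicate marker
    with pytest.raises(ValueError):
        build_map(["A", -1.0, "B"])     # negative distance


def test_scan_positions_include_both_ends():
    gmap = study_map()
    pos = gmap.scan_positions(1.0)
    assert pos[0] == 0.0 and pos[-1] == pytest.approx(115.2)


# ---------------------------------------------------------------------------
# single-gamete origin probability vs enumeration oracle
# ---------------------------------------------------------------------------

def _enumerate_origin_probability(marker_pos, marker_origins, query, line="W"):
    """Brute force: enumerate every crossover-indicator pattern over the loci
    (markers + query), weight by per-interval Haldane probabilities, and
    condition on the observed marker origins."""
    loci = sorted(set(marker_pos) | {query})
    r = [haldane_d_to_r(b - a) for a, b in zip(loci, loci[1:])]
    want = dict(zip(marker_pos, marker_origins))
    total = match = 0.0
    for start, flips in itertools.product("WE", itertools.product(
            (0, 1), repeat=len(r))):
        w = 0.5
        state = start
        origins = {}
        for k, x in enumerate(loci):
            if k > 0:
                w *= r[k - 1] if flips[k - 1] else 1.0 - r[k - 1]
                if flips[k - 1]:
                    state = "E" if state == "W" else "W"
            origins[x] = state
        if all(origins[x] == want[x] for x in marker_pos):
            total += w
            if origins[query] == line:
                match += w
    return match / total


TOY_MAP = LinkageMap(("m1", "m2", "m3"), np.array([0.0, 20.0, 35.0]))


@pytest.mark.parametrize("origins,query", [
    (("W", "W", "W"), 10.0),
    (("W", "E", "W"), 10.0),
    (("W", "E", "E"), 5.0),
    (("E", "W", "E"), 27.0),
    (("W", "E", "W"), 20.0),
    (("W", "W", "E"), 30.0),
])
def test_origin_probability_matches_enumeration(origins, query):
    track = GameteOriginTrack(TOY_MAP.positions, origins)
    got = gamete_origin_probability(track, TOY_MAP, query, "W")
    want = _enumerate_origin_probability(list(TOY_MAP.positions), origins, query)
    assert got == pytest.approx(want, abs=1e-9)


def test_origin_probability_spec_cases():
    gmap = LinkageMap(("a", "b"), np.array([0.0, 20.0]))
    track = GameteOriginTrack([0.0, 20.0], ("W", "E"))
    # at an informative marker the probability is degenerate
    assert gamete_origin_probability(track, gmap, 0.0, "W") == 1.0
    # midpoint of a recombinant interval: symmetry
    assert gamete_origin_probability(track, gmap, 10.0, "W") == pytest.approx(0.5)
    # 5 cM from the W flank: (1-r(5)) r(15) / r(20)
    r5, r15, r20 = (haldane_d_to_r(x) for x in (5, 15, 20))
    assert gamete_origin_probability(track, gmap, 5.0, "W") == pytest.approx(
        (1 - r5) * r15 / r20, abs=1e-12)
    assert gamete_origin_probability(track, gmap, 5.0, "W") == pytest.approx(
        0.7488, abs=5e-5)


def test_single_flank_information_decays_towards_half():
    gmap = LinkageMap(("a", "b"), np.array([0.0, 100.0]))
    track = GameteOriginTrack([0.0], ("W",))
    ps = [gamete_origin_probability(track, gmap, d, "W")
          for d in np.linspace(0.0, 100.0, 30)]
    assert ps[0] == 1.0
    assert np.all(np.diff(ps) < 0)
    assert ps[-1] > 0.5


def test_empty_track_rejected():
    with pytest.raises(ValueError):
        gamete_origin_probability(GameteOriginTrack([], ()), TOY_MAP, 1.0, "W")


# ---------------------------------------------------------------------------
# two-gamete states
# ---------------------------------------------------------------------------

def test_line_origin_state_products():
    gmap = LinkageMap(("a", "b"), np.array([0.0, 20.0]))
    w = GameteOriginTrack([0.0, 20.0], ("W", "W"))
    e = GameteOriginTrack([0.0, 20.0], ("E", "E"))
    s = line_origin_state_f2(w, w, gmap, 0.0, "W")
    assert (s.p_ww, s.p_we, s.p_ee) == (1.0, 0.0, 0.0)
    assert s.c_a == 1.0 and s.c_d == 0.0
    s = line_origin_state_f2(w, e, gmap, 0.0, "W")
    assert s.p_we == 1.0 and s.c_a == 0.0

    rec = GameteOriginTrack([0.0, 20.0], ("W", "E"))
    pm = gamete_origin_probability(rec, gmap, 5.0, "W")
    pp = gamete_origin_probability(w, gmap, 5.0, "W")  # ~0.993, double-crossover
    s = line_origin_state_f2(rec, w, gmap, 5.0, "W")
    assert s.p_ww == pytest.approx(pm * pp, abs=1e-12)
    assert s.p_ee == pytest.approx((1 - pm) * (1 - pp), abs=1e-12)
    assert s.c_a == pytest.approx(s.p_ww - s.p_ee, abs=1e-12)


@settings(deadline=None, max_examples=150, derandomize=True)
@given(
    o1=st.tuples(*[st.sampled_from("WE")] * 3),
    o2=st.tuples(*[st.sampled_from("WE")] * 3),
    x=st.floats(min_value=0.0, max_value=40.0, allow_nan=False),
)
def test_state_invariants_on_random_tracks(o1, o2, x):
    gmap = LinkageMap(("a", "b", "c"), np.array([0.0, 12.0, 40.0]))
    t1 = GameteOriginTrack(gmap.positions, o1)
    t2 = GameteOriginTrack(gmap.positions, o2)
    s = line_origin_state_f2(t1, t2, gmap, x, "W")
    assert abs(s.p_ww + s.p_we + s.p_ee - 1) < 1e-9
    assert -1.0 <= s.c_a <= 1.0
    assert 0.0 <= s.c_d <= 1.0


def test_probability_closure_fails_loudly():
    with pytest.raises(ValueError):
        LineOriginState(0.0, 0.6, 0.6, 0.1)


# ---------------------------------------------------------------------------
# Monte-Carlo consistency of the meiosis model and the probability machinery
# ---------------------------------------------------------------------------

def test_origin_probability_matches_simulated_gametes():
    """Empirical origin frequencies among 100k simulated F1 gametes,
    conditioned on the flanking-marker origin pattern, match the computed
    probabilities within 3 binomial standard errors."""
    from crossqtl.simulate import _meiosis_batch

    rng = np.random.default_rng(99)
    pos = np.array([0.0, 20.0, 35.0])
    r_int = haldane_d_to_r(np.diff(pos))
    # an F1 parent: one whole-W and one whole-E chromosome
    alleles = np.zeros((1, 3, 2), dtype=np.int16)
    origins = np.stack([np.ones((1, 3), dtype=np.int8),
                        np.zeros((1, 3), dtype=np.int8)], axis=2)
    ga, go = _meiosis_batch(alleles, origins, np.zeros(100_000, dtype=int),
                            r_int, rng)
    query = 8.0
    gmap = LinkageMap(("a", "b", "c"), pos)
    # insert the query locus by re-simulating with it on the map
    pos_q = np.array([0.0, 8.0, 20.0, 35.0])
    rq = haldane_d_to_r(np.diff(pos_q))
    alleles_q = np.zeros((1, 4, 2), dtype=np.int16)
    origins_q = np.stack([np.ones((1, 4), dtype=np.int8),
                          np.zeros((1, 4), dtype=np.int8)], axis=2)
    _, goq = _meiosis_batch(alleles_q, origins_q,
                            np.zeros(100_000, dtype=int), rq,
                            np.random.default_rng(99))
    marker_cols = [0, 2, 3]
    for pattern in itertools.product([1, 0], repeat=3):
        sel = np.all(goq[:, marker_cols] == pattern, axis=1)
        if sel.sum() < 500:
            continue
        emp = goq[sel, 1].mean()
        track = GameteOriginTrack(pos, tuple("W" if p else "E" for p in pattern))
        want = gamete_origin_probability(track, gmap, query, "W")
        se = np.sqrt(max(want * (1 - want), 1e-12) / sel.sum())
        assert abs(emp - want) < max(3 * se, 1e-3), pattern


# ---------------------------------------------------------------------------
# origin tracks from pedigree genotypes
# ---------------------------------------------------------------------------

def test_tracks_match_simulator_truth():
    design = CrossDesign(n_f2=300, n_phenotyped=300)
    fx = make_fixture("paper_like", seed=11, design=design)
    ids, O, line = origin_matrix_from_genotypes(fx.pedigree, fx.genotypes,
                                                fx.gmap)
    assert line == "W"
    tids, TO = fx.cross.origin_matrix(fx.gmap)
    truth = {i: TO[k] for k, i in enumerate(tids)}
    informative = 0
    for k, ind in enumerate(ids):
        m = ~np.isnan(O[k])
        informative += m.sum()
        assert np.array_equal(O[k][m], truth[ind][m])
    # line-divergent microsatellites make most markers family-informative
    assert informative / O.size > 0.5


def test_breed_fixed_marker_informative_everywhere(small_fixture):
    """A marker fixed for different alleles in the two founder lines is
    informative in every family."""
    fx = small_fixture
    geno = fx.cross.genotype_frame(["snp_a", "diag_snp"])
    gmap = LinkageMap(("snp_a", "diag_snp"), np.array([60.45, 80.0]))
    ids, O, _ = origin_matrix_from_genotypes(fx.pedigree, geno, gmap,
                                             line="W")
    j = list(gmap.markers).index("diag_snp")
    # every F1 is heterozygous with known phase, so every homozygous F2 is
    # fully resolved; only het children of two het parents remain ambiguous
    gt = geno.set_index("id")
    for k, ind in enumerate(ids):
        hom = gt.at[ind, "diag_snp_1"] == gt.at[ind, "diag_snp_2"]
        if hom:
            assert not np.isnan(O[k, :, j]).any()
        else:
            assert np.isnan(O[k, :, j]).all()


def test_monomorphic_marker_uninformative():
    import pandas as pd
    ped = pd.DataFrame({
        "id": ["s", "d", "f1s", "f1d", "c"],
        "sire": ["", "", "s", "s", "f1s"],
        "dam": ["", "", "d", "d", "f1d"],
        "generation": [0, 0, 1, 1, 2],
        "breed": ["W", "E", "", "", ""],
        "sex": ["M", "F", "M", "F", "M"],
    })
    geno = pd.DataFrame({
        "id": ["s", "d", "f1s", "f1d", "c"],
        "m1_1": ["1"] * 5, "m1_2": ["1"] * 5,        # monomorphic
        "m2_1": ["1", "2", "1", "1", "2"],           # line-diagnostic
        "m2_2": ["1", "2", "2", "2", "2"],
    })
    gmap = LinkageMap(("m1", "m2"), np.array([0.0, 10.0]))
    ids, O, _ = origin_matrix_from_genotypes(ped, geno, gmap, line="W")
    assert np.isnan(O[0, :, 0]).all()  # m1 uninformative for both gametes
    # m2: the child is 2/2, and allele 2 is the E-origin allele of both F1s
    assert O[0, 0, 1] == 0.0 and O[0, 1, 1] == 0.0


def test_mendelian_inconsistency_reported():
    import pandas as pd
    from crossqtl.linkage import MendelianError
    ped = pd.DataFrame({
        "id": ["s", "d", "f1", "f1b", "c"],
        "sire": ["", "", "s", "s", "f1"],
        "dam": ["", "", "d", "d", "f1b"],
        "generation": [0, 0, 1, 1, 2],
        "breed": ["W", "E", "", "", ""],
    })
    geno = pd.DataFrame({
        "id": ["s", "d", "f1", "f1b", "c"],
        "m1_1": ["1", "2", "1", "1", "3"],          # allele 3 from nowhere
        "m1_2": ["1", "2", "2", "2", "3"],
        "m2_1": ["1", "2", "1", "1", "1"],
        "m2_2": ["1", "2", "2", "2", "2"],
    })
    gmap = LinkageMap(("m1", "m2"), np.array([0.0, 10.0]))
    with pytest.raises(MendelianError, match="'c'.*'m1'"):
        origin_matrix_from_genotypes(ped, geno, gmap)


def test_tracks_object_layer(small_fixture):
    fx = small_fixture
    pairs = tracks_from_genotypes(fx.pedigree, fx.genotypes, fx.gmap)
    some_id = next(iter(pairs))
    pat, mat = pairs[some_id]
    assert set(pat.origins) <= {"W", "E"}
    assert np.all(np.isin(pat.positions, fx.gmap.positions))


# ---------------------------------------------------------------------------
# the grid
# ---------------------------------------------------------------------------

def test_grid_matches_per_individual_computation(small_fixture):
    """The vectorised grid equals the object-level per-individual state."""
    fx = small_fixture
    pairs = tracks_from_genotypes(fx.pedigree, fx.genotypes, fx.gmap)
    states = origin_grid(fx.pedigree, fx.genotypes, fx.gmap, step=10.0)
    rng = np.random.default_rng(0)
    ids = list(pairs)
    for ind in rng.choice(ids, 15, replace=False):
        pat, mat = pairs[ind]
        if len(pat) == 0 or len(mat) == 0:
            continue
        for j in (0, 3, 7):
            x = states.positions[j]
            want = line_origin_state_f2(mat, pat, fx.gmap, x, "W")
            i = states.ids.index(ind)
            assert states.p_ww[i, j] == pytest.approx(want.p_ww, abs=1e-9)
            assert states.p_we[i, j] == pytest.approx(want.p_we, abs=1e-9)


def test_grid_probability_closure(paper_states):
    s = paper_states
    assert np.allclose(s.p_ww + s.p_we + s.p_ee, 1.0, atol=1e-9)
    assert np.all((s.c_a >= -1) & (s.c_a <= 1))
    assert np.all((s.c_d >= 0) & (s.c_d <= 1))
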