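"""Inheritance-vector engine, S_pairs scoring, Kong & Cox combination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

import linkgeo as lg
from linkgeo.linkage import (FamilyEngine, InconsistentGenotypesError,
                             LinkageTrack, MeiosisCapError, kong_cox)
from linkgeo.pedio import Individual, Pedigree
from linkgeo.synthdata import (DiseaseModel, gene_drop, marker_panel,
                               simulate_pedigrees)
from conftest import uniform_freqs


# ---------------------------------------------------------------------------
# independent transmission-path oracle for single-marker posteriors
# ---------------------------------------------------------------------------

def oracle_singlepoint(ped, genotypes, freqs):
    """Brute force: enumerate founder ordered genotypes x inheritance
    vectors, descend alleles through the pedigree, score consistency.

    Independent of the engine's founder-allele-slot machinery (uses direct
    transmission), but indexed by the same meiosis order so distributions
    can be compared vector by vector.
    """
    eng = FamilyEngine(ped)          # only for the meiosis ordering
    order = ped.topological_order()
    founders = [pid for pid in order if ped.get(pid).is_founder]
    alleles = sorted(freqs)
    L = np.zeros(eng.nv)
    for fg in itertools.product(itertools.product(alleles, repeat=2),
                                repeat=len(founders)):
        w = 1.0
        for (a, b) in fg:
            w *= freqs[a] * freqs[b]
        assign = dict(zip(founders, fg))
        for v in range(eng.nv):
            geno = dict(assign)
            ok = True
            for bidx, (child, side) in enumerate(eng.meioses):
                bit = (v >> bidx) & 1
                parent = (ped.get(child).father_id if side == "pat"
                          else ped.get(child).mother_id)
                transmitted = geno[parent][bit]
                prev = geno.get(child, (None, None))
                geno[child] = ((transmitted, prev[1]) if side == "pat"
                               else (prev[0], transmitted))
            for pid, g in genotypes.items():
                if set(geno[pid]) != set(g) and sorted(geno[pid]) != sorted(g):
                    ok = False
                    break
            if ok:
                L[v] += w
    return L


@pytest.mark.parametrize("seed", range(8))
def test_singlepoint_matches_exhaustive_oracle(trio_pedigree, seed):
    """Engine posteriors equal brute-force enumeration over founder
    genotype completions (partial typing, <= 4 alleles)."""
    rng = np.random.default_rng(seed)
    freqs = {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    genotypes = {}
    for pid in trio_pedigree.member_ids():
        if rng.random() < 0.7:
            genotypes[pid] = tuple(sorted(rng.integers(1, 5, 2)))
    eng = FamilyEngine(trio_pedigree)
    L_eng = eng.likelihoods(genotypes, freqs)
    L_orc = oracle_singlepoint(trio_pedigree, genotypes, freqs)
    assert np.allclose(L_eng, L_orc, atol=1e-12)


def test_singlepoint_oracle_on_sibship(sib_pair_pedigree):
    rng = np.random.default_rng(3)
    freqs = {1: 0.35, 2: 0.35, 3: 0.3}
    for _ in range(5):
        genotypes = {pid: tuple(sorted(rng.integers(1, 4, 2)))
                     for pid in sib_pair_pedigree.member_ids()
                     if rng.random() < 0.8}
        L_eng = FamilyEngine(sib_pair_pedigree).likelihoods(genotypes, freqs)
        L_orc = oracle_singlepoint(sib_pair_pedigree, genotypes, freqs)
        assert np.allclose(L_eng, L_orc, atol=1e-12)


def test_fully_informative_sib_pair(sib_pair_engine):
    freqs = uniform_freqs(4)
    post = sib_pair_engine.posterior_single(
        {"f": (1, 2), "m": (3, 4), "c1": (1, 3), "c2": (1, 3)}, freqs)
    ibd = FamilyEngine._pair_ibd(sib_pair_engine.slots["c1"],
                                 sib_pair_engine.slots["c2"])
    assert post[ibd < 2].sum() == pytest.approx(0.0, abs=1e-12)


def test_untyped_marker_uniform(sib_pair_engine):
    post = sib_pair_engine.posterior_single({}, uniform_freqs(4))
    assert np.allclose(post, 1.0 / sib_pair_engine.nv)


def test_impossible_genotypes_raise(sib_pair_engine):
    with pytest.raises(InconsistentGenotypesError):
        sib_pair_engine.posterior_single(
            {"f": (1, 1), "m": (2, 2), "c1": (3, 3)}, uniform_freqs(4))


def test_meiosis_cap():
    members = [Individual("f", "B", None, None, "male", "unaffected"),
               Individual("m", "B", None, None, "female", "unaffected")] + [
        Individual(f"c{i}", "B", "f", "m", "male", "affected")
        for i in range(9)]
    with pytest.raises(MeiosisCapError, match="split"):
        FamilyEngine(Pedigree("B", members), meiosis_cap=16)


# ---------------------------------------------------------------------------
# S_pairs
# ---------------------------------------------------------------------------

def test_spairs_sib_pair_null_moments(sib_pair_engine):
    """Enumeration over the 16 sib-pair vectors: mean 1, variance 1/2."""
    counts = {}
    for v in range(16):
        counts[v] = sib_pair_engine.spairs(v)
    vals = np.array(list(counts.values()))
    assert vals.mean() == 1.0
    assert vals.var() == 0.5
    assert sib_pair_engine.mu0 == 1.0
    assert sib_pair_engine.sigma0 ** 2 == pytest.approx(0.5)


def test_spairs_extremes(sib_pair_engine):
    assert sib_pair_engine.spairs_v.max() == 2    # both transmissions shared
    assert sib_pair_engine.spairs_v.min() == 0


def test_spairs_inbred_pair_can_exceed_two():
    """Under a full-sib mating loop a pair can share more than 2 alleles."""
    members = [Individual("f", "I", None, None, "male", "unaffected"),
               Individual("m", "I", None, None, "female", "unaffected"),
               Individual("c1", "I", "f", "m", "male", "affected"),
               Individual("c2", "I", "f", "m", "female", "affected")]
    ped = Pedigree("I", members)
    lg.add_inbreeding_loop(ped, ("f", "m"), "full sib")
    eng = FamilyEngine(ped)
    assert eng.spairs_v.max() > 2


def test_fewer_than_two_affected_skipped(primary_study):
    cfg, peds, _, mmap, freqs = primary_study
    lone = Pedigree("LONE", [
        Individual("f", "LONE", None, None, "male", "unaffected"),
        Individual("m", "LONE", None, None, "female", "unaffected"),
        Individual("c", "LONE", "f", "m", "male", "affected")])
    gm, _ = gene_drop([peds[0], lone], mmap, freqs, cfg, seed=2)
    with pytest.warns(UserWarning, match="fewer than 2 affected"):
        track = lg.scan([peds[0], lone], gm, mmap, freqs,
                        mask_mendelian=False)
    assert list(track.weights.index) == [peds[0].family_id]


# ---------------------------------------------------------------------------
# multipoint HMM
# ---------------------------------------------------------------------------

def _emissions(eng, freqs, rng, n=3, p_typed=0.8):
    out = []
    for _ in range(n):
        g = {pid: tuple(sorted(rng.integers(1, len(freqs) + 1, 2)))
             for pid in eng.ped.member_ids() if rng.random() < p_typed}
        L = eng.likelihoods(g, freqs)
        out.append(L if L.sum() > 0 else np.ones(eng.nv))
    return out


def test_multipoint_single_marker_equals_singlepoint(sib_pair_engine, rng):
    freqs = uniform_freqs(4)
    (e,) = _emissions(sib_pair_engine, freqs, rng, n=1)
    post = sib_pair_engine.multipoint_posteriors([e], np.array([]))
    assert np.allclose(post[0], e / e.sum())


def test_multipoint_theta_half_decouples(sib_pair_engine, rng):
    freqs = uniform_freqs(4)
    ems = _emissions(sib_pair_engine, freqs, rng, n=3)
    posts = sib_pair_engine.multipoint_posteriors(ems, np.array([0.5, 0.5]))
    for p, e in zip(posts, ems):
        assert np.allclose(p, e / e.sum(), atol=1e-12)


def test_multipoint_theta_zero_copies_information(sib_pair_engine):
    freqs = uniform_freqs(4)
    informative = sib_pair_engine.likelihoods(
        {"f": (1, 2), "m": (3, 4), "c1": (1, 3), "c2": (1, 3)}, freqs)
    blank = np.ones(sib_pair_engine.nv)
    posts = sib_pair_engine.multipoint_posteriors(
        [informative, blank], np.array([0.0]))
    assert np.allclose(posts[1], posts[0], atol=1e-12)


def test_multipoint_posteriors_normalized(sib_pair_engine, rng):
    freqs = uniform_freqs(5)
    ems = _emissions(sib_pair_engine, freqs, rng, n=4)
    posts = sib_pair_engine.multipoint_posteriors(
        ems, np.array([0.05, 0.2, 0.45]))
    for p in posts:
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (p >= 0).all()


# ---------------------------------------------------------------------------
# Kong & Cox LOD
# ---------------------------------------------------------------------------

def test_kong_cox_zero_scores():
    z = np.zeros(5)
    assert kong_cox(z, -np.ones(5), np.ones(5)) == (0.0, 0.0)


def test_kong_cox_single_family_numeric_oracle():
    """1-D numeric maximization oracle + the quadratic upper bound."""
    z = np.sqrt(2)
    zmin, zmax = -np.sqrt(2), np.sqrt(2)
    dhat, slod = kong_cox(np.array([z]), np.array([zmin]), np.array([zmax]))
    grid = np.linspace(1e-9, -1.0 / zmin - 1e-9, 200001)
    oracle = np.log1p(grid * z).max() / np.log(10)
    assert slod == pytest.approx(oracle, abs=1e-6)
    assert slod <= z ** 2 / (2 * np.log(10)) + 1e-12


def test_kong_cox_negative_scores_sign():
    z = np.array([-1.0, -0.5, -1.2]) / np.sqrt(3)
    zmin = np.full(3, -2.0) / np.sqrt(3)
    zmax = np.full(3, 2.0) / np.sqrt(3)
    dhat, slod = kong_cox(z, zmin, zmax)
    assert dhat < 0 and slod < 0


def test_kong_cox_monotone_in_added_sharing():
    """Adding an excess-sharing family never lowers the maximized LOD."""
    base = np.array([0.5, -0.2, 0.8])
    zmin = np.full(4, -2.0)
    zmax = np.full(4, 2.0)
    _, l1 = kong_cox(base, zmin[:3], zmax[:3])
    _, l2 = kong_cox(np.append(base, 1.2), zmin, zmax)
    assert l2 >= l1 - 1e-12


@given(st.floats(min_value=1e-6, max_value=0.5))
@settings(deadline=None, max_examples=80)
def test_lod_p_round_trip(p):
    assert lg.lod_to_p(lg.p_to_lod(p)) == pytest.approx(p, abs=1e-12)


def test_lod_to_p_errors():
    with pytest.raises(ValueError):
        lg.lod_to_p(-0.1)
    with pytest.raises(ValueError):
        lg.p_to_lod(0.7)
    assert lg.lod_to_p(0.0) == 0.5


def test_family_weights_symmetry_and_normalization(sib_pair_pedigree):
    e1 = FamilyEngine(sib_pair_pedigree)
    members = [Individual(i.person_id, "FAM2", i.father_id, i.mother_id,
                          i.sex, i.affection)
               for i in sib_pair_pedigree.members()]
    e2 = FamilyEngine(Pedigree("FAM2", members))
    w = lg.family_weights({"FAM": e1, "FAM2": e2}, power=0.5)
    assert np.allclose(w.to_numpy(), 1 / np.sqrt(2))
    assert (w ** 2).sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def _track(lods, chrom="1"):
    tbl = pd.DataFrame({
        "chrom": chrom, "marker": [f"M{i}" for i in range(len(lods))],
        "cM": np.arange(len(lods)) * 10.0, "dhat": 0.0, "lod": lods,
        "p": 0.5, "ic": 0.8})
    z = pd.DataFrame(index=tbl["marker"])
    return LinkageTrack(tbl, z, pd.Series(dtype=float))


def test_call_regions_examples():
    r = lg.call_regions(_track([0.7, 0.6, 0.1]))
    assert len(r) == 1
    assert (r.iloc[0]["start_marker"], r.iloc[0]["end_marker"]) == ("M0", "M1")
    assert r.iloc[0]["peak_marker"] == "M0"           # leftmost maximum
    assert lg.call_regions(_track([-0.2, 3.0, -0.1])).empty
    assert lg.call_regions(_track([])).empty


def test_call_regions_leftmost_tie():
    r = lg.call_regions(_track([0.8, 0.8, 0.8]))
    assert r.iloc[0]["peak_marker"] == "M0"


# ---------------------------------------------------------------------------
# whole scans
# ---------------------------------------------------------------------------

def test_scan_track_invariants(primary_study):
    cfg, peds, _, mmap, freqs = primary_study
    gm, _ = gene_drop(peds, mmap, freqs, cfg, seed=21)
    track = lg.scan(peds, gm, mmap, freqs, mask_mendelian=False)
    t = track.table
    assert ((t["ic"] >= 0) & (t["ic"] <= 1)).all()
    assert ((t["p"] > 0) & (t["p"] <= 0.5)).all()
    assert (t.loc[t["lod"] >= 0, "dhat"] >= 0).all()
    assert ((w := track.weights) ** 2).sum() == pytest.approx(1.0)
    assert track.family_z.shape == (len(mmap), len(w))


def test_planted_locus_peaks_at_planted_marker(primary_study):
    """A strongly penetrant planted locus puts the genome-wide peak at the
    planted marker in >= 90% of replicates of the primary design."""
    cfg, peds, _, _, _ = primary_study
    cfg2 = lg.StudyConfig(
        pedigrees=cfg.pedigrees,
        disease=DiseaseModel(chrom="1", position_cM=20.0, risk_freq=0.05,
                             f0=0.01, f1=0.9, f2=0.9))
    mmap, freqs = marker_panel(cfg2, seed=2)
    hits = 0
    n = 20
    for s in range(n):
        gm, _ = gene_drop(peds, mmap, freqs, cfg2, seed=3000 + s)
        track = lg.scan(peds, gm, mmap, freqs, mask_mendelian=False)
        peak = track.table.loc[track.table["lod"].idxmax(), "marker"]
        hits += peak == "M003"
    assert hits / n >= 0.9


def test_posterior_concentrates_on_true_vector(primary_study):
    """With near-unique alleles and no missingness the posterior sharing
    equals the gene drop's true S_pairs."""
    cfg, peds, _, _, _ = primary_study
    cfg2 = lg.StudyConfig(pedigrees=cfg.pedigrees,
                          panel=lg.MarkerPanel(n_markers=1, min_alleles=14,
                                               max_alleles=14,
                                               target_het=0.92),
                          missing_rate=0.0)
    mmap, freqs = marker_panel(cfg2, seed=31)
    subset = peds[:20]
    gm, truth = gene_drop(subset, mmap, freqs, cfg2, seed=32)
    diffs = []
    for ped in subset:
        eng = lg.get_engine(ped)
        post = eng.posterior_single(
            gm.family_genotypes(ped, "M001"), freqs["M001"])
        s_obs = float(post @ eng.spairs_v)
        diffs.append(abs(s_obs - eng.spairs(truth[ped.family_id]["M001"])))
    assert np.mean(diffs) < 0.1
    assert np.mean(np.array(diffs) < 1e-9) >= 0.8
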