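"""Pedigree/genotype I/O, integrity checks, frequencies, HWE, loops."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import linkgeo as lg
from linkgeo.pedio import (GenotypeMatrix, Individual, MarkerMap, PedFormatError,
                           Pedigree, _hwe_chi2, haldane_theta)
from linkgeo.synthdata import gene_drop, marker_panel, simulate_pedigrees


# ---------------------------------------------------------------------------
# parsing and round trips
# ---------------------------------------------------------------------------

def _write_inputs(tmp_path, ped_text, map_text="1 MK1 0.0\n"):
    ped = tmp_path / "t.ped"
    mp = tmp_path / "t.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp


def test_parse_single_founder_row(tmp_path):
    ped, mp = _write_inputs(tmp_path, "F1 101 0 0 1 2 3 4\n")
    peds, gm, mmap = lg.parse_ped(ped, mp)
    assert len(peds) == 1 and len(peds[0]) == 1
    ind = peds[0].get("101")
    assert ind.is_founder and ind.sex == "male" and ind.affection == "affected"
    assert gm.get("F1", "101", "MK1") == (3, 4)


@pytest.mark.parametrize("row", [
    "F1 101 0 0 0 2 3 4",          # sex code 0
    "F1 101 0 0 3 2 3 4",          # invalid sex
    "F1 101 0 0 1 2 3",            # column count mismatch
    "F1 101 9 9 1 2 3 4",          # parent referenced but absent
    "F1 101 0 0 1 7 3 4",          # invalid affection
])
def test_parse_rejects_malformed_rows(tmp_path, row):
    ped, mp = _write_inputs(tmp_path, row + "\n")
    with pytest.raises(PedFormatError):
        lg.parse_ped(ped, mp)


def test_half_typed_genotype_set_missing(tmp_path):
    ped, mp = _write_inputs(tmp_path, "F1 101 0 0 1 2 3 0\n")
    _, gm, _ = lg.parse_ped(ped, mp)
    assert gm.get("F1", "101", "MK1") is None


def test_parse_write_parse_round_trip(tmp_path, primary_study):
    cfg, peds, _, mmap, freqs = primary_study
    gm, _ = gene_drop(peds, mmap, freqs, cfg, seed=5)
    lg.write_ped(tmp_path / "s.ped", peds, gm)
    lg.write_map(tmp_path / "s.map", mmap)
    peds2, gm2, mmap2 = lg.parse_ped(tmp_path / "s.ped", tmp_path / "s.map")
    assert lg.cohort_counts(peds2) == lg.cohort_counts(peds)
    assert np.array_equal(gm2.data, gm.data)
    assert list(mmap2.table["marker"]) == list(mmap.table["marker"])
    lg.write_ped(tmp_path / "s2.ped", peds2, gm2)
    assert (tmp_path / "s.ped").read_text() == (tmp_path / "s2.ped").read_text()


def test_primary_design_parsed_counts(tmp_path, primary_study):
    """The primary preset emits 58 pedigrees / 74 nuclear families /
    353 individuals through a full write+parse cycle."""
    cfg, peds, _, mmap, freqs = primary_study
    gm, _ = gene_drop(peds, mmap, freqs, cfg, seed=6)
    lg.write_ped(tmp_path / "s.ped", peds, gm)
    lg.write_map(tmp_path / "s.map", mmap)
    peds2, _, _ = lg.parse_ped(tmp_path / "s.ped", tmp_path / "s.map")
    counts = lg.cohort_counts(peds2)
    assert counts["pedigrees"] == 58
    assert counts["nuclear_families"] == 74
    assert counts["individuals"] == 353


def test_pedigree_validation_errors():
    with pytest.raises(PedFormatError):        # one parent only
        Pedigree("F", [Individual("a", "F", "x", None, "male", "unknown")])
    with pytest.raises(PedFormatError):        # father not male
        Pedigree("F", [
            Individual("p", "F", None, None, "female", "unknown"),
            Individual("q", "F", None, None, "female", "unknown"),
            Individual("c", "F", "p", "q", "male", "unknown")])
    with pytest.raises(PedFormatError):        # cycle
        Pedigree("F", [
            Individual("a", "F", "b", "c", "male", "unknown"),
            Individual("b", "F", "a", "c", "male", "unknown"),
            Individual("c", "F", None, None, "female", "unknown")])


def test_map_theta_haldane():
    m = MarkerMap(__import__("pandas").DataFrame(
        {"chrom": ["1", "1"], "marker": ["A", "B"], "cM": [0.0, 10.0]}))
    theta = m.thetas("1")[0]
    assert theta == pytest.approx((1 - np.exp(-0.2)) / 2)
    assert 0 <= theta <= 0.5


@given(st.floats(min_value=0.0, max_value=500.0))
@settings(deadline=None, max_examples=50)
def test_haldane_theta_range_and_monotone(d):
    th = float(haldane_theta(d))
    assert 0.0 <= th < 0.5 or (d == 0 and th == 0)


# ---------------------------------------------------------------------------
# Mendelian checks
# ---------------------------------------------------------------------------

def _one_marker_gm(ped, genos):
    gm = GenotypeMatrix([(ped.family_id, p) for p in ped.member_ids()],
                        ["MK1"])
    for pid, g in genos.items():
        gm.set(ped.family_id, pid, "MK1", g)
    return gm


def test_check_mendelian_trio_examples(sib_pair_pedigree):
    ped = sib_pair_pedigree
    bad = _one_marker_gm(ped, {"f": (1, 1), "m": (2, 2), "c1": (1, 1)})
    errs = lg.check_mendelian([ped], bad)
    assert len(errs) == 1 and errs[0].marker == "MK1"
    ok = _one_marker_gm(ped, {"f": (1, 2), "m": (1, 2), "c1": (1, 2)})
    assert lg.check_mendelian([ped], ok) == []


def test_check_mendelian_sibship_without_parents():
    """Joint nuclear-family checks catch inconsistencies no trio shows."""
    members = [Individual("f", "F", None, None, "male", "unknown"),
               Individual("m", "F", None, None, "female", "unknown")] + [
        Individual(f"c{i}", "F", "f", "m", "male", "affected")
        for i in range(3)]
    ped = Pedigree("F", members)
    gm = _one_marker_gm(ped, {"c0": (1, 2), "c1": (3, 4), "c2": (5, 6)})
    assert len(lg.check_mendelian([ped], gm)) == 1


def test_check_mendelian_clean_on_simulated_data(primary_study):
    """Gene-dropped genotypes are never flagged (many seeds)."""
    cfg, peds, _, mmap, freqs = primary_study
    subset = peds[:12]
    for seed in range(100):
        gm, _ = gene_drop(subset, mmap, freqs, cfg, seed=seed)
        assert lg.check_mendelian(subset, gm) == []


def test_planted_violations_recovered_exactly(primary_study):
    """50 planted impossible genotypes are all flagged, and nothing else."""
    cfg, peds, _, mmap, freqs = primary_study
    gm, _ = gene_drop(peds, mmap, freqs, cfg, seed=77)
    rng = np.random.default_rng(99)
    planted = set()
    simple = [p for p in peds if len(p.nuclear_families()) == 1]
    combos = [(p, m) for p in simple for m in mmap.markers]
    for idx in rng.choice(len(combos), size=50, replace=False):
        ped, marker = combos[idx]
        (fa, mo), kids = next(iter(ped.nuclear_families().items()))
        alleles = set(freqs[marker])
        for pid in (fa, mo):
            g = gm.get(ped.family_id, pid, marker)
            if g is None:
                g = tuple(sorted(alleles))[:2]
                gm.set(ped.family_id, pid, marker, g)
            alleles -= set(g)
        bad = tuple(sorted(alleles))[:2]
        gm.set(ped.family_id, kids[0], marker, bad)
        planted.add((ped.family_id, marker))
    errs = lg.check_mendelian(peds, gm)
    assert {(e.family_id, e.marker) for e in errs} == planted


def test_mask_errors_clears_flagged_genotypes(sib_pair_pedigree):
    ped = sib_pair_pedigree
    gm = _one_marker_gm(ped, {"f": (1, 1), "m": (2, 2), "c1": (3, 3)})
    errs = lg.check_mendelian([ped], gm, mask=True)
    assert errs and all(
        gm.get(ped.family_id, pid, "MK1") is None for pid in errs[0].members)
    assert lg.check_mendelian([ped], gm) == []


# ---------------------------------------------------------------------------
# founder frequencies
# ---------------------------------------------------------------------------

def test_founder_freqs_counting(sib_pair_pedigree):
    gm = _one_marker_gm(sib_pair_pedigree, {"f": (1, 1), "m": (1, 2)})
    fr = lg.founder_freqs([sib_pair_pedigree], gm)
    assert fr["MK1"] == {1: 0.75, 2: 0.25}


def test_founder_freqs_error_when_untyped(sib_pair_pedigree):
    gm = _one_marker_gm(sib_pair_pedigree, {"c1": (1, 2)})   # kids only
    with pytest.raises(ValueError, match="MK1"):
        lg.founder_freqs([sib_pair_pedigree], gm)


def test_founder_freqs_recover_simulator_inputs(primary_study):
    """Gene-dropped founder counts converge on the input frequencies."""
    cfg, peds, _, mmap, freqs = primary_study
    cfg_clean = lg.StudyConfig(pedigrees=cfg.pedigrees, panel=cfg.panel,
                               disease=cfg.disease, missing_rate=0.0)
    gm, _ = gene_drop(peds, mmap, freqs, cfg_clean, seed=8)
    est = lg.founder_freqs(peds, gm)
    n_chrom = 2 * len(lg.unrelated_individuals(peds))
    for m in mmap.markers:
        assert sum(est[m].values()) == pytest.approx(1.0, abs=1e-9)
        for a, p in freqs[m].items():
            se = max(np.sqrt(p * (1 - p) / n_chrom), 1e-3)
            assert abs(est[m].get(a, 0.0) - p) < 3 * se


def test_founder_freqs_label_permutation_invariance(primary_study):
    cfg, peds, _, mmap, freqs = primary_study
    gm, _ = gene_drop(peds, mmap, freqs, cfg, seed=9)
    fr = lg.founder_freqs(peds, gm)
    perm = {a: 100 - a for a in range(1, 20)}
    gm2 = gm.copy()
    nz = gm2.data != 0
    gm2.data[nz] = 100 - gm2.data[nz]
    fr2 = lg.founder_freqs(peds, gm2)
    for m in mmap.markers:
        assert {perm[a]: f for a, f in fr[m].items()} == fr2[m]


# ---------------------------------------------------------------------------
# HWE filter
# ---------------------------------------------------------------------------

def _founder_panel_gm(geno_rows, n_markers=1):
    """n unrelated unaffected founders in one pedigree + genotype rows."""
    n = len(geno_rows)
    members = [Individual(f"u{i}", "P", None, None, "male", "unaffected")
               for i in range(n)]
    ped = Pedigree("P", members)
    markers = [f"MK{j}" for j in range(n_markers)]
    gm = GenotypeMatrix([("P", f"u{i}") for i in range(n)], markers)
    for i, row in enumerate(geno_rows):
        for j, g in enumerate(np.atleast_2d(row)):
            gm.set("P", f"u{i}", markers[j], tuple(g))
    return ped, gm


def test_hwe_perfect_proportions_retained():
    rows = [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25
    ped, gm = _founder_panel_gm(rows)
    kept, pv = lg.hwe_filter(gm, [ped])
    assert kept == ["MK0"] and pv["MK0"] == pytest.approx(1.0)


def test_hwe_no_heterozygotes_excluded():
    rows = [(1, 1)] * 50 + [(2, 2)] * 50
    ped, gm = _founder_panel_gm(rows)
    stat, df, sparse = _hwe_chi2(np.array(rows))
    assert stat == pytest.approx(100.0) and df == 1 and not sparse
    kept, pv = lg.hwe_filter(gm, [ped])
    assert kept == [] and pv["MK0"] < 9.5e-5


def test_hwe_few_unrelateds_warns_and_retains():
    rows = [(1, 2)] * 5
    ped, gm = _founder_panel_gm(rows)
    with pytest.warns(UserWarning):
        kept, pv = lg.hwe_filter(gm, [ped])
    assert kept == ["MK0"] and np.isnan(pv["MK0"])


def test_hwe_null_calibration():
    """Under HWE the chi-square exclusion rate matches alpha (3 binomial SE)."""
    rng = np.random.default_rng(4)
    n_mark, n_ind = 1000, 250
    members = [Individual(f"u{i}", "P", None, None, "male", "unaffected")
               for i in range(n_ind)]
    ped = Pedigree("P", members)
    markers = [f"MK{j}" for j in range(n_mark)]
    data = rng.integers(1, 3, size=(n_ind, n_mark, 2))
    gm = GenotypeMatrix([("P", f"u{i}") for i in range(n_ind)], markers,
                        data)
    alpha = 0.05
    kept, pv = lg.hwe_filter(gm, [ped], alpha=alpha)
    rate = 1.0 - len(kept) / n_mark
    se = np.sqrt(alpha * (1 - alpha) / n_mark)
    assert abs(rate - alpha) < 3 * se
    # at the strict default threshold essentially nothing is excluded
    strict = sum(p < 9.5e-5 for p in pv.values())
    assert strict <= 2


# ---------------------------------------------------------------------------
# inbreeding loops
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("label,p0", [
    ("first cousin", 0.75),
    ("second cousin", 0.9375),
    ("half first cousin", 0.875),
    ("avuncular", 0.5),
    ("double first cousin", 0.5625),
    ("half sib plus first cousin", 0.375),
    ("full sib", 0.25),
])
def test_loop_installation_reproduces_expected_p0(label, p0):
    members = [Individual("f", "F", None, None, "male", "unaffected"),
               Individual("m", "F", None, None, "female", "unaffected"),
               Individual("c1", "F", "f", "m", "male", "affected"),
               Individual("c2", "F", "f", "m", "male", "affected")]
    ped = Pedigree("F", members)
    gm = _one_marker_gm(ped, {})
    n_before = gm.data.shape[0]
    lg.add_inbreeding_loop(ped, ("f", "m"), label, gm)
    got = lg.expected_ibd_probs(ped, ("f", "m"))
    assert got[0] == pytest.approx(p0, abs=1e-12)
    assert gm.data.shape[0] == n_before + (len(ped) - 4)
    assert all(gm.get("F", i.person_id, "MK1") is None
               for i in ped.members() if i.person_id.startswith("_L"))


def test_loop_unrelated_is_noop(sib_pair_pedigree):
    n = len(sib_pair_pedigree)
    lg.add_inbreeding_loop(sib_pair_pedigree, ("f", "m"), "unrelated")
    assert len(sib_pair_pedigree) == n and sib_pair_pedigree.loops == []


def test_loop_rejects_bad_input(sib_pair_pedigree):
    with pytest.raises(ValueError):
        lg.add_inbreeding_loop(sib_pair_pedigree, ("f", "m"), "step-uncle")
    with pytest.raises(ValueError):
        lg.add_inbreeding_loop(sib_pair_pedigree, ("c1", "m"), "full sib")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_affected_sex_ratio():
    members = ([Individual(f"m{i}", "P", None, None, "male", "affected")
                for i in range(238)]
               + [Individual(f"f{i}", "P", None, None, "female", "affected")
                  for i in range(156)])
    ped = Pedigree("P", members)
    assert round(lg.affected_sex_ratio([ped]), 1) == 1.5
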