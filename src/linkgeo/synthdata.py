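"""Synthetic multicase-pedigree studies: structures, genotypes, geography.

The generator emulates the design of a microsatellite genome scan of
geographically clustered multicase families: a fixed table of pedigree
structures (sibship-size classes per religious group, with some nuclear
families attached to a larger pedigree through a linking offspring), a
marker panel with 9-14 alleles per marker tuned to a target heterozygosity,
gene-dropped genotypes following the Haldane map with an optional planted
susceptibility locus and ascertainment on the designed affection pattern,
village-style geographic clusters inside a ~58 km x 31 km area, and
per-couple consanguinity loops.  All randomness flows through a single
integer seed.

The primary preset reproduces the study scale used throughout the tests:
58 pedigrees, 74 nuclear families, 353 individuals, 147 affected offspring
(31 Hindu / 27 Muslim pedigrees), with a ~10 cM marker spacing and 9%
missing genotypes.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geohet import latlon_to_utm, utm_to_latlon
from .linkage import LinkageTrack, get_engine, scan
from .pedio import (GenotypeMatrix, Individual, MarkerMap, Pedigree,
                    add_inbreeding_loop, haldane_theta, write_map,
                    write_metadata, write_ped)
from .relatedness import build_relationship_pedigree, gene_drop_alleles

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class NuclearSpec:
    """One nuclear family: affected/unaffected sibship sizes; when
    ``attach_to`` names an earlier nuclear family of the same pedigree, this
    family's father is a (male, unaffected) child of that family."""
    n_affected: int
    n_unaffected: int = 0
    attach_to: int | None = None


@dataclass
class PedigreeSpec:
    religion: str
    nuclears: list[NuclearSpec]
    affected_mother: bool = False


@dataclass
class MarkerPanel:
    n_markers: int = 6
    spacing_cM: float = 10.0
    min_alleles: int = 9
    max_alleles: int = 14
    target_het: float = 0.7
    chrom: str = "1"


@dataclass
class DiseaseModel:
    """Biallelic risk locus: allele 1 is the risk allele with frequency
    ``risk_freq``; penetrances f0/f1/f2 by risk-allele count.  With
    ``restrict_cluster`` set, only families of that geographic cluster
    segregate the locus (everyone else is drawn under the null)."""
    chrom: str = "1"
    position_cM: float = 20.0
    risk_freq: float = 0.05
    f0: float = 0.05
    f1: float = 0.05
    f2: float = 0.05
    restrict_cluster: int | None = None

    @property
    def is_null(self) -> bool:
        return self.f0 == self.f1 == self.f2

    def validate(self) -> None:
        for f in (self.f0, self.f1, self.f2):
            if not 0.0 <= f <= 1.0:
                raise ValueError("penetrances must lie in [0, 1]")
        if not (self.f2 >= self.f1 >= self.f0):
            raise ValueError("penetrances must satisfy f2 >= f1 >= f0")
        if not 0.0 <= self.risk_freq <= 1.0:
            raise ValueError("risk allele frequency must lie in [0, 1]")


@dataclass
class Geography:
    """Village-style clusters (km offsets inside the study frame).  The
    default centers span a 58 km (E-W) x 31 km (N-S) frame with a largest
    pairwise family distance of roughly 55 km."""
    clusters: list[tuple[float, float]] = field(default_factory=lambda: [
        (4.0, 8.0), (15.0, 25.0), (25.0, 6.0),
        (35.0, 22.0), (45.0, 10.0), (52.0, 26.0)])
    dispersion_km: float = 1.2
    origin_lat: float = 25.80
    origin_lon: float = 85.05
    zone: int = 45


@dataclass
class StudyConfig:
    pedigrees: list[PedigreeSpec]
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    disease: DiseaseModel = field(default_factory=DiseaseModel)
    geography: Geography = field(default_factory=Geography)
    consanguinity: dict = field(default_factory=dict)   # label -> rate
    missing_rate: float = 0.09
    ascertainment_cap: int = 100_000

    def validate(self) -> None:
        self.disease.validate()
        if self.panel.spacing_cM <= 0:
            raise ValueError("marker spacing must be positive")
        if self.panel.target_het > 1.0 - 1.0 / self.panel.min_alleles:
            raise ValueError("target heterozygosity unattainable")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must lie in [0, 1)")
        for spec in self.pedigrees:
            for k, nuc in enumerate(spec.nuclears):
                if nuc.n_affected + nuc.n_unaffected < 1:
                    raise ValueError("empty sibship")
                if nuc.attach_to is not None:
                    if not 0 <= nuc.attach_to < k:
                        raise ValueError(
                            "attach_to must name an earlier nuclear family")
                    host = spec.nuclears[nuc.attach_to]
                    if host.n_unaffected < 1:
                        raise ValueError(
                            "host nuclear family needs an unaffected child "
                            "to act as linking parent")


def primary_design() -> StudyConfig:
    """The primary study preset: 58 pedigrees / 74 nuclear families /
    353 individuals, 31 Hindu + 27 Muslim, sibship classes
    (1,2,3,4,5 affected sibs) = (16, 47, 8, 2, 1)."""
    H, M = "Hindu", "Muslim"
    peds: list[PedigreeSpec] = []
    # Hindu: 31 pedigrees, 39 nuclear families, 75 affected offspring
    for _ in range(2):
        peds.append(PedigreeSpec(H, [NuclearSpec(1, 1),
                                     NuclearSpec(1, 1, attach_to=0)]))
    for _ in range(6):
        peds.append(PedigreeSpec(H, [NuclearSpec(2, 1),
                                     NuclearSpec(1, 1, attach_to=0)]))
    for _ in range(18):
        peds.append(PedigreeSpec(H, [NuclearSpec(2, 1)]))
    for _ in range(2):
        peds.append(PedigreeSpec(H, [NuclearSpec(3, 1)]))
    peds.append(PedigreeSpec(H, [NuclearSpec(3, 0)]))
    for _ in range(2):
        peds.append(PedigreeSpec(H, [NuclearSpec(4, 0)]))
    # Muslim: 27 pedigrees, 35 nuclear families, 72 affected offspring
    for _ in range(2):
        peds.append(PedigreeSpec(M, [NuclearSpec(2, 1),
                                     NuclearSpec(2, 1, attach_to=0)]))
    for _ in range(6):
        peds.append(PedigreeSpec(M, [NuclearSpec(2, 1),
                                     NuclearSpec(1, 1, attach_to=0)]))
    for _ in range(3):
        peds.append(PedigreeSpec(M, [NuclearSpec(2, 2)]))
    for _ in range(10):
        peds.append(PedigreeSpec(M, [NuclearSpec(2, 1)]))
    for _ in range(5):
        peds.append(PedigreeSpec(M, [NuclearSpec(3, 1)]))
    peds.append(PedigreeSpec(M, [NuclearSpec(5, 1)]))
    # 12 Hindu + 13 Muslim affected (historical-case) parents
    n_h = n_m = 0
    for spec in peds:
        if spec.religion == H and n_h < 12:
            spec.affected_mother = True
            n_h += 1
        elif spec.religion == M and n_m < 13:
            spec.affected_mother = True
            n_m += 1
    return StudyConfig(pedigrees=peds)


def table2_rates() -> dict:
    """Consanguinity rates per relationship bin matching the observed
    parental-pair proportions (22 of 47 couples related)."""
    return {"second cousin": 11 / 47, "half first cousin": 7 / 47,
            "first cousin": 3 / 47, "avuncular": 1 / 47}


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------

def _build_pedigree(spec: PedigreeSpec, family_id: str) -> Pedigree:
    members: list[Individual] = []
    kid_ids: list[list[str]] = []
    linked_hosts = {nuc.attach_to for nuc in spec.nuclears
                    if nuc.attach_to is not None}
    parent_of: dict[int, tuple[str, str]] = {}
    for k, nuc in enumerate(spec.nuclears):
        if nuc.attach_to is None:
            father = f"n{k}f"
            mother = f"n{k}m"
            aff_mother = ("affected" if (k == 0 and spec.affected_mother)
                          else "unaffected")
            members.append(Individual(father, family_id, None, None,
                                      "male", "unaffected"))
            members.append(Individual(mother, family_id, None, None,
                                      "female", aff_mother))
        else:
            father = kid_ids[nuc.attach_to][-1]      # linking unaffected son
            mother = f"n{k}m"
            members.append(Individual(mother, family_id, None, None,
                                      "female", "unaffected"))
        parent_of[k] = (father, mother)
        kids = []
        n_kids = nuc.n_affected + nuc.n_unaffected
        for j in range(n_kids):
            pid = f"n{k}c{j}"
            affection = "affected" if j < nuc.n_affected else "unaffected"
            sex = "male" if j % 2 == 0 else "female"
            if k in linked_hosts and j == n_kids - 1:
                sex = "male"                          # will marry in below
            kids.append(Individual(pid, family_id, father, mother,
                                   sex, affection))
        members.extend(kids)
        kid_ids.append([kid.person_id for kid in kids])
    return Pedigree(family_id, members)


def simulate_pedigrees(config: StudyConfig, seed: int = 0):
    """Instantiate the configured pedigree designs.

    Returns ``(pedigrees, meta)`` where ``meta`` carries family_id and
    religion.  Class counts match the design table exactly; consanguinity
    loops are installed on founder couples at the configured per-bin rates.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    peds: list[Pedigree] = []
    rows = []
    for i, spec in enumerate(config.pedigrees, start=1):
        fid = f"F{i:03d}"
        ped = _build_pedigree(spec, fid)
        if config.consanguinity:
            labels = list(config.consanguinity)
            probs = np.array([config.consanguinity[l] for l in labels])
            if probs.sum() > 1:
                raise ValueError("consanguinity rates exceed 1")
            for couple, kids in list(ped.nuclear_families().items()):
                fa, mo = couple
                if not (ped.get(fa).is_founder and ped.get(mo).is_founder):
                    continue
                u = rng.random()
                acc = 0.0
                for label, pr in zip(labels, probs):
                    acc += pr
                    if u < acc:
                        add_inbreeding_loop(ped, couple, label)
                        break
        peds.append(ped)
        rows.append((fid, spec.religion))
    meta = pd.DataFrame(rows, columns=["family_id", "religion"])
    return peds, meta


# ---------------------------------------------------------------------------
# Marker panel and allele frequencies
# ---------------------------------------------------------------------------

def _blend_to_het(p: np.ndarray, target: float) -> np.ndarray:
    """Blend a frequency vector toward uniform (or a point mass) so the
    heterozygosity 1 - sum p^2 hits the target exactly."""
    k = len(p)
    want = 1.0 - target

    def solve(a, b):
        # sum((a + t b)^2) = want for t in [0, 1]
        A = float((b * b).sum())
        B = 2.0 * float((a * b).sum())
        C = float((a * a).sum()) - want
        if A < 1e-15:
            return None
        disc = B * B - 4 * A * C
        if disc < 0:
            return None
        for t in sorted([(-B - math.sqrt(disc)) / (2 * A),
                         (-B + math.sqrt(disc)) / (2 * A)]):
            if -1e-12 <= t <= 1 + 1e-12:
                return min(max(t, 0.0), 1.0)
        return None

    u = np.full(k, 1.0 / k)
    t = solve(u, p - u)             # uniform -> draw
    if t is not None:
        return u + t * (p - u)
    spike = np.zeros(k)
    spike[int(np.argmax(p))] = 1.0
    t = solve(p, spike - p)         # draw -> point mass
    if t is None:
        raise ValueError("target heterozygosity unattainable")
    return p + t * (spike - p)


def marker_panel(config: StudyConfig, seed: int = 0):
    """Build the marker map and per-marker allele frequencies.

    Allele counts cycle over [min_alleles, max_alleles]; frequencies are a
    Dirichlet draw adjusted to hit the target heterozygosity exactly.
    Returns ``(marker_map, freqs)``.
    """
    rng = np.random.default_rng(seed)
    panel = config.panel
    rows = []
    freqs = {}
    counts = list(range(panel.min_alleles, panel.max_alleles + 1))
    for i in range(panel.n_markers):
        name = f"M{i + 1:03d}"
        rows.append((panel.chrom, name, i * panel.spacing_cM))
        k = counts[i % len(counts)]
        p = _blend_to_het(rng.dirichlet(np.ones(k)), panel.target_het)
        freqs[name] = {a + 1: float(p[a]) for a in range(k)}
    mmap = MarkerMap(pd.DataFrame(rows, columns=["chrom", "marker", "cM"]))
    return mmap, freqs


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

def _cum(freq: dict):
    alleles = np.array(list(freq), dtype=np.int64)
    cum = np.cumsum(np.array(list(freq.values()), dtype=float))
    cum[-1] = 1.0
    return alleles, cum


def _draw_alleles(cum, n: int, rng) -> np.ndarray:
    alleles, c = cum
    idx = np.minimum(np.searchsorted(c, rng.random(n), side="right"),
                     len(alleles) - 1)
    return alleles[idx]


def _chain_bits(L: int, thetas: np.ndarray, rng, anchor=None) -> np.ndarray:
    """Inheritance indicators along one chromosome: a two-state Markov
    chain with per-interval flip probability theta.  With ``anchor``
    (index, bit) the chain is extended outward from the fixed position,
    which is exact because the chain is reversible."""
    b = np.empty(L, dtype=np.int64)
    if anchor is None:
        b[0] = rng.integers(0, 2)
        if L > 1:
            flips = rng.random(L - 1) < thetas
            b[1:] = (b[0] + np.cumsum(flips)) % 2
        return b
    d, bit = anchor
    b[d] = bit
    if d + 1 < L:
        flips = rng.random(L - 1 - d) < thetas[d:]
        b[d + 1:] = (b[d] + np.cumsum(flips)) % 2
    if d > 0:
        flips = rng.random(d) < thetas[:d][::-1]
        b[d - 1::-1] = (b[d] + np.cumsum(flips)) % 2
    return b


def _drop_chrom(ped: Pedigree, L: int, thetas: np.ndarray, pos_cums: list,
                rng, anchor=None):
    """One meiotic realization of a family along one chromosome.

    ``anchor``, when given, is ``(d_idx, founder_alleles, bits1)`` fixing
    the founder alleles and meiosis bits at one position (the ascertained
    disease locus).  Returns per-person haplotype pairs over the positions
    and the per-meiosis indicator arrays (0 = grandpaternal).
    """
    haps: dict[str, list[np.ndarray]] = {}
    bits: dict[tuple[str, str], np.ndarray] = {}
    d_idx = anchor[0] if anchor else None
    for pid in ped.topological_order():
        ind = ped.get(pid)
        if ind.is_founder:
            h = np.empty((2, L), dtype=np.int64)
            for i in range(L):
                h[:, i] = _draw_alleles(pos_cums[i], 2, rng)
            if anchor is not None:
                h[:, d_idx] = anchor[1][pid]
            haps[pid] = [h[0], h[1]]
        else:
            out = []
            for side, parent in (("pat", ind.father_id),
                                 ("mat", ind.mother_id)):
                ba = (None if anchor is None
                      else (d_idx, anchor[2][(pid, side)]))
                b = _chain_bits(L, thetas, rng, anchor=ba)
                out.append(np.where(b == 0, haps[parent][0],
                                    haps[parent][1]))
                bits[(pid, side)] = b
            haps[pid] = out
    return haps, bits


def _ascertain_at_locus(ped: Pedigree, dis: DiseaseModel, designed: dict,
                        cap: int, rng):
    """Rejection-sample the disease-locus state until the realized
    affection pattern matches the designed one.

    Returns ``(founder_alleles, bits)`` at the locus (risk allele coded 1,
    the rest 2)."""
    topo = ped.topological_order()
    pens = (dis.f0, dis.f1, dis.f2)
    for _ in range(cap):
        fa: dict[str, np.ndarray] = {}
        bits1: dict[tuple[str, str], int] = {}
        geno: dict[str, tuple] = {}
        ok = True
        for pid in topo:
            ind = ped.get(pid)
            if ind.is_founder:
                g = np.where(rng.random(2) < dis.risk_freq, 1, 2)
                fa[pid] = g
                geno[pid] = (int(g[0]), int(g[1]))
            else:
                bp = int(rng.integers(0, 2))
                bm = int(rng.integers(0, 2))
                bits1[(pid, "pat")] = bp
                bits1[(pid, "mat")] = bm
                geno[pid] = (geno[ind.father_id][bp],
                             geno[ind.mother_id][bm])
        for pid in topo:
            want = designed[pid]
            if want == "unknown":
                continue
            n_risk = (geno[pid][0] == 1) + (geno[pid][1] == 1)
            realized = ("affected" if rng.random() < pens[n_risk]
                        else "unaffected")
            if realized != want:
                ok = False
                break
        if ok:
            return fa, bits1
    raise RuntimeError(
        f"family {ped.family_id}: ascertainment pattern not met within "
        f"{cap} draws; use a stronger disease model")


def gene_drop(pedigrees: list[Pedigree], mmap: MarkerMap, freqs: dict,
              config: StudyConfig, seed: int = 0,
              linked_families: set[str] | None = None):
    """Gene-drop genotypes for every family, ascertained on the designed
    affection pattern.

    Founder alleles are drawn from the marker frequencies; meioses follow
    the Haldane map with independent per-interval crossovers; affection is
    assigned from the risk-locus genotype through the penetrances and the
    family is resampled until the realized pattern matches the designed
    one (trivially satisfied under the null).  Missing genotypes are
    applied at the configured rate afterwards.

    Returns ``(genotypes, truth)`` where ``truth`` maps family ->
    marker -> inheritance-vector index in the family engine's meiosis
    order (autosomal engines).
    """
    rng = np.random.default_rng(seed)
    dis = config.disease
    keys = [(p.family_id, i.person_id) for p in pedigrees
            for i in p.members()]
    gm = GenotypeMatrix(keys, mmap.markers)
    truth: dict[str, dict[str, int]] = {}

    chrom_layout = []
    for chrom in mmap.chromosomes():
        sub = mmap.chrom_markers(chrom)
        names = list(sub["marker"])
        pos = sub["cM"].to_numpy(dtype=float)
        pos_cums = [_cum(freqs[m]) for m in names]
        d_idx = None
        if (dis is not None and not dis.is_null
                and str(dis.chrom) == str(chrom)):
            d_idx = int(np.searchsorted(pos, dis.position_cM))
            pos = np.insert(pos, d_idx, dis.position_cM)
            names = names[:d_idx] + [None] + names[d_idx:]
            pos_cums = (pos_cums[:d_idx]
                        + [_cum({1: dis.risk_freq, 2: 1.0 - dis.risk_freq})]
                        + pos_cums[d_idx:])
        chrom_layout.append((chrom, names, len(pos),
                             haldane_theta(np.diff(pos)), pos_cums, d_idx))

    for ped in pedigrees:
        fam_linked = (linked_families is None
                      or ped.family_id in linked_families)
        condition = (dis is not None and not dis.is_null and fam_linked)
        designed = {i.person_id: i.affection for i in ped.members()}
        eng = get_engine(ped)
        fam_truth: dict[str, int] = {}
        for chrom, names, L, thetas, pos_cums, d_idx in chrom_layout:
            anchor = None
            if condition and d_idx is not None:
                fa, bits1 = _ascertain_at_locus(
                    ped, dis, designed, config.ascertainment_cap, rng)
                anchor = (d_idx, fa, bits1)
            haps, bits = _drop_chrom(ped, L, thetas, pos_cums, rng,
                                     anchor=anchor)
            for i, name in enumerate(names):
                if name is None:
                    continue
                for pid in ped.member_ids():
                    gm.set(ped.family_id, pid, name,
                           (haps[pid][0][i], haps[pid][1][i]))
                v = 0
                for bidx, (child, side) in enumerate(eng.meioses):
                    v |= int(bits[(child, side)][i]) << bidx
                fam_truth[name] = v
        truth[ped.family_id] = fam_truth

    if config.missing_rate > 0:
        mask = rng.random(gm.data.shape[:2]) < config.missing_rate
        gm.data[mask] = 0
    return gm, truth


def true_spairs(ped: Pedigree, truth: dict, marker: str) -> int:
    """S_pairs score implied by the recorded true inheritance vector."""
    return get_engine(ped).spairs(truth[ped.family_id][marker])


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def assign_geography(pedigrees: list[Pedigree], config: StudyConfig,
                     seed: int = 0,
                     religions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Scatter families around the configured cluster centers.

    Returns a metadata frame with family_id, religion, cluster, lat, lon
    and the UTM easting/northing (meters) the lat/lon round-trips to.
    """
    rng = np.random.default_rng(seed)
    geo = config.geography
    e0, n0 = latlon_to_utm(geo.origin_lat, geo.origin_lon, geo.zone)
    rel = {}
    if religions is not None:
        rel = dict(zip(religions["family_id"], religions["religion"]))
    rows = []
    for ped in pedigrees:
        c = int(rng.integers(0, len(geo.clusters)))
        cx, cy = geo.clusters[c]
        e = e0 + cx * 1000.0 + rng.normal(0.0, geo.dispersion_km * 1000.0)
        n = n0 + cy * 1000.0 + rng.normal(0.0, geo.dispersion_km * 1000.0)
        lat, lon = utm_to_latlon(e, n, geo.zone)
        rows.append((ped.family_id, rel.get(ped.family_id, "NA"), c,
                     round(lat, 6), round(lon, 6)))
    meta = pd.DataFrame(rows, columns=["family_id", "religion", "cluster",
                                       "lat", "lon"])
    utm = [latlon_to_utm(r.lat, r.lon, geo.zone) for r in meta.itertuples()]
    meta["easting"] = [e for e, _ in utm]
    meta["northing"] = [n for _, n in utm]
    return meta


# ---------------------------------------------------------------------------
# Whole studies and the power simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: StudyConfig
    pedigrees: list[Pedigree]
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    freqs: dict
    meta: pd.DataFrame
    truth: dict


def simulate_study(config: StudyConfig, seed: int = 0) -> SimulatedStudy:
    """Generate one complete study (pedigrees, genotypes, geography)."""
    ss = np.random.SeedSequence(seed)
    s_ped, s_panel, s_geo, s_drop = ss.spawn(4)
    peds, religions = simulate_pedigrees(config, _seed_of(s_ped))
    mmap, freqs = marker_panel(config, _seed_of(s_panel))
    meta = assign_geography(peds, config, _seed_of(s_geo),
                            religions=religions)
    linked = None
    if (config.disease is not None
            and config.disease.restrict_cluster is not None):
        linked = set(meta.loc[meta["cluster"]
                              == config.disease.restrict_cluster,
                              "family_id"])
    gm, truth = gene_drop(peds, mmap, freqs, config, _seed_of(s_drop),
                          linked_families=linked)
    return SimulatedStudy(config, peds, gm, mmap, freqs, meta, truth)


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0])


def write_study(study: SimulatedStudy, outdir) -> None:
    """Emit the PED / map / metadata / frequency files pedio consumes."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_ped(out / "study.ped", study.pedigrees, study.genotypes)
    write_map(out / "study.map", study.marker_map)
    write_metadata(out / "families.csv",
                   study.meta[["family_id", "lat", "lon", "religion"]])
    rows = [(m, a, f) for m, fa in study.freqs.items()
            for a, f in fa.items()]
    pd.DataFrame(rows, columns=["marker", "allele", "freq"]).to_csv(
        out / "freqs.tsv", sep="\t", index=False)


def power_simulation(config: StudyConfig, n_reps: int = 100,
                     lod_threshold: float = 3.0, seed: int = 0,
                     region_cM: float = 15.0, power: float = 0.5) -> dict:
    """Fraction of replicates whose peak signed LOD near the planted locus
    reaches the threshold, with its binomial standard error."""
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    ss = np.random.SeedSequence(seed)
    s_ped, s_panel, *s_reps = ss.spawn(2 + n_reps)
    peds, _ = simulate_pedigrees(config, _seed_of(s_ped))
    mmap, freqs = marker_panel(config, _seed_of(s_panel))
    dis = config.disease
    in_region = mmap.table["marker"][
        (mmap.table["chrom"] == str(dis.chrom))
        & ((mmap.table["cM"] - dis.position_cM).abs() <= region_cM)]
    hits = 0
    for rep in range(n_reps):
        gm, _ = gene_drop(peds, mmap, freqs, config, _seed_of(s_reps[rep]))
        track = scan(peds, gm, mmap, freqs, power=power,
                     mask_mendelian=False)
        peak = track.table.loc[
            track.table["marker"].isin(in_region), "lod"].max()
        if peak >= lod_threshold:
            hits += 1
    p = hits / n_reps
    return {"power": p, "se": math.sqrt(p * (1 - p) / n_reps),
            "n_reps": n_reps, "threshold": lod_threshold}


# ---------------------------------------------------------------------------
# Relative-pair simulation (for relatedness calibration)
# ---------------------------------------------------------------------------

def simulate_relative_pair(label: str, freqs: dict, seed_or_rng=0):
    """Genotypes of one relative pair over unlinked markers.

    The canonical pedigree for ``label`` is gene-dropped once per marker;
    founder alleles are drawn from each marker's frequencies.  Returns
    ``(g1, g2)`` as marker -> allele-pair dicts.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    ped, (a, b) = build_relationship_pedigree(label)
    sub = ped.ancestor_closure({a, b})
    markers = list(freqs)
    labels = gene_drop_alleles(sub, len(markers), rng)
    n_slots = 2 * len(sub.founders())
    g1, g2 = {}, {}
    for k, m in enumerate(markers):
        alleles = np.array(list(freqs[m]))
        pr = np.array(list(freqs[m].values()))
        draw = alleles[rng.choice(len(alleles), size=n_slots, p=pr)]
        g1[m] = (int(draw[labels[a][k, 0]]), int(draw[labels[a][k, 1]]))
        g2[m] = (int(draw[labels[b][k, 0]]), int(draw[labels[b][k, 1]]))
    return g1, g2


# ---------------------------------------------------------------------------
# YAML round trip for configs
# ---------------------------------------------------------------------------

def config_to_yaml(config: StudyConfig) -> str:
    return yaml.safe_dump(asdict(config), sort_keys=False)


def config_from_yaml(text: str) -> StudyConfig:
    raw = yaml.safe_load(text)
    peds = [PedigreeSpec(religion=p["religion"],
                         nuclears=[NuclearSpec(**n) for n in p["nuclears"]],
                         affected_mother=p.get("affected_mother", False))
            for p in raw["pedigrees"]]
    geo = raw.get("geography", {})
    if "clusters" in geo:
        geo["clusters"] = [tuple(c) for c in geo["clusters"]]
    cfg = StudyConfig(
        pedigrees=peds,
        panel=MarkerPanel(**raw.get("panel", {})),
        disease=DiseaseModel(**raw.get("disease", {})),
        geography=Geography(**geo),
        consanguinity=raw.get("consanguinity", {}),
        missing_rate=raw.get("missing_rate", 0.09),
        ascertainment_cap=raw.get("ascertainment_cap", 100_000))
    cfg.validate()
    return cfg
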