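"""Pedigree, genotype and map I/O with genetic-integrity checks.

This module handles the LINKAGE pre-MAKEPED dialect used by microsatellite
genome scans: whitespace-delimited rows of six leading columns (family id,
person id, father id, mother id, sex, affection) followed by two allele
columns per marker, with ``0`` meaning a missing allele or absent parent.
On top of parsing it provides the data-quality steps that precede any
allele-sharing analysis: Mendelian-inconsistency detection per nuclear
family, founder-based allele-frequency estimation, a Hardy-Weinberg
equilibrium marker filter, and installation of inbreeding loops that encode
consanguineous parental relationships as untyped ancestor scaffolds.

Conventions (LINKAGE dialect): sex 1=male, 2=female; affection 2=affected,
1=unaffected, 0=unknown.  A genotype with exactly one typed allele is set
fully missing.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = 0

_SEX_CODE = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2"}
_AFF_CODE = {"2": "affected", "1": "unaffected", "0": "unknown"}
_AFF_OUT = {"affected": "2", "unaffected": "1", "unknown": "0"}


class PedFormatError(ValueError):
    """Raised for malformed pedigree/genotype input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders (including
    marry-in parents); the pedigree validator enforces that either both
    parents are present or both absent.
    """

    person_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str                    # 'male' | 'female'
    affection: str              # 'affected' | 'unaffected' | 'unknown'

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """A single family: directed graph of individuals plus loop bookkeeping."""

    def __init__(self, family_id: str, individuals: list[Individual]):
        self.family_id = family_id
        self._members: dict[str, Individual] = {}
        self.loops: list[tuple[tuple[str, str], str]] = []
        for ind in individuals:
            if ind.person_id in self._members:
                raise PedFormatError(
                    f"duplicate person id {ind.person_id!r} in family {family_id}")
            self._members[ind.person_id] = ind
        self.validate()

    # -- accessors ----------------------------------------------------------
    def members(self) -> list[Individual]:
        return list(self._members.values())

    def member_ids(self) -> list[str]:
        return list(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, pid: str) -> bool:
        return pid in self._members

    def get(self, pid: str) -> Individual:
        return self._members[pid]

    def founders(self) -> list[Individual]:
        return [i for i in self._members.values() if i.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [i for i in self._members.values() if not i.is_founder]

    def affected_ids(self) -> list[str]:
        return [i.person_id for i in self._members.values()
                if i.affection == "affected"]

    def nuclear_families(self) -> dict[tuple[str, str], list[str]]:
        """Parent-pair groupings: (father_id, mother_id) -> child ids."""
        out: dict[tuple[str, str], list[str]] = {}
        for ind in self._members.values():
            if not ind.is_founder:
                out.setdefault((ind.father_id, ind.mother_id), []).append(
                    ind.person_id)
        return out

    def topological_order(self) -> list[str]:
        """Member ids with every parent before its children."""
        placed: set[str] = set()
        order: list[str] = []
        pending = list(self._members.values())
        while pending:
            rest = []
            for ind in pending:
                if ind.is_founder or (
                        ind.father_id in placed and ind.mother_id in placed):
                    order.append(ind.person_id)
                    placed.add(ind.person_id)
                else:
                    rest.append(ind)
            if len(rest) == len(pending):   # cycle; validate() should prevent
                raise PedFormatError(
                    f"cyclic parentage in family {self.family_id}")
            pending = rest
        return order

    def ancestor_closure(self, ids: set[str]) -> "Pedigree":
        """Sub-pedigree of the given members and all their ancestors."""
        keep: set[str] = set()
        stack = list(ids)
        while stack:
            pid = stack.pop()
            if pid in keep:
                continue
            keep.add(pid)
            ind = self._members[pid]
            if not ind.is_founder:
                stack.extend([ind.father_id, ind.mother_id])
        return Pedigree(self.family_id,
                        [i for i in self._members.values()
                         if i.person_id in keep])

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for ind in self._members.values():
            if (ind.father_id is None) != (ind.mother_id is None):
                raise PedFormatError(
                    f"{self.family_id}/{ind.person_id}: exactly one parent given")
            if ind.is_founder:
                continue
            for pid, want in ((ind.father_id, "male"), (ind.mother_id, "female")):
                if pid not in self._members:
                    raise PedFormatError(
                        f"{self.family_id}/{ind.person_id}: parent {pid!r} "
                        "referenced but absent")
                if self._members[pid].sex != want:
                    raise PedFormatError(
                        f"{self.family_id}/{ind.person_id}: parent {pid!r} "
                        f"is not {want}")
        self.topological_order()    # raises on cycles

    # -- mutation (used by loop installation and simulators) ---------------
    def add_individual(self, ind: Individual) -> None:
        if ind.person_id in self._members:
            raise PedFormatError(f"duplicate person id {ind.person_id!r}")
        self._members[ind.person_id] = ind

    def set_parents(self, pid: str, father_id: str, mother_id: str) -> None:
        self._members[pid] = replace(
            self._members[pid], father_id=father_id, mother_id=mother_id)


class MarkerMap:
    """Genetic map: marker name, chromosome and Haldane cM position.

    Inter-marker recombination fractions follow the Haldane map function
    theta = (1 - exp(-2 d / 100)) / 2 for a distance of d centimorgans.
    """

    def __init__(self, table: pd.DataFrame):
        need = {"chrom", "marker", "cM"}
        if not need.issubset(table.columns):
            raise PedFormatError(f"marker map needs columns {sorted(need)}")
        table = table.reset_index(drop=True).copy()
        table["chrom"] = table["chrom"].astype(str)
        table["cM"] = table["cM"].astype(float)
        for chrom, grp in table.groupby("chrom", sort=False):
            if (np.diff(grp["cM"].to_numpy()) < 0).any():
                raise PedFormatError(
                    f"map positions decrease on chromosome {chrom}")
        if table["marker"].duplicated().any():
            raise PedFormatError("duplicate marker names in map")
        self.table = table

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    def __len__(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_markers(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == str(chrom)]

    def position(self, marker: str) -> float:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(marker)
        return float(row["cM"].iloc[0])

    def thetas(self, chrom: str) -> np.ndarray:
        """Recombination fractions between consecutive markers of a chromosome."""
        d = np.diff(self.chrom_markers(chrom)["cM"].to_numpy())
        return haldane_theta(d)

    def subset(self, markers: list[str]) -> "MarkerMap":
        keep = self.table[self.table["marker"].isin(markers)]
        return MarkerMap(keep)


def haldane_theta(d_cM) -> np.ndarray:
    """Map distance (cM) -> recombination fraction, Haldane."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0)) / 2.0


def haldane_distance(theta) -> np.ndarray:
    """Inverse Haldane: recombination fraction -> distance in cM."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(theta, dtype=float))


class GenotypeMatrix:
    """Two-allele-per-marker calls for every individual.

    Backed by an ``(n_individuals, n_markers, 2)`` integer array with 0 for
    missing; allele pairs are unordered.  Individuals are keyed by
    ``(family_id, person_id)``.
    """

    def __init__(self, individuals: list[tuple[str, str]], markers: list[str],
                 data: np.ndarray | None = None):
        self.individuals = list(individuals)
        self.markers = list(markers)
        self._row = {key: i for i, key in enumerate(self.individuals)}
        self._col = {m: j for j, m in enumerate(self.markers)}
        if data is None:
            data = np.zeros((len(self.individuals), len(self.markers), 2),
                            dtype=np.int32)
        self.data = np.asarray(data, dtype=np.int32)
        if self.data.shape != (len(self.individuals), len(self.markers), 2):
            raise PedFormatError("genotype array shape mismatch")

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.individuals, self.markers, self.data.copy())

    def get(self, family_id: str, person_id: str, marker: str):
        a, b = self.data[self._row[(family_id, person_id)], self._col[marker]]
        if a == MISSING or b == MISSING:
            return None
        return (int(a), int(b))

    def set(self, family_id: str, person_id: str, marker: str, pair) -> None:
        row, col = self._row[(family_id, person_id)], self._col[marker]
        if pair is None:
            self.data[row, col] = (MISSING, MISSING)
        else:
            self.data[row, col] = (int(pair[0]), int(pair[1]))

    def family_genotypes(self, ped: Pedigree, marker: str) -> dict[str, tuple]:
        """Typed genotypes of one family at one marker: person_id -> (a, b)."""
        col = self._col[marker]
        out = {}
        for pid in ped.member_ids():
            key = (ped.family_id, pid)
            if key not in self._row:
                continue
            a, b = self.data[self._row[key], col]
            if a != MISSING and b != MISSING:
                out[pid] = (int(a), int(b))
        return out

    def observed_alleles(self, marker: str) -> list[int]:
        col = self.data[:, self._col[marker], :]
        return sorted(int(a) for a in np.unique(col) if a != MISSING)

    def missing_rate(self) -> float:
        return float((self.data[:, :, 0] == MISSING).mean())

    def add_individuals(self, keys: list[tuple[str, str]]) -> None:
        """Append untyped rows (all genotypes missing)."""
        pad = np.zeros((len(keys), len(self.markers), 2), dtype=np.int32)
        self.data = np.concatenate([self.data, pad], axis=0)
        for key in keys:
            self._row[key] = len(self.individuals)
            self.individuals.append(key)

    def drop_markers(self, markers: set[str]) -> "GenotypeMatrix":
        keep = [m for m in self.markers if m not in markers]
        cols = [self._col[m] for m in keep]
        return GenotypeMatrix(self.individuals, keep, self.data[:, cols, :])


AlleleFrequencies = dict  # marker -> {allele label: frequency}


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

def parse_map(map_file) -> MarkerMap:
    """Read a 3-column TSV map: chromosome, marker name, Haldane cM."""
    tbl = pd.read_csv(map_file, sep=r"\s+", header=None,
                      names=["chrom", "marker", "cM"], comment="#")
    return MarkerMap(tbl)


def parse_ped(ped_file, map_file):
    """Parse LINKAGE pre-MAKEPED pedigree + genotype rows against a map.

    Returns ``(pedigrees, genotypes, marker_map)``.  Raises
    :class:`PedFormatError` on malformed rows, absent parents, invalid sex
    codes, or a column count that disagrees with the map.
    """
    mmap = parse_map(map_file)
    n_mark = len(mmap)
    fam_members: dict[str, list[Individual]] = {}
    keys: list[tuple[str, str]] = []
    rows: list[list[int]] = []
    half_typed = 0

    with open(ped_file) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) != 6 + 2 * n_mark:
                raise PedFormatError(
                    f"line {lineno}: expected {6 + 2 * n_mark} columns for "
                    f"{n_mark} markers, got {len(tokens)}")
            fam, pid, fa, mo, sex, aff = tokens[:6]
            if sex not in _SEX_CODE:
                raise PedFormatError(f"line {lineno}: invalid sex code {sex!r}")
            if aff not in _AFF_CODE:
                raise PedFormatError(
                    f"line {lineno}: invalid affection code {aff!r}")
            ind = Individual(
                person_id=pid, family_id=fam,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex=_SEX_CODE[sex], affection=_AFF_CODE[aff])
            fam_members.setdefault(fam, []).append(ind)
            alleles = []
            for j in range(n_mark):
                try:
                    a = int(tokens[6 + 2 * j])
                    b = int(tokens[7 + 2 * j])
                except ValueError as exc:
                    raise PedFormatError(
                        f"line {lineno}: non-integer allele") from exc
                if a < 0 or b < 0:
                    raise PedFormatError(f"line {lineno}: negative allele")
                if (a == MISSING) != (b == MISSING):
                    half_typed += 1
                    a = b = MISSING
                alleles.extend([a, b])
            keys.append((fam, pid))
            rows.append(alleles)

    peds = [Pedigree(fam, members) for fam, members in fam_members.items()]
    data = np.asarray(rows, dtype=np.int32).reshape(len(keys), n_mark, 2)
    gm = GenotypeMatrix(keys, mmap.markers, data)
    if half_typed:
        logger.warning("%d half-typed genotypes set to missing", half_typed)
    logger.info("parsed %d pedigrees, %d individuals, %d markers "
                "(missing rate %.1f%%)", len(peds), len(keys), n_mark,
                100 * gm.missing_rate())
    return peds, gm, mmap


def write_ped(path, pedigrees: list[Pedigree], gm: GenotypeMatrix) -> None:
    """Write pedigrees + genotypes in the pre-MAKEPED layout parse_ped reads."""
    with open(path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.members():
                key = (ped.family_id, ind.person_id)
                cols = [ped.family_id, ind.person_id,
                        ind.father_id or "0", ind.mother_id or "0",
                        _SEX_OUT[ind.sex], _AFF_OUT[ind.affection]]
                row = gm.data[gm._row[key]].reshape(-1)
                cols.extend(str(int(x)) for x in row)
                fh.write(" ".join(cols) + "\n")


def write_map(path, mmap: MarkerMap) -> None:
    mmap.table[["chrom", "marker", "cM"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_metadata(path) -> pd.DataFrame:
    """Family metadata CSV: family_id, lat, lon, religion."""
    meta = pd.read_csv(path)
    need = {"family_id", "lat", "lon", "religion"}
    if not need.issubset(meta.columns):
        raise PedFormatError(f"metadata needs columns {sorted(need)}")
    meta["family_id"] = meta["family_id"].astype(str)
    return meta


def write_metadata(path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Mendelian integrity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MendelianInconsistency:
    family_id: str
    marker: str
    members: tuple[str, ...]


def _nuclear_consistent(father_g, mother_g, child_gs: list[tuple]) -> bool:
    """Existence check: can some parental genotype pair explain all children?

    Untyped parents range over unordered pairs drawn from the alleles seen in
    this nuclear family plus one wildcard label standing for any unobserved
    allele (a wildcard never matches an observed child allele, which is the
    correct feasibility relaxation).
    """
    observed = set()
    for g in [father_g, mother_g, *child_gs]:
        if g is not None:
            observed.update(g)
    dummy = (max(observed) + 1) if observed else 1
    universe = sorted(observed) + [dummy]

    def candidates(g):
        if g is not None:
            return [g]
        return [(a, b) for i, a in enumerate(universe)
                for b in universe[i:]]

    for gf in candidates(father_g):
        for gmo in candidates(mother_g):
            ok = True
            for (a, b) in child_gs:
                if not ((a in gf and b in gmo) or (b in gf and a in gmo)):
                    ok = False
                    break
            if ok:
                return True
    return False


def check_mendelian(pedigrees: list[Pedigree], gm: GenotypeMatrix,
                    mask: bool = False) -> list[MendelianInconsistency]:
    """Flag (family, marker, member-set) combinations impossible under
    Mendelian transmission.

    Each nuclear family is checked jointly (typed parents constrain typed
    children and vice versa); inconsistencies that only emerge across nuclear
    families through an untyped connector are not detected.  With
    ``mask=True`` every flagged member's genotype at the marker is set
    missing in ``gm``.
    """
    errors: list[MendelianInconsistency] = []
    for ped in pedigrees:
        nucs = ped.nuclear_families()
        for marker in gm.markers:
            genos = gm.family_genotypes(ped, marker)
            if not genos:
                continue
            for (fa, mo), kids in nucs.items():
                child_gs = [genos[k] for k in kids if k in genos]
                if not child_gs:
                    continue
                if not _nuclear_consistent(genos.get(fa), genos.get(mo),
                                           child_gs):
                    members = tuple(p for p in (fa, mo, *kids) if p in genos)
                    errors.append(MendelianInconsistency(
                        ped.family_id, marker, members))
    if mask:
        for err in errors:
            for pid in err.members:
                gm.set(err.family_id, pid, err.marker, None)
        if errors:
            logger.info("masked %d inconsistent family-marker sets",
                        len(errors))
    return errors


# ---------------------------------------------------------------------------
# Founder allele frequencies and HWE filter
# ---------------------------------------------------------------------------

def unrelated_individuals(pedigrees: list[Pedigree]) -> list[tuple[str, str]]:
    """Founders and marry-in parents: everyone without parents on record.

    Within a pedigree these individuals are mutually unrelated, which is what
    both frequency estimation and the HWE test require.
    """
    return [(p.family_id, i.person_id)
            for p in pedigrees for i in p.founders()]


def founder_freqs(pedigrees: list[Pedigree],
                  gm: GenotypeMatrix) -> AlleleFrequencies:
    """Counting estimator of allele frequencies over unrelated individuals."""
    unrel = set(unrelated_individuals(pedigrees))
    rows = [gm._row[key] for key in gm.individuals if key in unrel]
    freqs: AlleleFrequencies = {}
    for marker in gm.markers:
        col = gm.data[rows, gm._col[marker], :].reshape(-1)
        col = col[col != MISSING]
        if col.size == 0:
            raise ValueError(
                f"no typed unrelated individuals at marker {marker!r}")
        counts = Counter(int(a) for a in col)
        total = sum(counts.values())
        freqs[marker] = {a: c / total for a, c in sorted(counts.items())}
    return freqs


def _hwe_chi2(pairs: np.ndarray):
    """Genotype-count chi-square against HWE expectations.

    Returns (statistic, df, expected-count array, sparse flag).  Allele
    frequencies are estimated from the same genotypes; df = k(k-1)/2.
    """
    alleles = sorted(set(pairs.reshape(-1).tolist()))
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}
    n = len(pairs)
    counts = np.zeros((k, k))
    for a, b in pairs:
        i, j = sorted((idx[a], idx[b]))
        counts[i, j] += 1
    p = np.bincount([idx[a] for a in pairs.reshape(-1)],
                    minlength=k) / (2 * n)
    stat = 0.0
    expected = []
    for i in range(k):
        for j in range(i, k):
            e = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            o = counts[i, j]
            if e > 0:
                stat += (o - e) ** 2 / e
                expected.append(e)
    df = k * (k - 1) // 2
    sparse = bool(np.min(expected) < 5) if expected else True
    return stat, df, sparse


def hwe_filter(gm: GenotypeMatrix, pedigrees: list[Pedigree],
               alpha: float = 9.5e-5, n_mc: int = 10_000, seed: int = 0,
               min_unrelated: int = 10):
    """Hardy-Weinberg marker filter on unrelated unaffected individuals.

    Markers with P < ``alpha`` are excluded.  P comes from the chi-square
    goodness of fit on genotype counts, replaced by a Monte Carlo exact test
    (allele permutation, ``n_mc`` draws, add-one estimator) whenever any
    expected genotype count falls below 5.  Markers with fewer than
    ``min_unrelated`` typed unrelated unaffecteds are retained with a
    warning.

    Returns ``(retained_markers, pvalues)``.
    """
    affection = {(p.family_id, i.person_id): i.affection
                 for p in pedigrees for i in p.members()}
    unrel = [key for key in unrelated_individuals(pedigrees)
             if affection[key] == "unaffected"]
    rows = [gm._row[key] for key in gm.individuals if key in set(unrel)]
    rng = np.random.default_rng(seed)
    pvals: dict[str, float] = {}
    retained: list[str] = []
    for marker in gm.markers:
        col = gm.data[rows, gm._col[marker], :]
        typed = col[(col[:, 0] != MISSING) & (col[:, 1] != MISSING)]
        if len(typed) < min_unrelated:
            warnings.warn(
                f"{marker}: only {len(typed)} unrelated unaffecteds typed; "
                "HWE not tested, marker retained", stacklevel=2)
            pvals[marker] = np.nan
            retained.append(marker)
            continue
        if len(np.unique(typed)) < 2:       # monomorphic
            pvals[marker] = 1.0
            retained.append(marker)
            continue
        stat, df, sparse = _hwe_chi2(typed)
        if not sparse:
            p = float(stats.chi2.sf(stat, df))
        else:
            pool = typed.reshape(-1).copy()
            hits = 0
            for _ in range(n_mc):
                rng.shuffle(pool)
                s, _, _ = _hwe_chi2(pool.reshape(-1, 2))
                if s >= stat - 1e-12:
                    hits += 1
            p = (1 + hits) / (1 + n_mc)
        pvals[marker] = p
        if p >= alpha:
            retained.append(marker)
    return retained, pvals


# ---------------------------------------------------------------------------
# Inbreeding loops
# ---------------------------------------------------------------------------

def _mk(ped: Pedigree, pid: str, sex: str,
        father: str | None = None, mother: str | None = None) -> str:
    ped.add_individual(Individual(
        person_id=pid, family_id=ped.family_id, father_id=father,
        mother_id=mother, sex=sex, affection="unknown"))
    return pid


def _install_loop(ped: Pedigree, a: str, b: str, label: str,
                  prefix: str) -> list[str]:
    """Insert the minimal untyped ancestor scaffold giving the (a, b) couple
    the named relationship.  Returns the inserted person ids."""
    P = prefix
    new: list[str] = []

    def mk(pid, sex, father=None, mother=None):
        new.append(_mk(ped, pid, sex, father, mother))
        return pid

    if label == "full sib":
        f0 = mk(P + "f0", "male"); m0 = mk(P + "m0", "female")
        ped.set_parents(a, f0, m0); ped.set_parents(b, f0, m0)
    elif label == "half sib":
        f0 = mk(P + "f0", "male")
        m1 = mk(P + "m1", "female"); m2 = mk(P + "m2", "female")
        ped.set_parents(a, f0, m1); ped.set_parents(b, f0, m2)
    elif label == "avuncular":
        # a is maternal uncle of b
        g1 = mk(P + "g1", "male"); g2 = mk(P + "g2", "female")
        link = mk(P + "l1", "female", g1, g2)
        sp = mk(P + "s1", "male")
        ped.set_parents(a, g1, g2); ped.set_parents(b, sp, link)
    elif label == "half avuncular":
        # a is paternal half-uncle of b
        g = mk(P + "g1", "male")
        w1 = mk(P + "w1", "female"); w2 = mk(P + "w2", "female")
        link = mk(P + "l1", "female", g, w2)
        sp = mk(P + "s1", "male")
        ped.set_parents(a, g, w1); ped.set_parents(b, sp, link)
    elif label == "first cousin":
        g1 = mk(P + "g1", "male"); g2 = mk(P + "g2", "female")
        l1 = mk(P + "l1", "male", g1, g2); l2 = mk(P + "l2", "female", g1, g2)
        s1 = mk(P + "s1", "female"); s2 = mk(P + "s2", "male")
        ped.set_parents(a, l1, s1); ped.set_parents(b, s2, l2)
    elif label == "half first cousin":
        g = mk(P + "g1", "male")
        w1 = mk(P + "w1", "female"); w2 = mk(P + "w2", "female")
        l1 = mk(P + "l1", "male", g, w1); l2 = mk(P + "l2", "female", g, w2)
        s1 = mk(P + "s1", "female"); s2 = mk(P + "s2", "male")
        ped.set_parents(a, l1, s1); ped.set_parents(b, s2, l2)
    elif label == "second cousin":
        gg1 = mk(P + "gg1", "male"); gg2 = mk(P + "gg2", "female")
        c1 = mk(P + "c1", "male", gg1, gg2)
        c2 = mk(P + "c2", "female", gg1, gg2)
        d1 = mk(P + "d1", "female"); d2 = mk(P + "d2", "male")
        l1 = mk(P + "l1", "male", c1, d1); l2 = mk(P + "l2", "female", d2, c2)
        s1 = mk(P + "s1", "female"); s2 = mk(P + "s2", "male")
        ped.set_parents(a, l1, s1); ped.set_parents(b, s2, l2)
    elif label == "double first cousin":
        g1 = mk(P + "g1", "male"); g2 = mk(P + "g2", "female")
        g3 = mk(P + "g3", "male"); g4 = mk(P + "g4", "female")
        l1 = mk(P + "l1", "male", g1, g2)
        l3 = mk(P + "l3", "male", g1, g2)
        l2 = mk(P + "l2", "female", g3, g4)
        l4 = mk(P + "l4", "female", g3, g4)
        ped.set_parents(a, l1, l2); ped.set_parents(b, l3, l4)
    elif label == "half sib plus first cousin":
        f0 = mk(P + "f0", "male")
        gm1 = mk(P + "gm1", "male"); gm2 = mk(P + "gm2", "female")
        m1 = mk(P + "m1", "female", gm1, gm2)
        m2 = mk(P + "m2", "female", gm1, gm2)
        ped.set_parents(a, f0, m1); ped.set_parents(b, f0, m2)
    else:
        raise ValueError(f"unknown relationship label {label!r}")
    return new


LOOP_LABELS = [
    "unrelated", "second cousin", "half first cousin", "first cousin",
    "avuncular", "double first cousin", "half sib",
    "half sib plus first cousin", "full sib",
]


def add_inbreeding_loop(ped: Pedigree, parent_pair: tuple[str, str],
                        label: str, gm: GenotypeMatrix | None = None) -> Pedigree:
    """Encode a consanguineous parental relationship as an ancestor loop.

    ``parent_pair`` must be a (father, mother) couple of the pedigree, both
    currently founders.  All inserted ancestors are untyped with unknown
    affection; when ``gm`` is given it is padded with missing rows.  The
    label "unrelated" is a no-op.
    """
    label = label.strip().lower()
    if label == "unrelated":
        return ped
    a, b = parent_pair
    for pid, sex in ((a, "male"), (b, "female")):
        if pid not in ped:
            raise ValueError(f"{pid!r} not in family {ped.family_id}")
        if ped.get(pid).sex != sex:
            raise ValueError(f"{pid!r} is not the {sex} of the couple")
        if not ped.get(pid).is_founder:
            raise ValueError(f"{pid!r} already has parents; cannot install loop")
    if (a, b) not in ped.nuclear_families():
        raise ValueError(f"({a}, {b}) is not a parent couple in "
                         f"family {ped.family_id}")
    prefix = f"_L{len(ped.loops) + 1}_"
    new = _install_loop(ped, a, b, label, prefix)
    ped.loops.append(((a, b), label))
    ped.validate()
    if gm is not None:
        gm.add_individuals([(ped.family_id, pid) for pid in new])
    return ped


# ---------------------------------------------------------------------------
# Small cohort summaries
# ---------------------------------------------------------------------------

def affected_sex_ratio(pedigrees: list[Pedigree]) -> float:
    """Male:female ratio among affected individuals."""
    males = sum(1 for p in pedigrees for i in p.members()
                if i.affection == "affected" and i.sex == "male")
    females = sum(1 for p in pedigrees for i in p.members()
                  if i.affection == "affected" and i.sex == "female")
    if females == 0:
        raise ValueError("no affected females")
    return males / females


def cohort_counts(pedigrees: list[Pedigree]) -> dict:
    """Pedigree / nuclear family / individual totals for a family set."""
    return {
        "pedigrees": len(pedigrees),
        "nuclear_families": sum(len(p.nuclear_families()) for p in pedigrees),
        "individuals": sum(len(p) for p in pedigrees),
        "affected": sum(len(p.affected_ids()) for p in pedigrees),
    }
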