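"""Multipoint nonparametric allele-sharing linkage analysis.

The engine follows the Lander-Green view of a pedigree: at any map position
the segregation state of a family is an *inheritance vector* v with one bit
per scored meiosis (paternal and maternal bit per non-founder on autosomes;
only meioses with a choice are scored on X, where males are hemizygous).
Marker data define a likelihood P(genotypes | v) obtained by summing founder
allele assignments over the founder-allele graph that v induces, and a
hidden Markov chain with per-meiosis flip probability theta (Haldane) links
adjacent markers; the forward-backward pass is carried out in the Walsh-
Hadamard domain where the transition kernel is diagonal.

Sharing is scored with the Whittemore-Halpern S_pairs statistic: the sum
over all affected relative pairs of the number of alleles shared identical
by descent under v (multiset intersection of founder-allele labels, so
inbred pairs can exceed 2).  Each family's expected score under the
posterior is standardized by the exact enumeration null moments, weighted
for unequal pedigree sizes, and combined across families with the Kong &
Cox one-parameter linear likelihood

    l(delta) = sum_f log(1 + delta * w_f * Z_f),

whose maximized log10 ratio is the allele-sharing LOD, reported signed as
sign(delta_hat) * LOD.  Nominal one-sided P-values use
P = 1 - Phi(sqrt(2 ln 10 * LOD)); information content is the entropy
complement of the posterior averaged over families by meiosis count.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedio import (MISSING, GenotypeMatrix, MarkerMap, Pedigree,
                    check_mendelian)

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)
DEFAULT_MEIOSIS_CAP = 16


class MeiosisCapError(RuntimeError):
    """Family exceeds the inheritance-vector budget."""


class InconsistentGenotypesError(RuntimeError):
    """All inheritance vectors have zero likelihood at a marker."""


# ---------------------------------------------------------------------------
# Family engine: inheritance vectors, founder-allele slots, S_pairs
# ---------------------------------------------------------------------------

def _fwht(a: np.ndarray) -> np.ndarray:
    """Unnormalized fast Walsh-Hadamard transform (involution up to n)."""
    a = np.array(a, dtype=float)
    h = 1
    n = a.size
    while h < n:
        a = a.reshape(-1, 2, h)
        s = a[:, 0, :] + a[:, 1, :]
        d = a[:, 0, :] - a[:, 1, :]
        a = np.stack([s, d], axis=1)
        h *= 2
    return a.reshape(-1)


class FamilyEngine:
    """Exact inheritance-vector machinery for one pedigree.

    Precomputes, per inheritance vector: the founder-allele slot carried by
    every gamete of every member, the S_pairs score over affected pairs, and
    the exact null moments of S_pairs under the uniform prior.  Instances
    depend only on pedigree structure (and chromosome type) and are reused
    across markers and simulation replicates.
    """

    def __init__(self, ped: Pedigree, x_linked: bool = False,
                 meiosis_cap: int = DEFAULT_MEIOSIS_CAP):
        self.ped = ped
        self.x_linked = x_linked
        order = ped.topological_order()
        self.meioses: list[tuple[str, str]] = []   # (child id, 'pat'|'mat')
        n_slots = 0
        plan: dict[str, list] = {}
        for pid in order:
            ind = ped.get(pid)
            gametes = []
            if x_linked and ind.sex == "male":
                sides = ["mat"]
            else:
                sides = ["pat", "mat"]
            for side in sides:
                if ind.is_founder:
                    gametes.append(("slot", n_slots))
                    n_slots += 1
                else:
                    parent = ind.father_id if side == "pat" else ind.mother_id
                    if len(plan[parent]) == 1:
                        gametes.append(("copy", parent, 0))
                    else:
                        gametes.append(("bit", parent, len(self.meioses)))
                        self.meioses.append((pid, side))
            plan[pid] = gametes

        self.n_bits = len(self.meioses)
        if self.n_bits > meiosis_cap:
            raise MeiosisCapError(
                f"family {ped.family_id}: {self.n_bits} meioses exceed the "
                f"cap of {meiosis_cap}; split the pedigree into smaller units")
        self.nv = 1 << self.n_bits
        self.n_slots = n_slots

        v = np.arange(self.nv)
        self.slots: dict[str, list[np.ndarray]] = {}
        for pid in order:
            arrs = []
            for g in plan[pid]:
                if g[0] == "slot":
                    arrs.append(np.full(self.nv, g[1], dtype=np.int16))
                elif g[0] == "copy":
                    arrs.append(self.slots[g[1]][g[2]])
                else:
                    _, parent, bit = g
                    take = ((v >> bit) & 1).astype(bool)
                    p0, p1 = self.slots[parent]
                    arrs.append(np.where(take, p1, p0).astype(np.int16))
            self.slots[pid] = arrs

        # founder slot constants, descendant sets and per-member slot-pair
        # combos, used by the vectorized likelihood path
        self.founder_slots: dict[str, tuple[int, ...]] = {}
        for pid in order:
            if ped.get(pid).is_founder:
                self.founder_slots[pid] = tuple(
                    int(a[0]) for a in self.slots[pid])
        ancestors: dict[str, set[str]] = {}
        for pid in order:
            ind = ped.get(pid)
            if ind.is_founder:
                ancestors[pid] = {pid}
            else:
                ancestors[pid] = (ancestors[ind.father_id]
                                  | ancestors[ind.mother_id] | {pid})
        self.descendants: dict[str, list[str]] = {f: [] for f in
                                                  self.founder_slots}
        for pid in order:
            for anc in ancestors[pid]:
                if anc in self.founder_slots and anc != pid:
                    self.descendants[anc].append(pid)
        self._combos: dict[str, tuple[list, np.ndarray]] = {}
        for pid in order:
            arrs = self.slots[pid]
            if len(arrs) == 2:
                key = arrs[0].astype(np.int64) * (n_slots + 1) + arrs[1]
            else:
                key = arrs[0].astype(np.int64)
            uniq, inv = np.unique(key, return_inverse=True)
            if len(arrs) == 2:
                combos = [(int(k) // (n_slots + 1), int(k) % (n_slots + 1))
                          for k in uniq]
            else:
                combos = [(int(k),) for k in uniq]
            self._combos[pid] = (combos, inv)

        self.affected = [pid for pid in order
                         if ped.get(pid).affection == "affected"]
        self.pairs = [(self.affected[i], self.affected[j])
                      for i in range(len(self.affected))
                      for j in range(i + 1, len(self.affected))]
        self.n_pairs = len(self.pairs)
        sp = np.zeros(self.nv, dtype=np.int32)
        for a, b in self.pairs:
            sp += self._pair_ibd(self.slots[a], self.slots[b])
        self.spairs_v = sp
        self.mu0 = float(sp.mean())
        self.sigma0 = float(sp.std())
        if self.sigma0 > 0:
            self.z_min = (sp.min() - self.mu0) / self.sigma0
            self.z_max = (sp.max() - self.mu0) / self.sigma0
        else:
            self.z_min = self.z_max = 0.0
        self._bitcount = np.bitwise_count(v.astype(np.uint64)).astype(float)

    @staticmethod
    def _pair_ibd(la: list[np.ndarray], lb: list[np.ndarray]) -> np.ndarray:
        """Pairwise allele sharing IBD: the Whittemore-Halpern cross-count
        over all (allele of a, allele of b) comparisons.

        Equals the usual 0/1/2 IBD count for outbred pairs and can exceed 2
        when inbreeding makes an individual carry the same founder allele
        twice; hemizygotes carry one slot (male-male pairs max out at 1).
        """
        out = np.zeros(la[0].shape, dtype=np.int32)
        for sa in la:
            for sb in lb:
                out += sa == sb
        return out

    # -- single-marker likelihood ------------------------------------------
    def spairs(self, v_index: int) -> int:
        """S_pairs score of one inheritance vector."""
        return int(self.spairs_v[v_index])

    _DUMMY = -1           # pooled label for alleles seen in no descendant
    _ASSIGN_BUDGET = 4e7  # assignments x vectors before recursion fallback

    def likelihoods(self, genotypes: dict[str, tuple], freqs: dict) -> np.ndarray:
        """P(observed genotypes | v) for every inheritance vector.

        ``genotypes`` maps typed person ids to unordered allele pairs
        (hemizygous X males must be coded homozygous).  The likelihood sums
        ordered founder-allele assignments: each founder ranges over its own
        phased genotype if typed, otherwise over the alleles observed in its
        typed descendants plus one pooled label carrying the remaining
        frequency mass (an exact marginalization).  Consistency of every
        typed non-founder is evaluated vectorized over inheritance vectors.
        """
        typed_d = {pid: tuple(g) for pid, g in genotypes.items()
                   if pid in self.slots}
        if not typed_d:
            return np.ones(self.nv)
        cand = []
        n_assign = 1
        for fpid, fslots in self.founder_slots.items():
            hemi = len(fslots) == 1
            if fpid in typed_d:
                a, b = typed_d[fpid]
                fa, fb = freqs.get(a, 0.0), freqs.get(b, 0.0)
                if hemi:
                    if a != b:
                        raise InconsistentGenotypesError(
                            f"{fpid}: heterozygous call for a hemizygote")
                    lst = [((a,), fa)]
                elif a == b:
                    lst = [((a, a), fa * fa)]
                else:
                    lst = [((a, b), fa * fb), ((b, a), fa * fb)]
            else:
                seen = sorted({al for d in self.descendants[fpid]
                               if d in typed_d for al in typed_d[d]})
                opts = [(al, freqs.get(al, 0.0)) for al in seen]
                rest = max(0.0, 1.0 - sum(w for _, w in opts))
                opts.append((self._DUMMY, rest))
                opts = [(al, w) for al, w in opts if w > 0.0]
                if hemi:
                    lst = [((al,), w) for al, w in opts]
                else:
                    lst = [((x, y), wx * wy) for x, wx in opts
                           for y, wy in opts]
            if not lst:
                return np.zeros(self.nv)
            cand.append((fslots, lst))
            n_assign *= len(lst)
        if n_assign * self.nv > self._ASSIGN_BUDGET:
            return self._likelihoods_recursive(typed_d, freqs)

        check = [(pid, g) for pid, g in typed_d.items()
                 if pid not in self.founder_slots]
        L = np.zeros(self.nv)
        alleles = np.full(self.n_slots, self._DUMMY, dtype=np.int64)
        for combo in itertools.product(*[lst for _, lst in cand]):
            w = 1.0
            for (fslots, _), (als, wgt) in zip(cand, combo):
                w *= wgt
                for s, al in zip(fslots, als):
                    alleles[s] = al
            if w <= 0.0:
                continue
            mask = None
            dead = False
            for pid, (a, b) in check:
                combos, inv = self._combos[pid]
                if len(combos[0]) == 2:
                    tab = np.fromiter(
                        (((alleles[s1] == a and alleles[s2] == b)
                          or (alleles[s1] == b and alleles[s2] == a))
                         for s1, s2 in combos), dtype=bool,
                        count=len(combos))
                else:
                    tab = np.fromiter(
                        (a == b and alleles[s] == a for (s,) in combos),
                        dtype=bool, count=len(combos))
                if not tab.any():
                    dead = True
                    break
                m = tab[inv]
                mask = m if mask is None else (mask & m)
                if not mask.any():
                    dead = True
                    break
            if dead:
                continue
            if mask is None:
                L += w
            else:
                L[mask] += w
        return L

    def _likelihoods_recursive(self, genotypes: dict[str, tuple],
                               freqs: dict) -> np.ndarray:
        """Signature-grouped recursive fallback for very unconstrained
        founder sets."""
        typed = [(pid, g) for pid, g in genotypes.items() if pid in self.slots]
        if not typed:
            return np.ones(self.nv)
        cols = []
        spec = []       # (n slots, alleles) aligned with column blocks
        for pid, (a, b) in typed:
            arrs = self.slots[pid]
            if len(arrs) == 2:
                cols.append(np.minimum(arrs[0], arrs[1]))
                cols.append(np.maximum(arrs[0], arrs[1]))
                spec.append((2, (a, b)))
            else:
                if a != b:
                    raise InconsistentGenotypesError(
                        f"{pid}: heterozygous call for a hemizygote")
                cols.append(arrs[0])
                spec.append((1, (a,)))
        M = np.stack(cols, axis=1)
        uniq, inv = np.unique(M, axis=0, return_inverse=True)
        vals = np.array([self._solve_signature(row, spec, freqs)
                         for row in uniq])
        return vals[inv.reshape(-1)]

    @staticmethod
    def _solve_signature(row, spec, freqs) -> float:
        constraints = []
        i = 0
        for n, alleles in spec:
            constraints.append((tuple(int(s) for s in row[i:i + n]), alleles))
            i += n
        assign: dict[int, int] = {}

        def bind(s, a):
            """Try slot s <- allele a; return (ok, weight, added)."""
            if s in assign:
                return assign[s] == a, 1.0, False
            f = freqs.get(a, 0.0)
            if f <= 0.0:
                return False, 0.0, False
            assign[s] = a
            return True, f, True

        def rec(j):
            if j == len(constraints):
                return 1.0
            slots, alleles = constraints[j]
            if len(slots) == 1:
                (s,), (a,) = slots, alleles
                ok, wgt, added = bind(s, a)
                out = wgt * rec(j + 1) if ok else 0.0
                if added:
                    del assign[s]
                return out
            (s1, s2), (a, b) = slots, alleles
            if s1 == s2:
                if a != b:
                    return 0.0
                ok, wgt, added = bind(s1, a)
                out = wgt * rec(j + 1) if ok else 0.0
                if added:
                    del assign[s1]
                return out
            total = 0.0
            orders = [(a, b)] if a == b else [(a, b), (b, a)]
            for x, y in orders:
                ok1, w1, add1 = bind(s1, x)
                if ok1:
                    ok2, w2, add2 = bind(s2, y)
                    if ok2:
                        total += w1 * w2 * rec(j + 1)
                    if add2:
                        del assign[s2]
                if add1:
                    del assign[s1]
            return total
        return rec(0)

    def posterior_single(self, genotypes, freqs) -> np.ndarray:
        """Normalized P(v | genotypes) at one marker (uniform prior)."""
        L = self.likelihoods(genotypes, freqs)
        tot = L.sum()
        if tot <= 0:
            raise InconsistentGenotypesError(
                f"family {self.ped.family_id}: genotypes impossible under "
                "Mendelian transmission")
        return L / tot

    # -- multipoint HMM -----------------------------------------------------
    def _transport(self, x: np.ndarray, theta: float) -> np.ndarray:
        """Apply the per-meiosis independent-flip transition kernel."""
        lam = 1.0 - 2.0 * theta
        y = _fwht(x)
        y *= lam ** self._bitcount
        return _fwht(y) / self.nv

    def multipoint_posteriors(self, emissions: list[np.ndarray],
                              thetas: np.ndarray) -> list[np.ndarray]:
        """Forward-backward posteriors at every marker of one chromosome.

        ``emissions[k]`` is P(genotypes at marker k | v); ``thetas[k]`` is
        the recombination fraction between markers k and k+1.
        """
        K = len(emissions)
        if K == 1:
            e = emissions[0]
            return [e / e.sum()]
        fwd = []
        f = emissions[0].copy()
        s = f.sum()
        if s <= 0:
            raise InconsistentGenotypesError("zero likelihood at first marker")
        fwd.append(f / s)
        for k in range(1, K):
            f = self._transport(fwd[-1], thetas[k - 1]) * emissions[k]
            s = f.sum()
            if s <= 0:
                raise InconsistentGenotypesError(
                    f"zero likelihood at marker index {k}")
            fwd.append(f / s)
        bwd = [np.ones(self.nv)]
        for k in range(K - 2, -1, -1):
            b = self._transport(bwd[0] * emissions[k + 1], thetas[k])
            m = b.max()
            bwd.insert(0, b / m if m > 0 else b)
        out = []
        for k in range(K):
            p = fwd[k] * bwd[k]
            p = np.clip(p, 0.0, None)
            out.append(p / p.sum())
        return out

    def information_content(self, posterior: np.ndarray) -> float:
        """Entropy-based IC in [0, 1]: 1 - H(posterior)/H(uniform)."""
        if self.n_bits == 0:
            return 1.0
        p = posterior[posterior > 0]
        h = -(p * np.log2(p)).sum()
        return float(max(0.0, min(1.0, 1.0 - h / self.n_bits)))


# ---------------------------------------------------------------------------
# S_pairs scoring and Kong & Cox combination
# ---------------------------------------------------------------------------

@dataclass
class FamilyScore:
    """Standardized sharing of one family at one position."""
    family_id: str
    position: float
    s_obs: float
    mu0: float
    sigma0: float
    z: float
    weight: float = np.nan


def family_weights(engines: dict[str, FamilyEngine],
                   power: float = 0.5) -> pd.Series:
    """Pedigree-size weights for combining family Z scores.

    ``w_f = k_f**(power - 1) * sigma0_f`` with k_f the number of affected
    pairs, normalized to ``sum w**2 = 1``.  With power=1 each family's raw
    excess sharing enters once per affected pair (pair weighting); power=0
    weights the per-pair average equally across families (family
    weighting); power=0.5 is the compromise used for unequal pedigree
    sizes.
    """
    w = {}
    for fid, eng in engines.items():
        if eng.n_pairs == 0 or eng.sigma0 <= 0:
            continue
        w[fid] = eng.n_pairs ** (power - 1.0) * eng.sigma0
    s = pd.Series(w, dtype=float)
    return s / math.sqrt((s ** 2).sum())


def kong_cox(wz: np.ndarray, wz_min: np.ndarray, wz_max: np.ndarray,
             tol: float = 1e-10):
    """Maximize the Kong & Cox linear-model likelihood over delta.

    ``wz`` holds the observed w_f * Z_f terms; ``wz_min``/``wz_max`` the
    extreme attainable values of w_f * Z_f(v) over inheritance vectors,
    which bound delta so that every per-vector likelihood factor
    1 + delta * w_f * Z_f(v) stays positive.  Returns
    ``(delta_hat, signed_lod)``.
    """
    wz = np.asarray(wz, dtype=float)
    if np.all(wz == 0):
        return 0.0, 0.0
    neg = wz_min[wz_min < 0]
    pos = wz_max[wz_max > 0]
    hi = np.min(-1.0 / neg) if neg.size else 1.0
    lo = np.max(-1.0 / pos) if pos.size else -1.0
    margin = 1e-9 * (hi - lo)

    def nll(d):
        return -np.log1p(d * wz).sum()

    res = optimize.minimize_scalar(
        nll, bounds=(lo + margin, hi - margin), method="bounded",
        options={"xatol": tol})
    dhat = float(res.x)
    if abs(dhat) < 1e-9 * max(abs(hi), abs(lo)):
        # the interior optimum may sit at 0 exactly
        if -nll(0.0) >= -res.fun - 1e-15:
            return 0.0, 0.0
    lod = max(0.0, -res.fun) / LN10
    if lod < 1e-12:
        return 0.0, 0.0
    return dhat, math.copysign(lod, dhat)


def lod_to_p(lod) -> float:
    """One-sided nominal P for an allele-sharing LOD >= 0.

    P = 1 - Phi(sqrt(2 ln 10 * LOD)); LOD 0 maps to P = 0.5.
    """
    lod = np.asarray(lod, dtype=float)
    if np.any(lod < 0):
        raise ValueError("lod_to_p requires a non-negative LOD")
    out = stats.norm.sf(np.sqrt(2.0 * LN10 * lod))
    return float(out) if out.ndim == 0 else out


def p_to_lod(p) -> float:
    """Inverse of :func:`lod_to_p` (exact round-trip)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 0.5)):
        raise ValueError("p must lie in (0, 0.5]")
    z = stats.norm.isf(p)
    out = z * z / (2.0 * LN10)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

@dataclass
class LinkageTrack:
    """Per-position combined linkage results plus the family decomposition.

    ``table`` columns: chrom, marker, cM, dhat, lod (signed), p, ic.
    ``family_z`` is markers x families; ``weights`` the family weights.
    """
    table: pd.DataFrame
    family_z: pd.DataFrame
    weights: pd.Series

    def to_tsv(self, path) -> None:
        full = self.table.copy()
        z = self.family_z.rename(columns=lambda f: f"Z_{f}")
        full = pd.concat([full.set_index("marker"), z], axis=1)
        full.to_csv(path, sep="\t")

    def row(self, marker: str) -> pd.Series:
        hit = self.table[self.table["marker"] == marker]
        if hit.empty:
            raise KeyError(f"marker {marker!r} not in track")
        return hit.iloc[0]


_ENGINE_CACHE: dict[tuple, FamilyEngine] = {}


def _structure_key(ped: Pedigree, x_linked: bool) -> tuple:
    rows = tuple((i.person_id, i.father_id, i.mother_id, i.sex,
                  i.affection == "affected") for i in ped.members())
    return (ped.family_id, rows, x_linked)


def get_engine(ped: Pedigree, x_linked: bool = False,
               meiosis_cap: int = DEFAULT_MEIOSIS_CAP) -> FamilyEngine:
    """Structure-cached :class:`FamilyEngine` factory."""
    key = _structure_key(ped, x_linked)
    eng = _ENGINE_CACHE.get(key)
    if eng is None or eng.n_bits > meiosis_cap:
        eng = FamilyEngine(ped, x_linked=x_linked, meiosis_cap=meiosis_cap)
        _ENGINE_CACHE[key] = eng
    return eng


def scan(pedigrees: list[Pedigree], gm: GenotypeMatrix, mmap: MarkerMap,
         freqs: dict, power: float = 0.5, families: list[str] | None = None,
         meiosis_cap: int = DEFAULT_MEIOSIS_CAP,
         mask_mendelian: bool = True) -> LinkageTrack:
    """Multipoint S_pairs genome scan over all map positions.

    Families with fewer than two affected members (or a degenerate null SD)
    contribute no score and are skipped with a warning.  Marker genotypes
    inconsistent with Mendelian transmission are masked first unless
    ``mask_mendelian=False``.
    """
    if families is not None:
        pedigrees = [p for p in pedigrees if p.family_id in set(families)]
    if mask_mendelian:
        gm = gm.copy()
        check_mendelian(pedigrees, gm, mask=True)

    engines: dict[str, FamilyEngine] = {}
    for ped in pedigrees:
        if len(ped.affected_ids()) < 2:
            warnings.warn(f"family {ped.family_id}: fewer than 2 affected "
                          "members, skipped", stacklevel=2)
            continue
        eng = get_engine(ped, meiosis_cap=meiosis_cap)
        if eng.sigma0 <= 0:
            warnings.warn(f"family {ped.family_id}: degenerate null SD, "
                          "skipped", stacklevel=2)
            continue
        engines[ped.family_id] = eng

    if not engines:
        raise ValueError("no scorable families")
    weights = family_weights(engines, power=power)

    records = []
    zmat: dict[str, dict[str, float]] = {m: {} for m in mmap.markers}
    ic_num: dict[str, float] = {m: 0.0 for m in mmap.markers}
    ic_den: dict[str, float] = {m: 0.0 for m in mmap.markers}

    for chrom in mmap.chromosomes():
        sub = mmap.chrom_markers(chrom)
        markers = list(sub["marker"])
        thetas = mmap.thetas(chrom)
        x_linked = str(chrom).upper() == "X"
        for fid, eng0 in engines.items():
            eng = (get_engine(eng0.ped, x_linked=True,
                              meiosis_cap=meiosis_cap) if x_linked else eng0)
            if x_linked and (eng.sigma0 <= 0 or eng.n_bits == 0):
                continue
            ped = eng.ped
            emissions = [eng.likelihoods(gm.family_genotypes(ped, m), freqs[m])
                         for m in markers]
            posts = eng.multipoint_posteriors(emissions, thetas)
            for m, post in zip(markers, posts):
                s_obs = float(post @ eng.spairs_v)
                zmat[m][fid] = (s_obs - eng.mu0) / eng.sigma0
                ic_num[m] += eng.n_bits * eng.information_content(post)
                ic_den[m] += eng.n_bits

    fids = list(weights.index)
    w = weights.to_numpy()
    for _, row in mmap.table.iterrows():
        m = row["marker"]
        z = np.array([zmat[m].get(f, 0.0) for f in fids])
        wz = w * z
        wz_min = w * np.array([engines[f].z_min for f in fids])
        wz_max = w * np.array([engines[f].z_max for f in fids])
        dhat, slod = kong_cox(wz, wz_min, wz_max)
        p = lod_to_p(max(slod, 0.0))
        ic = ic_num[m] / ic_den[m] if ic_den[m] > 0 else 0.0
        records.append((row["chrom"], m, row["cM"], dhat, slod, p, ic))

    table = pd.DataFrame(records, columns=[
        "chrom", "marker", "cM", "dhat", "lod", "p", "ic"])
    family_z = pd.DataFrame(
        {f: [zmat[m].get(f, 0.0) for m in table["marker"]] for f in fids},
        index=table["marker"])
    return LinkageTrack(table=table, family_z=family_z, weights=weights)


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

def call_regions(track: LinkageTrack, lod_min: float = 0.59,
                 min_adjacent: int = 2) -> pd.DataFrame:
    """Maximal runs of >= ``min_adjacent`` consecutive markers with signed
    LOD >= ``lod_min``; peaks break ties leftmost."""
    rows = []
    tbl = track.table
    for chrom in dict.fromkeys(tbl["chrom"]):
        sub = tbl[tbl["chrom"] == chrom].reset_index(drop=True)
        above = (sub["lod"] >= lod_min).to_numpy()
        i = 0
        while i < len(sub):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and above[j + 1]:
                j += 1
            if j - i + 1 >= min_adjacent:
                run = sub.iloc[i:j + 1]
                peak = run["lod"].to_numpy().argmax()    # leftmost maximum
                rows.append((chrom, run["cM"].iloc[0], run["cM"].iloc[-1],
                             run["marker"].iloc[0], run["marker"].iloc[-1],
                             run["marker"].iloc[peak],
                             float(run["lod"].iloc[peak])))
            i = j + 1
    return pd.DataFrame(rows, columns=[
        "chrom", "start_cM", "end_cM", "start_marker", "end_marker",
        "peak_marker", "peak_lod"])


def write_regions(path, regions: pd.DataFrame) -> None:
    regions.to_csv(path, sep="\t", index=False)
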