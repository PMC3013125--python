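"""Detection of mis-specified and consanguineous parental relationships.

A pair of individuals is summarized by (P0, P1, P2), the probabilities of
sharing 0, 1 or 2 alleles identical by descent.  Expected values for a
relationship come from exact enumeration of the inheritance vectors of its
canonical pedigree; empirical values for a genotyped pair come from a
method-of-moments estimator built on identity-by-state expectations given
marker allele frequencies.  Pairs are then binned to the nearest catalogued
relationship, with P0 < 0.95 flagged as consistent with a consanguineal
marriage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage import FamilyEngine
from .pedio import Individual, Pedigree, add_inbreeding_loop

# Catalogue of relationship labels -> exact (P0, P1, P2).
CATALOGUE: dict[str, tuple[float, float, float]] = {
    "unrelated": (1.0, 0.0, 0.0),
    "second cousin": (0.9375, 0.0625, 0.0),
    "half first cousin": (0.875, 0.125, 0.0),
    "first cousin": (0.75, 0.25, 0.0),
    "half avuncular": (0.75, 0.25, 0.0),
    "double first cousin": (0.5625, 0.375, 0.0625),
    "half sib": (0.5, 0.5, 0.0),
    "avuncular": (0.5, 0.5, 0.0),
    "grandparent-child": (0.5, 0.5, 0.0),
    "half sib plus first cousin": (0.375, 0.5, 0.125),
    "full sib": (0.25, 0.5, 0.25),
    "parent-offspring": (0.0, 1.0, 0.0),
}

# Table-style bins keyed by P0 (grouped labels share a bin).
BINS: list[tuple[float, str]] = [
    (1.0, "unrelated"),
    (0.9375, "second cousin"),
    (0.875, "half-first cousin"),
    (0.75, "first cousin/half-avuncular"),
    (0.5625, "double first cousin"),
    (0.5, "half-sib/grandparent-child/avuncular"),
    (0.375, "half-sib plus first cousin"),
    (0.25, "full sib"),
    (0.0, "parent-offspring"),
]

RELATED_P0_CUTOFF = 0.95


@dataclass(frozen=True)
class RelationshipEstimate:
    pair: tuple[str, str]
    p0: float
    p1: float
    p2: float
    bin: str
    related: bool

    @property
    def triple(self):
        return (self.p0, self.p1, self.p2)


# ---------------------------------------------------------------------------
# Canonical pedigrees and expected sharing
# ---------------------------------------------------------------------------

def build_relationship_pedigree(label: str):
    """Canonical pedigree realizing a catalogue relationship.

    Returns ``(pedigree, (id_a, id_b))`` where the named pair has the
    relationship.  The pair is modelled as a couple with one (irrelevant)
    child so the same ancestor scaffolds used for inbreeding loops apply.
    """
    label = label.strip().lower()
    a, b = "A", "B"
    members = [
        Individual(a, "REL", None, None, "male", "unknown"),
        Individual(b, "REL", None, None, "female", "unknown"),
        Individual("C", "REL", a, b, "male", "unknown"),
    ]
    ped = Pedigree("REL", members)
    if label == "parent-offspring":
        return ped, (a, "C")
    if label == "grandparent-child":
        ped.add_individual(Individual("D", "REL", None, None, "female",
                                      "unknown"))
        ped.add_individual(Individual("E", "REL", "C", "D", "male", "unknown"))
        return ped, (a, "E")
    add_inbreeding_loop(ped, (a, b), label)
    return ped, (a, b)


def _pair_ibd_distribution(ped: Pedigree, pair: tuple[str, str]):
    sub = ped.ancestor_closure(set(pair))
    eng = FamilyEngine(sub, meiosis_cap=24)
    ibd = FamilyEngine._pair_ibd(eng.slots[pair[0]], eng.slots[pair[1]])
    return np.array([(ibd == k).mean() for k in (0, 1, 2)])


def expected_ibd_probs(relationship, pair: tuple[str, str] | None = None):
    """Exact (P0, P1, P2) for a catalogue label or a pedigree pair.

    With a label the catalogue constant is returned; with a
    :class:`Pedigree` and a pair of member ids the probabilities are
    computed exactly by enumerating the inheritance vectors of the pair's
    ancestor closure.
    """
    if isinstance(relationship, str):
        label = relationship.strip().lower()
        if label not in CATALOGUE:
            raise ValueError(f"unknown relationship label {relationship!r}")
        return CATALOGUE[label]
    if pair is None:
        raise ValueError("a pair of person ids is required with a pedigree")
    p = _pair_ibd_distribution(relationship, pair)
    return (float(p[0]), float(p[1]), float(p[2]))


def gene_drop_alleles(ped: Pedigree, n_reps: int, rng) -> dict[str, np.ndarray]:
    """Vectorized gene drop of founder-allele labels.

    Returns person id -> (n_reps, 2) array of founder-slot labels; labels
    are unique per founder allele so IBD equals label identity.
    """
    out: dict[str, np.ndarray] = {}
    slot = 0
    for pid in ped.topological_order():
        ind = ped.get(pid)
        if ind.is_founder:
            out[pid] = np.tile(np.array([slot, slot + 1]), (n_reps, 1))
            slot += 2
        else:
            rows = np.arange(n_reps)
            pat = out[ind.father_id][rows, rng.integers(0, 2, n_reps)]
            mat = out[ind.mother_id][rows, rng.integers(0, 2, n_reps)]
            out[pid] = np.column_stack([pat, mat])
    return out


def mc_ibd_probs(ped: Pedigree, pair: tuple[str, str], n_reps: int = 100_000,
                 seed: int = 0):
    """Monte Carlo gene-drop estimate of (P0, P1, P2) for a pedigree pair."""
    rng = np.random.default_rng(seed)
    sub = ped.ancestor_closure(set(pair))
    labels = gene_drop_alleles(sub, n_reps, rng)
    a, b = labels[pair[0]], labels[pair[1]]
    e11 = a[:, 0] == b[:, 0]; e22 = a[:, 1] == b[:, 1]
    e12 = a[:, 0] == b[:, 1]; e21 = a[:, 1] == b[:, 0]
    ibd = np.maximum(e11.astype(int) + e22, e12.astype(int) + e21)
    return tuple(float((ibd == k).mean()) for k in (0, 1, 2))


# ---------------------------------------------------------------------------
# Moments estimation from marker data
# ---------------------------------------------------------------------------

def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, len(v) + 1) > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


def pair_likelihood_triplet(g1, g2, p: dict):
    """P(genotype pair | IBD = 0, 1, 2) given allele frequencies.

    Unordered genotypes; the IBD=1 cases follow the classical conditional
    kinship formulas (each marginalizes back to the HWE genotype
    probability).
    """
    a, b = g1
    c, d = g2
    pa, pb = p.get(a, 0.0), p.get(b, 0.0)
    pc, pd_ = p.get(c, 0.0), p.get(d, 0.0)
    pg1 = pa * pa if a == b else 2.0 * pa * pb
    pg2 = pc * pc if c == d else 2.0 * pc * pd_
    l0 = pg1 * pg2
    same = tuple(sorted((a, b))) == tuple(sorted((c, d)))
    l2 = pg1 if same else 0.0
    s1, s2 = {a, b}, {c, d}
    if a == b and c == d:
        l1 = pa ** 3 if a == c else 0.0
    elif a == b:                                   # hom vs het
        l1 = pa * pa * (pd_ if c == a else pc) if a in s2 else 0.0
    elif c == d:
        l1 = pc * pc * (pb if a == c else pa) if c in s1 else 0.0
    elif s1 == s2:
        l1 = pa * pb * (pa + pb)
    else:
        shared = s1 & s2
        if len(shared) == 1:
            s = next(iter(shared))
            o1 = next(iter(s1 - shared))
            o2 = next(iter(s2 - shared))
            l1 = p.get(s, 0.0) * p.get(o1, 0.0) * p.get(o2, 0.0)
        else:
            l1 = 0.0
    return l0, l1, l2


def estimate_ibd_probs(g1: dict, g2: dict, freqs: dict,
                       min_markers: int = 100, max_iter: int = 500,
                       tol: float = 1e-10) -> RelationshipEstimate:
    """Estimate (P0, P1, P2) for a genotyped pair of individuals.

    The genotype pairs across markers are modelled as a three-component
    mixture over the latent IBD state with per-marker component
    likelihoods from :func:`pair_likelihood_triplet`; the mixing weights
    (P0, P1, P2) are fitted by EM, which keeps the estimate on the
    probability simplex by construction.  Markers are treated as
    independent (a deliberate simplification for sparsely spaced maps).
    """
    markers = [m for m in g1 if m in g2 and g1[m] is not None
               and g2[m] is not None and m in freqs]
    if len(markers) < min_markers:
        raise ValueError(
            f"only {len(markers)} markers typed in both individuals "
            f"(need >= {min_markers})")
    L = np.array([pair_likelihood_triplet(g1[m], g2[m], freqs[m])
                  for m in markers])
    L = L[L.sum(axis=1) > 0]
    pi = np.full(3, 1.0 / 3.0)
    for _ in range(max_iter):
        w = L * pi
        w /= w.sum(axis=1, keepdims=True)
        new = w.mean(axis=0)
        if np.abs(new - pi).max() < tol:
            pi = new
            break
        pi = new
    pi = _project_simplex(pi)        # guard against floating drift
    p0, p1, p2 = (float(x) for x in pi)
    bin_label, related = classify_relationship(p0)
    return RelationshipEstimate(pair=("", ""), p0=p0, p1=p1, p2=p2,
                                bin=bin_label, related=related)


def pair_genotypes(gm, family_id: str, person_id: str) -> dict:
    """Convenience: one individual's typed genotypes as marker -> pair."""
    return {m: gm.get(family_id, person_id, m) for m in gm.markers
            if gm.get(family_id, person_id, m) is not None}


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------

def classify_relationship(p0: float):
    """Nearest-bin relationship label for an estimated P0.

    Returns ``(bin_label, related)`` where ``related`` is True iff
    P0 < 0.95 (the consanguineal-marriage indicator).
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("P0 must lie in [0, 1]")
    if p0 >= RELATED_P0_CUTOFF:
        return BINS[0][1], False
    best = min(BINS[1:], key=lambda bp: abs(bp[0] - p0))
    return best[1], True


def bin_of_label(label: str) -> str:
    """Catalogue label -> the grouped bin label it falls in."""
    p0 = CATALOGUE[label.strip().lower()][0]
    return classify_relationship(p0)[0]


def summarize_relatedness(estimates: list[RelationshipEstimate]):
    """Counts and percentages per relationship bin for parental pairs.

    Returns ``(table, percent_related)``; percentages carry one decimal,
    the overall percent related (P0 < 0.95) is a whole percent.
    """
    if not estimates:
        return pd.DataFrame(columns=["bin", "count", "percent"]), 0
    total = len(estimates)
    order = {label: i for i, (_, label) in enumerate(BINS)}
    counts = pd.Series([e.bin for e in estimates]).value_counts()
    rows = [(label, int(counts[label]),
             round(100.0 * counts[label] / total, 1))
            for label in sorted(counts.index, key=order.get)]
    table = pd.DataFrame(rows, columns=["bin", "count", "percent"])
    n_related = sum(e.related for e in estimates)
    percent_related = round(100.0 * n_related / total)
    return table, percent_related


def parental_pair_report(estimates: list[RelationshipEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.pair[0], e.pair[1], e.p0, e.p1, e.p2, e.bin, e.related)
         for e in estimates],
        columns=["id1", "id2", "P0", "P1", "P2", "bin", "related"])
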