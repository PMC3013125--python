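"""Geographic-heterogeneity analysis of family linkage contributions.

Families are placed on a metric grid (UTM, WGS84), the combined allele-
sharing LOD at a marker is decomposed into additive per-family
contributions at the fitted Kong & Cox delta, and two complementary views
of spatial structure are built on top: a regression tree (CART) over UTM
northing/easting and religion, grown by SSE reduction and pruned by
cost-complexity cross-validation, and an inverse-distance-weighted raster
surface of the LOD contributions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import LN10, LinkageTrack, lod_to_p

# ---------------------------------------------------------------------------
# UTM conversion (transverse Mercator, WGS84, Karney/Krueger series)
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500_000.0

_n = _WGS84_F / (2.0 - _WGS84_F)
_E2 = _WGS84_F * (2.0 - _WGS84_F)
_E = math.sqrt(_E2)
_A_BAR = _WGS84_A / (1.0 + _n) * (1.0 + _n ** 2 / 4.0 + _n ** 4 / 64.0)
_ALPHA = (
    _n / 2.0 - 2.0 * _n ** 2 / 3.0 + 5.0 * _n ** 3 / 16.0
    + 41.0 * _n ** 4 / 180.0,
    13.0 * _n ** 2 / 48.0 - 3.0 * _n ** 3 / 5.0 + 557.0 * _n ** 4 / 1440.0,
    61.0 * _n ** 3 / 240.0 - 103.0 * _n ** 4 / 140.0,
    49561.0 * _n ** 4 / 161280.0,
)
_BETA = (
    _n / 2.0 - 2.0 * _n ** 2 / 3.0 + 37.0 * _n ** 3 / 96.0
    - _n ** 4 / 360.0,
    _n ** 2 / 48.0 + _n ** 3 / 15.0 - 437.0 * _n ** 4 / 1440.0,
    17.0 * _n ** 3 / 480.0 - 37.0 * _n ** 4 / 840.0,
    4397.0 * _n ** 4 / 161280.0,
)


def utm_central_meridian(zone: int) -> float:
    return -183.0 + 6.0 * zone


def latlon_to_utm(lat: float, lon: float, zone: int = 45):
    """Geographic (WGS84) to UTM easting/northing in meters.

    Standard transverse Mercator with scale 0.9996 and 500,000 m false
    easting; northern-hemisphere northing origin.  Latitudes outside
    [-80, 84] (the UTM domain) are rejected.
    """
    if not -80.0 <= lat <= 84.0:
        raise ValueError(f"latitude {lat} outside the UTM domain [-80, 84]")
    phi = math.radians(lat)
    lam = math.radians(lon - utm_central_meridian(zone))
    t = math.tan(phi)
    sigma = math.sinh(_E * math.atanh(_E * t / math.sqrt(1.0 + t * t)))
    tau = t * math.sqrt(1.0 + sigma * sigma) - sigma * math.sqrt(1.0 + t * t)
    xi_p = math.atan2(tau, math.cos(lam))
    eta_p = math.asinh(math.sin(lam) / math.hypot(tau, math.cos(lam)))
    xi = xi_p
    eta = eta_p
    for j, a in enumerate(_ALPHA, start=1):
        xi += a * math.sin(2 * j * xi_p) * math.cosh(2 * j * eta_p)
        eta += a * math.cos(2 * j * xi_p) * math.sinh(2 * j * eta_p)
    easting = _FALSE_EASTING + _K0 * _A_BAR * eta
    northing = _K0 * _A_BAR * xi
    if lat < 0:
        northing += 10_000_000.0
    return easting, northing


def utm_to_latlon(easting: float, northing: float, zone: int = 45,
                  northern: bool = True):
    """Inverse UTM projection (meters -> WGS84 lat/lon degrees)."""
    if not northern:
        northing -= 10_000_000.0
    xi = northing / (_K0 * _A_BAR)
    eta = (easting - _FALSE_EASTING) / (_K0 * _A_BAR)
    xi_p = xi
    eta_p = eta
    for j, b in enumerate(_BETA, start=1):
        xi_p -= b * math.sin(2 * j * xi) * math.cosh(2 * j * eta)
        eta_p -= b * math.cos(2 * j * xi) * math.sinh(2 * j * eta)
    tau_p = math.sin(xi_p) / math.hypot(math.sinh(eta_p), math.cos(xi_p))
    lam = math.atan2(math.sinh(eta_p), math.cos(xi_p))
    tau = tau_p / (1.0 - _E2)            # initial guess
    for _ in range(6):                   # Newton on tau'(tau) - tau_p = 0
        sigma = math.sinh(_E * math.atanh(
            _E * tau / math.sqrt(1.0 + tau * tau)))
        cur = (tau * math.sqrt(1.0 + sigma * sigma)
               - sigma * math.sqrt(1.0 + tau * tau))
        df = ((1.0 - _E2) * math.sqrt(1.0 + cur * cur)
              / math.sqrt(1.0 + tau * tau))
        tau -= (cur - tau_p) / df
    lat = math.degrees(math.atan(tau))
    lon = math.degrees(lam) + utm_central_meridian(zone)
    return lat, lon


def families_to_utm(meta: pd.DataFrame, zone: int = 45) -> pd.DataFrame:
    """Family metadata (family_id, lat, lon, religion) -> UTM coordinates."""
    rows = []
    for _, r in meta.iterrows():
        e, n = latlon_to_utm(float(r["lat"]), float(r["lon"]), zone)
        rows.append((str(r["family_id"]), e, n, r["religion"]))
    return pd.DataFrame(rows, columns=["family_id", "easting", "northing",
                                       "religion"]).set_index("family_id")


# ---------------------------------------------------------------------------
# Per-family LOD decomposition
# ---------------------------------------------------------------------------

def family_lod_decomposition(track: LinkageTrack, marker: str) -> pd.Series:
    """Additive per-family signed LOD contributions at one marker.

    Family f contributes sign(delta_hat) * log10(1 + delta_hat w_f Z_f) at
    the combined delta_hat, so the contributions sum exactly to the
    combined signed LOD.
    """
    row = track.row(marker)
    dhat = float(row["dhat"])
    z = track.family_z.loc[marker]
    w = track.weights.reindex(z.index).fillna(0.0)
    if dhat == 0.0:
        return pd.Series(0.0, index=z.index)
    contrib = np.sign(dhat) * np.log1p(dhat * w * z) / LN10
    return contrib


# ---------------------------------------------------------------------------
# Regression tree (CART) over geography and religion
# ---------------------------------------------------------------------------

@dataclass
class GeoNode:
    """One tree node with the bookkeeping used in reporting: the number of
    families n, their mean LOD contribution, and the summed LOD."""
    ids: list
    n: int
    mean: float
    total: float
    sse: float
    var: str | None = None
    cut: float | None = None
    cats: frozenset | None = None
    left: "GeoNode | None" = None
    right: "GeoNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def rule(self) -> str:
        if self.is_leaf:
            return "<leaf>"
        if self.cut is not None:
            return f"{self.var} < {self.cut:.6g}"
        return f"{self.var} in {{{', '.join(sorted(map(str, self.cats)))}}}"


NUMERIC_VARS = ("northing", "easting")
CATEGORICAL_VARS = ("religion",)


def _sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0


def _best_split(y: np.ndarray, X: pd.DataFrame, min_leaf: int):
    """Best SSE-reducing binary split; ties toward the earlier variable and
    smaller cut."""
    parent = _sse(y)
    best = None     # (improvement, var, cut, cats)
    n = len(y)
    for var in NUMERIC_VARS + CATEGORICAL_VARS:
        if var not in X.columns:
            continue
        x = X[var].to_numpy()
        if var in CATEGORICAL_VARS:
            levels = pd.unique(x)
            if len(levels) < 2:
                continue
            means = {lv: y[x == lv].mean() for lv in levels}
            ordered = sorted(levels, key=lambda lv: (means[lv], str(lv)))
            codes = np.array([ordered.index(v) for v in x], dtype=float)
            scan_x, is_cat = codes, ordered
        else:
            scan_x, is_cat = x.astype(float), None
        order = np.argsort(scan_x, kind="mergesort")
        xs, ys = scan_x[order], y[order]
        cs, cs2 = np.cumsum(ys), np.cumsum(ys ** 2)
        tot, tot2 = cs[-1], cs2[-1]
        for i in range(n - 1):
            if xs[i + 1] <= xs[i]:
                continue
            nl = i + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            sl = cs2[i] - cs[i] ** 2 / nl
            sr = (tot2 - cs2[i]) - (tot - cs[i]) ** 2 / nr
            imp = parent - sl - sr
            if best is None or imp > best[0] + 1e-12:
                if is_cat is None:
                    best = (imp, var, (xs[i] + xs[i + 1]) / 2.0, None)
                else:
                    best = (imp, var, None, frozenset(is_cat[:int(xs[i]) + 1]))
    return best


def _grow(y: pd.Series, X: pd.DataFrame, ids: list, min_leaf: int,
          min_split: int, depth: int, max_depth: int) -> GeoNode:
    yv = y.loc[ids].to_numpy(dtype=float)
    node = GeoNode(ids=list(ids), n=len(ids), mean=float(yv.mean()),
                   total=float(yv.sum()), sse=_sse(yv))
    if len(ids) < min_split or depth >= max_depth or node.sse <= 1e-14:
        return node
    found = _best_split(yv, X.loc[ids], min_leaf)
    if found is None or found[0] <= 1e-12:
        return node
    _, var, cut, cats = found
    xcol = X.loc[ids, var]
    if cut is not None:
        go_left = xcol.astype(float) < cut
    else:
        go_left = xcol.isin(cats)
    left_ids = [i for i, g in zip(ids, go_left) if g]
    right_ids = [i for i, g in zip(ids, go_left) if not g]
    node.var, node.cut, node.cats = var, cut, cats
    node.left = _grow(y, X, left_ids, min_leaf, min_split, depth + 1,
                      max_depth)
    node.right = _grow(y, X, right_ids, min_leaf, min_split, depth + 1,
                       max_depth)
    return node


def _subtree_stats(node: GeoNode):
    if node.is_leaf:
        return node.sse, 1
    ls, ln_ = _subtree_stats(node.left)
    rs, rn = _subtree_stats(node.right)
    return ls + rs, ln_ + rn


def _copy_tree(node: GeoNode) -> GeoNode:
    clone = GeoNode(ids=node.ids, n=node.n, mean=node.mean, total=node.total,
                    sse=node.sse, var=node.var, cut=node.cut, cats=node.cats)
    if not node.is_leaf:
        clone.left = _copy_tree(node.left)
        clone.right = _copy_tree(node.right)
    return clone


def _prune_at_alpha(node: GeoNode, alpha: float) -> GeoNode:
    """Collapse every internal node whose weakest-link value g <= alpha."""
    if node.is_leaf:
        return node
    node.left = _prune_at_alpha(node.left, alpha)
    node.right = _prune_at_alpha(node.right, alpha)
    sub_sse, leaves = _subtree_stats(node)
    g = (node.sse - sub_sse) / (leaves - 1)
    if g <= alpha + 1e-15:
        node.var = node.cut = node.cats = None
        node.left = node.right = None
    return node


def _alpha_sequence(root: GeoNode) -> list[float]:
    """Weakest-link alpha path of a grown tree."""
    alphas = [0.0]
    tree = _copy_tree(root)
    while not tree.is_leaf:
        gs = []

        def walk(nd):
            if nd.is_leaf:
                return
            sub_sse, leaves = _subtree_stats(nd)
            gs.append((nd.sse - sub_sse) / (leaves - 1))
            walk(nd.left)
            walk(nd.right)
        walk(tree)
        a = min(gs)
        alphas.append(a)
        tree = _prune_at_alpha(tree, a)
    return sorted(set(alphas))


def _predict(node: GeoNode, row: pd.Series) -> float:
    while not node.is_leaf:
        if node.cut is not None:
            node = node.left if float(row[node.var]) < node.cut else node.right
        else:
            node = node.left if row[node.var] in node.cats else node.right
    return node.mean


class GeoTree:
    """Fitted regression tree over (northing, easting, religion)."""

    def __init__(self, root: GeoNode, response: pd.Series,
                 predictors: pd.DataFrame, cv_table: pd.DataFrame | None):
        self.root = root
        self.response = response
        self.predictors = predictors
        self.cv_table = cv_table

    def leaves(self) -> list[GeoNode]:
        out = []

        def walk(nd):
            if nd.is_leaf:
                out.append(nd)
            else:
                walk(nd.left)
                walk(nd.right)
        walk(self.root)
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return pd.Series([_predict(self.root, r) for _, r in X.iterrows()],
                         index=X.index)

    def first_split(self):
        if self.root.is_leaf:
            return None
        return (self.root.var,
                self.root.cut if self.root.cut is not None else self.root.cats)

    def format_text(self) -> str:
        lines = []

        def walk(nd, indent, tag):
            lines.append(
                f"{'  ' * indent}{tag}{nd.rule()}  "
                f"n={nd.n} mean={nd.mean:.4f} sum={nd.total:.4f}")
            if not nd.is_leaf:
                walk(nd.left, indent + 1, "T: ")
                walk(nd.right, indent + 1, "F: ")
        walk(self.root, 0, "")
        return "\n".join(lines)

    def to_json(self) -> str:
        def encode(nd):
            d = {"n": nd.n, "mean": nd.mean, "sum": nd.total}
            if not nd.is_leaf:
                d["var"] = nd.var
                if nd.cut is not None:
                    d["cut"] = nd.cut
                else:
                    d["categories"] = sorted(map(str, nd.cats))
                d["left"] = encode(nd.left)
                d["right"] = encode(nd.right)
            else:
                d["families"] = list(map(str, nd.ids))
            return d
        return json.dumps(encode(self.root), indent=1)


def fit_geo_tree(lod: pd.Series, geo: pd.DataFrame, min_leaf: int = 5,
                 min_split: int | None = None, max_depth: int = 10,
                 cv_folds: int = 10, seed: int = 0,
                 prune: bool = True) -> GeoTree:
    """Greedy SSE regression tree with cost-complexity CV pruning.

    ``lod`` holds one LOD contribution per family; ``geo`` is indexed by
    family with columns northing, easting (meters) and religion.  Numeric
    rules read "var < cut" with the true branch on the left; candidate cuts
    are midpoints of sorted unique values.  The grown tree is pruned to the
    cost-complexity subtree whose ``cv_folds``-fold cross-validation error
    first reaches the distinct minimum (smallest tree within numerical tie
    of the CV minimum).
    """
    ids = [i for i in lod.index if i in geo.index]
    if len(ids) < 2:
        raise ValueError("need at least 2 families")
    y = lod.loc[ids].astype(float)
    X = geo.loc[ids]
    if min_split is None:
        min_split = max(2 * min_leaf, 2)
    root = _grow(y, X, ids, min_leaf, min_split, 0, max_depth)
    cv_table = None
    if prune and not root.is_leaf:
        alphas = _alpha_sequence(root)
        cands = [0.0] + [math.sqrt(alphas[i] * alphas[i + 1])
                         if alphas[i] > 0 else alphas[i + 1] / 2.0
                         for i in range(len(alphas) - 1)] + [alphas[-1] * 1.01]
        cands = sorted(set(cands))
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(ids))
        folds = np.array_split(perm, min(cv_folds, len(ids)))
        err = np.zeros(len(cands))
        for fold in folds:
            if len(fold) == 0:
                continue
            test_ids = [ids[i] for i in fold]
            train_ids = [i for i in ids if i not in set(test_ids)]
            if len(train_ids) < 2:
                continue
            sub = _grow(y, X, train_ids, min_leaf, min_split, 0, max_depth)
            for ci, alpha in enumerate(cands):
                pruned = _prune_at_alpha(_copy_tree(sub), alpha)
                pred = np.array([_predict(pruned, X.loc[t])
                                 for t in test_ids])
                err[ci] += float(((y.loc[test_ids].to_numpy() - pred) ** 2)
                                 .sum())
        best = err.min()
        # smallest tree (largest alpha) within numerical tie of the minimum
        chosen = max(a for a, e in zip(cands, err)
                     if e <= best * (1 + 1e-9) + 1e-12)
        root = _prune_at_alpha(root, chosen)
        cv_table = pd.DataFrame({"alpha": cands, "cv_error": err})
    return GeoTree(root, y, X, cv_table)


def geo_report(tree: GeoTree) -> pd.DataFrame:
    """Per-leaf cluster table: families, n, mean LOD, summed LOD, nominal P
    (P from the LOD->P conversion when the summed LOD is non-negative)."""
    rows = []
    for k, leaf in enumerate(tree.leaves()):
        p = lod_to_p(leaf.total) if leaf.total >= 0 else np.nan
        rows.append((k, ",".join(map(str, leaf.ids)), leaf.n, leaf.mean,
                     leaf.total, p))
    return pd.DataFrame(rows, columns=["leaf", "families", "n", "mean_lod",
                                       "sum_lod", "p"])


# ---------------------------------------------------------------------------
# Inverse-distance-weighted LOD surface
# ---------------------------------------------------------------------------

@dataclass
class LodSurface:
    """IDW raster: lower-left origin (meters), square cell size, and a
    (nrows, ncols) value grid with row 0 at the bottom."""
    x0: float
    y0: float
    cell: float
    values: np.ndarray

    @property
    def shape(self):
        return self.values.shape


def idw_surface(points: pd.DataFrame, bounds=None, cell_km: float = 0.5,
                power: float = 1.0, pad_km: float = 1.0,
                exact_eps: float = 1.0) -> LodSurface:
    """Inverse-distance-weighted interpolation of family LOD values.

    ``points`` needs columns easting, northing, lod (meters).  Every data
    point contributes to every cell with weight 1/d**power (first-order by
    default); a point within ``exact_eps`` meters of a cell centroid takes
    the cell over exactly.  Default bounds pad the family bounding box by
    ``pad_km``.
    """
    if len(points) == 0:
        raise ValueError("empty point set")
    px = points["easting"].to_numpy(dtype=float)
    py = points["northing"].to_numpy(dtype=float)
    pv = points["lod"].to_numpy(dtype=float)
    cell = cell_km * 1000.0
    if bounds is None:
        pad = pad_km * 1000.0
        bounds = (px.min() - pad, px.max() + pad,
                  py.min() - pad, py.max() + pad)
    xmin, xmax, ymin, ymax = bounds
    ncols = max(1, int(math.ceil((xmax - xmin) / cell)))
    nrows = max(1, int(math.ceil((ymax - ymin) / cell)))
    cx = xmin + (np.arange(ncols) + 0.5) * cell
    cy = ymin + (np.arange(nrows) + 0.5) * cell
    gx, gy = np.meshgrid(cx, cy)
    d = np.hypot(gx[:, :, None] - px[None, None, :],
                 gy[:, :, None] - py[None, None, :])
    with np.errstate(divide="ignore"):
        w = 1.0 / np.where(d > 0, d, np.inf) ** power
    vals = (w * pv[None, None, :]).sum(axis=2) / w.sum(axis=2)
    near = d.argmin(axis=2)
    dmin = d.min(axis=2)
    vals = np.where(dmin <= exact_eps, pv[near], vals)
    return LodSurface(x0=xmin, y0=ymin, cell=cell, values=vals)


def write_esri_ascii(surface: LodSurface, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid raster (plain text, top row first)."""
    nrows, ncols = surface.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {surface.x0:.3f}\n")
        fh.write(f"yllcorner {surface.y0:.3f}\n")
        fh.write(f"cellsize {surface.cell:.3f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in surface.values[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
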