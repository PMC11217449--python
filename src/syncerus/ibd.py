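"""Isolation-by-distance inference.

Great-circle (Haversine) distances between population centroids, a Mantel
permutation test between the FST and distance matrices, classification of
population pairs (forest-buffalo and bottleneck classes versus the rest),
and per-class ordinary least squares of FST on distance with a two-sided
t-test of the intercept.  Under pure isolation by distance the intercept is
indistinguishable from zero; a significantly positive intercept flags excess
differentiation, as for a bottlenecked population.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import ParameterError, PopulationGroup

EARTH_RADIUS_KM = 6371.0

PAIR_CLASSES = ("involves_nanus", "involves_HU", "nanus_vs_HU", "rest")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ParameterError(f"coordinates out of bounds: ({lat}, {lon})")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def distance_matrix(groups: list[PopulationGroup]) -> pd.DataFrame:
    """Pairwise Haversine distances between group centroids (km)."""
    for g in groups:
        if g.lat is None or g.lon is None or not np.isfinite([g.lat, g.lon]).all():
            raise ParameterError(f"group {g.name!r} has no centroid")
    names = [g.name for g in groups]
    n = len(groups)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(groups[i].lat, groups[i].lon,
                             groups[j].lat, groups[j].lon)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str
    method: str          # "sampled" or "exact"
    undefined: bool = False


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _pearson(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Correlation of x against each row of Y (vectorized)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = Yc @ xc
    den = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _as_square(m) -> np.ndarray:
    a = np.asarray(m, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] < 3:
        raise ParameterError("mantel_test needs square matrices of size >= 3")
    if not np.allclose(a, a.T) or not np.allclose(np.diag(a), 0.0):
        raise ParameterError("mantel_test needs symmetric, zero-diagonal matrices")
    return a


def mantel_test(
    m1,
    m2,
    n_perm: int = 9999,
    alternative: str = "two-sided",
    seed: int | None = 0,
    method: str = "auto",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson correlation of the strict upper triangles;
    the null distribution jointly permutes rows and columns of ``m2``.  For
    the sampled test, p = (#{extreme} + 1) / (n_perm + 1).  ``method="exact"``
    (or ``"auto"`` when n! <= n_perm) enumerates every relabeling and reports
    the exact fraction, counting the identity.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    a = _as_square(m1)
    b = _as_square(m2)
    if a.shape != b.shape:
        raise ParameterError("mantel_test matrices differ in shape")
    n = a.shape[0]
    x = _upper(a)
    y = _upper(b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MantelResult(np.nan, np.nan, 0, alternative, "none", undefined=True)
    r_obs = float(_pearson(x, y[None, :])[0])

    exact = method == "exact" or (
        method == "auto" and math.factorial(n) <= n_perm
    )
    iu = np.triu_indices(n, k=1)
    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    permuted = b[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]
    r_perm = _pearson(x, permuted)

    eps = 1e-12
    if alternative == "two-sided":
        extreme = np.abs(r_perm) >= abs(r_obs) - eps
    elif alternative == "greater":
        extreme = r_perm >= r_obs - eps
    else:
        extreme = r_perm <= r_obs + eps
    if exact:
        p = float(extreme.sum()) / len(perms)
        return MantelResult(r_obs, p, len(perms), alternative, "exact")
    p = (float(extreme.sum()) + 1.0) / (n_perm + 1.0)
    return MantelResult(r_obs, p, n_perm, alternative, "sampled")


# ---------------------------------------------------------------------------
# Pair classification and per-class regression
# ---------------------------------------------------------------------------

def classify_pair(name_a: str, name_b: str, nanus: set, hu: set) -> str:
    """Class label for one population pair.

    ``nanus_vs_HU`` when one side is a forest-buffalo group and the other the
    bottlenecked group; otherwise ``involves_nanus``, then ``involves_HU``,
    then ``rest``.
    """
    a_n, b_n = name_a in nanus, name_b in nanus
    a_h, b_h = name_a in hu, name_b in hu
    if (a_n and b_h) or (a_h and b_n):
        return "nanus_vs_HU"
    if a_n or b_n:
        return "involves_nanus"
    if a_h or b_h:
        return "involves_HU"
    return "rest"


def pair_table(
    fst: pd.DataFrame,
    dist: pd.DataFrame,
    nanus: set | frozenset = frozenset(),
    hu: set | frozenset = frozenset(),
) -> pd.DataFrame:
    """Long-format table of population pairs with FST, km and class label."""
    names = list(fst.index)
    unknown = (set(nanus) | set(hu)) - set(names)
    if unknown:
        raise ParameterError(f"unknown group names: {sorted(unknown)}")
    if list(dist.index) != names or list(dist.columns) != names:
        dist = dist.loc[names, names]
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append(
                (a, b, float(fst.loc[a, b]), float(dist.loc[a, b]),
                 classify_pair(a, b, set(nanus), set(hu)))
            )
    return pd.DataFrame(
        rows, columns=["pop_a", "pop_b", "fst", "distance_km", "pair_class"]
    )


@dataclass
class RegressionResult:
    pair_class: str
    slope: float
    intercept: float
    intercept_se: float
    intercept_p: float
    n_pairs: int


def _ols(pairs: pd.DataFrame, label: str) -> RegressionResult:
    if len(pairs) < 3:
        raise ParameterError(
            f"class {label!r} has {len(pairs)} pairs; need >= 3 for a fit"
        )
    x = pairs["distance_km"].to_numpy()
    if np.ptp(x) == 0:
        raise ParameterError(f"class {label!r}: degenerate distances (all equal)")
    model = sm.OLS(pairs["fst"].to_numpy(), sm.add_constant(x)).fit()
    return RegressionResult(
        pair_class=label,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        intercept_se=float(model.bse[0]),
        intercept_p=float(model.pvalues[0]),
        n_pairs=len(pairs),
    )


def ibd_regression(
    pairs: pd.DataFrame, classes: tuple | list | None = None
) -> dict[str, RegressionResult]:
    """Per-class OLS of FST on distance with intercept t-tests.

    ``classes`` defaults to every class with at least three pairs.  The
    ``rest`` fit reproduces the exclusion analysis: only pairs in which
    neither population is flagged.  An ``all`` fit over every pair is always
    included.
    """
    out = {"all": _ols(pairs, "all")}
    wanted = classes
    if wanted is None:
        counts = pairs["pair_class"].value_counts()
        wanted = [c for c in PAIR_CLASSES if counts.get(c, 0) >= 3]
    for c in wanted:
        sub = pairs[pairs["pair_class"] == c]
        out[c] = _ols(sub, c)
    return out


def ibd_from_tables(
    fst: pd.DataFrame,
    dist: pd.DataFrame,
    nanus: set | frozenset = frozenset(),
    hu: set | frozenset = frozenset(),
    n_perm: int = 9999,
    seed: int | None = 0,
):
    """Full IBD workflow from an FST matrix and a centroid-distance matrix.

    Returns (pair table, Mantel over all groups, Mantel excluding the flagged
    groups, per-class regressions).  This is the entry point for deposited
    summary tables as well as simulated ones.
    """
    pairs = pair_table(fst, dist, nanus=nanus, hu=hu)
    mantel_all = mantel_test(fst.to_numpy(), dist.loc[fst.index, fst.index].to_numpy(),
                             n_perm=n_perm, seed=seed)
    keep = [n for n in fst.index if n not in set(nanus) | set(hu)]
    mantel_excl = None
    if len(keep) >= 3:
        mantel_excl = mantel_test(
            fst.loc[keep, keep].to_numpy(), dist.loc[keep, keep].to_numpy(),
            n_perm=n_perm, seed=seed,
        )
    regs = ibd_regression(pairs)
    return pairs, mantel_all, mantel_excl, regs
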