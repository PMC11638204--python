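"""Standard and weighted Kendall's tau between a ranked gene set and gene list.

A gene set (TF targets scored by binding-site strength) and a gene list
(genes scored by a per-sample specificity index) are intersected; the shared
genes are ordered by descending set score so that the set-side ranks are
i = 1..n, and R_i is the list-side rank of the gene at set position i. The
tau-a statistic

    τ  = 2/(n(n−1)) · Σ_{i>j} sgn(i−j)·sgn(R_i−R_j)

and its weighted form (Shieh-style per-item weights v_i)

    τ_w = 2/((Σv)² − Σv²) · Σ_{i>j} v_i v_j sgn(i−j)·sgn(R_i−R_j)

measure rank concordance. Five weighting schemes are supported, mirroring
the tool options ``-w 0/1/2/7/8``:

====  ===================  ====================================================
w     name                 weight of gene at set rank i_s, list rank i_l
====  ===================  ====================================================
0     STD                  1 (unweighted)
1     MIX-LINEAR           sqrt[(1−(i_s−0.5)/n)·(1−(i_l−0.5)/n)]
2     LINEAR               1−(i_l−0.5)/n (gene-list side only)
7     MIXED-DENSITY-CURVE  sqrt[(1−d_s/max d_s)·(1−d_l/max d_l)]
8     DENSITY-CURVE        1−d_l/max d_l (gene-list side only)
====  ===================  ====================================================

where d_s, d_l are Gaussian kernel densities (Silverman bandwidth) of the
continuous set/list scores evaluated at each gene's own score. The linear
schemes emphasize top-ranked genes; the density schemes up-weight both tails
of the score distribution (where the density is low) and down-weight the
non-differential bulk.

P-values come from a normal approximation with an exact permutation-null
variance computed from the realized weights. Every built-in scheme
factorizes as v_i = α_i·β_{R_i} (a set-side factor attached to set rank i
and a list-side factor attached to list rank r); under the null the β
factors travel with the permuted ranks, and the exact variance of the pair
sum follows from the permutation moments of generalized correlation
coefficients:

    Var(U) = A2·B2 / (2n(n−1)) + P_α·P_β / (n(n−1)(n−2)),

with A2 = Σ_{i≠j} α_i²α_j², P_α = Σ_i (Σ_{j≠i} α_iα_j sgn(j−i))² − A2 and
likewise for β. For α = β ≡ 1 this reduces algebraically to the classic
z = 3·sqrt(n(n−1)/(2(2n+5)))·τ. For a bare user-supplied weight vector the
weights are treated as fixed under permutation, with the corresponding
exact conditional variance

    Var(τ_w) = c²·[ Σ_{i<j} v_i²v_j²
                    + (2/3)·Σ_{i<j<k} v_i v_j v_k (v_i − v_j + v_k) ],

c = 2/((Σv)²−Σv²). A permutation p-value is available as a reference null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SCHEME_NAMES",
    "PairedRanks",
    "WeightVector",
    "TauResult",
    "align_ranks",
    "pairs_from_scores",
    "estimate_densities",
    "make_weights",
    "std_tau",
    "weighted_tau",
    "permutation_p",
    "association_test",
]

SCHEME_NAMES = {
    0: "STD",
    1: "MIX-LINEAR",
    2: "LINEAR",
    7: "MIXED-DENSITY-CURVE",
    8: "DENSITY-CURVE",
}

_ALIASES = {name.lower(): num for num, name in SCHEME_NAMES.items()}
_ALIASES.update({f"w{num}": num for num in SCHEME_NAMES})


def normalize_scheme(scheme) -> int:
    """Map 7, "7", "w7" or "mixed-density-curve" to the canonical number."""
    if isinstance(scheme, str):
        key = scheme.strip().lower()
        if key in _ALIASES:
            return _ALIASES[key]
        if key.isdigit():
            scheme = int(key)
    if scheme in SCHEME_NAMES:
        return int(scheme)
    raise ValueError(f"unknown weighting scheme {scheme!r} "
                     f"(choose from {sorted(SCHEME_NAMES)})")


@dataclass(frozen=True)
class PairedRanks:
    """Shared genes ordered by descending gene-set score.

    Set-side ranks are implicitly i = 1..n (the row order); ``ranks`` holds
    the list-side ranks R_i (1 = highest list score). The continuous scores
    are kept for the density weighting schemes.
    """

    genes: tuple[str, ...]
    set_scores: np.ndarray
    list_scores: np.ndarray
    ranks: np.ndarray
    testable: bool = True
    n_list_ties: int = 0

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class WeightVector:
    """Per-gene weights v_i for one scheme (clamped to (0, 1]).

    All built-in schemes factorize as v_i = alpha_i · beta_{R_i}, with
    ``alpha`` attached to the set-rank position i and ``beta`` attached to
    the list rank r. When the factors are present the null distribution
    accounts for the weights co-moving with the permutation (see
    :func:`weighted_tau`); a bare ``v`` (factors None) is treated as fixed.
    """

    scheme: int
    v: np.ndarray
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    d_set: np.ndarray | None = None
    d_list: np.ndarray | None = None


@dataclass(frozen=True)
class TauResult:
    tau: float
    z: float
    p: float
    direction: int
    n_overlap: int
    scheme: int
    null: str = "asymptotic"


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _as_score_map(obj) -> dict[str, float]:
    if hasattr(obj, "members"):  # RankedGeneSet
        obj = obj.members
    elif hasattr(obj, "scores"):  # RankedGeneList
        obj = obj.scores
    if hasattr(obj, "items"):
        return {str(k): float(v) for k, v in obj.items()}
    raise TypeError(f"cannot interpret {type(obj).__name__} as gene scores")


def align_ranks(gene_set, gene_list, min_overlap: int = 10) -> PairedRanks:
    """Intersect a gene set and a gene list into paired ranks.

    Genes are ordered by descending set score (rank 1 = top); R_i is the
    gene's position when the shared genes are ordered by descending list
    score. Score ties are broken by gene id for determinism and counted.
    Overlaps below ``min_overlap`` are flagged untestable.
    """
    set_map = _as_score_map(gene_set)
    list_map = _as_score_map(gene_list)
    if not set_map or not list_map:
        raise ValueError("gene set and gene list must be non-empty")
    common = sorted(set(set_map) & set(list_map))
    n = len(common)
    if n < max(min_overlap, 2):
        return PairedRanks(genes=tuple(common),
                           set_scores=np.array([set_map[g] for g in common]),
                           list_scores=np.array([list_map[g] for g in common]),
                           ranks=np.zeros(n, dtype=np.int64),
                           testable=False)
    order_set = sorted(common, key=lambda g: (-set_map[g], g))
    order_list = sorted(common, key=lambda g: (-list_map[g], g))
    list_rank = {g: r for r, g in enumerate(order_list, start=1)}
    list_vals = np.array([list_map[g] for g in order_set])
    n_ties = n - len(set(list_map[g] for g in common))
    if n_ties:
        warnings.warn(f"{n_ties} tied list score(s) broken by gene id",
                      RuntimeWarning, stacklevel=2)
    return PairedRanks(
        genes=tuple(order_set),
        set_scores=np.array([set_map[g] for g in order_set]),
        list_scores=list_vals,
        ranks=np.array([list_rank[g] for g in order_set], dtype=np.int64),
        testable=True,
        n_list_ties=n_ties,
    )


def pairs_from_scores(set_scores: Sequence[float], list_scores: Sequence[float],
                      genes: Sequence[str] | None = None,
                      min_overlap: int = 2) -> PairedRanks:
    """Build PairedRanks directly from two paired score vectors (e.g. simulated)."""
    s = np.asarray(set_scores, dtype=float)
    l = np.asarray(list_scores, dtype=float)
    if s.shape != l.shape or s.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    if genes is None:
        genes = [f"g{i:07d}" for i in range(s.size)]
    return align_ranks(dict(zip(genes, s)), dict(zip(genes, l)),
                       min_overlap=min_overlap)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def estimate_densities(pairs: PairedRanks) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE (Silverman bandwidth) of the set and list scores,
    evaluated at each gene's own score."""
    out = []
    for name, x in (("set", pairs.set_scores), ("list", pairs.list_scores)):
        try:
            kde = stats.gaussian_kde(x, bw_method="silverman")
            out.append(kde(x))
        except Exception as exc:
            raise ValueError(
                f"degenerate {name} scores (zero variance?): density weighting "
                "is undefined — use a rank-based scheme (w0/w1/w2)"
            ) from exc
    return out[0], out[1]


def make_weights(pairs: PairedRanks, scheme,
                 densities: tuple[np.ndarray, np.ndarray] | None = None,
                 clamp_min: float = 1e-3) -> WeightVector:
    """Build the weight vector v_i for one scheme (see module docstring).

    Weights are assembled from a set-side factor alpha (indexed by set rank
    i) and a list-side factor beta (indexed by list rank r), each clamped to
    [clamp_min, 1], so v_i = alpha_i·beta_{R_i} lies in [clamp_min², 1].
    """
    scheme = normalize_scheme(scheme)
    n = pairs.n
    if n < 2:
        raise ValueError("need at least two paired genes")
    ranks_lin = np.arange(1, n + 1, dtype=float)
    u = 1.0 - (ranks_lin - 0.5) / n  # linear taper: ~1 at the top rank
    d_s = d_l = None
    if scheme == 0:
        alpha = np.ones(n)
        beta = np.ones(n)
    elif scheme == 1:
        alpha = np.sqrt(u)
        beta = np.sqrt(u)
    elif scheme == 2:
        alpha = np.ones(n)
        beta = u.copy()
    else:
        d_s, d_l = densities if densities is not None else estimate_densities(pairs)
        rel_s = 1.0 - d_s / d_s.max()  # low density (tails) -> weight ~1
        rel_l = 1.0 - d_l / d_l.max()
        beta = np.empty(n)
        if scheme == 7:
            alpha = np.sqrt(rel_s)
            beta[pairs.ranks - 1] = np.sqrt(rel_l)
        else:  # scheme 8
            alpha = np.ones(n)
            beta[pairs.ranks - 1] = rel_l
    alpha = np.clip(alpha, clamp_min, 1.0)
    beta = np.clip(beta, clamp_min, 1.0)
    v = alpha * beta[pairs.ranks - 1]
    return WeightVector(scheme=scheme, v=v, alpha=alpha, beta=beta,
                        d_set=d_s, d_list=d_l)


# ---------------------------------------------------------------------------
# tau statistics
# ---------------------------------------------------------------------------

def _pair_sum(ranks: np.ndarray, v: np.ndarray) -> float:
    """Σ_{i>j} v_i v_j sgn(i−j) sgn(R_i−R_j), vectorized over all pairs."""
    dr = np.sign(ranks[:, None] - ranks[None, :]).astype(float)
    idx = np.arange(ranks.size)
    di = np.sign(idx[:, None] - idx[None, :]).astype(float)
    vv = v[:, None] * v[None, :]
    return float((vv * di * dr).sum() / 2.0)


def _null_variance(v: np.ndarray) -> float:
    """Exact variance of τ_w under a uniform random permutation of R,
    conditional on the weights (reduces to 2(2n+5)/(9n(n−1)) for v ≡ 1)."""
    v = np.asarray(v, dtype=float)
    s1 = v.sum()
    v2 = v * v
    s2 = v2.sum()
    c = 2.0 / (s1 * s1 - s2)
    t1 = 0.5 * (s2 * s2 - (v2 * v2).sum())
    prefix = np.concatenate(([0.0], np.cumsum(v)))[:-1]       # Σ_{i<j} v_i
    prefix2 = np.concatenate(([0.0], np.cumsum(v2)))[:-1]     # Σ_{i<j} v_i²
    suffix = s1 - prefix - v                                   # Σ_{k>j} v_k
    suffix2 = s2 - prefix2 - v2                                # Σ_{k>j} v_k²
    t2 = (np.sum(v * prefix2 * suffix)
          - np.sum(v2 * prefix * suffix)
          + np.sum(v * prefix * suffix2))
    return c * c * (t1 + (2.0 / 3.0) * t2)


def _row_moments(x: np.ndarray) -> tuple[float, float]:
    """For the antisymmetric kernel a_ij = x_i x_j sgn(j−i): return
    A2 = Σ_{i≠j} a_ij² and P = Σ_i (Σ_j a_ij)² − A2."""
    x2 = x * x
    a2 = x2.sum() ** 2 - (x2 * x2).sum()
    prefix = np.concatenate(([0.0], np.cumsum(x)))[:-1]
    rowsum = x * ((x.sum() - prefix - x) - prefix)  # Σ_{j>i}x_j − Σ_{j<i}x_j
    return float(a2), float((rowsum * rowsum).sum() - a2)


def _comoving_null_variance_u(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Exact null variance of U = Σ_{i<j} v_i v_j sgn(i−j) sgn(R_i−R_j) when
    R is a uniform random permutation and the weights co-move with it as
    v_i = alpha_i · beta_{R_i} (generalized-correlation permutation moments).

    For alpha = beta = 1 this reduces to n(n−1)(2n+5)/18, the classical
    Kendall tau-a null variance of U.
    """
    n = alpha.size
    a2, pa = _row_moments(alpha)
    b2, pb = _row_moments(beta)
    var = 0.5 * a2 * b2 / (n * (n - 1.0))
    if n > 2:
        var += pa * pb / (n * (n - 1.0) * (n - 2.0))
    return var


def _two_sided_p(z: float) -> float:
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(max(p, 5e-324), 1.0))


def _check_pairs(pairs: PairedRanks) -> None:
    if not pairs.testable:
        raise ValueError("pairs flagged untestable (overlap below minimum)")
    if pairs.n < 2:
        raise ValueError("need at least two paired genes")


def std_tau(pairs: PairedRanks) -> TauResult:
    """Unweighted Kendall tau-a with the classic normal approximation
    z = 3·sqrt(n(n−1)/(2(2n+5)))·τ."""
    _check_pairs(pairs)
    n = pairs.n
    num = _pair_sum(pairs.ranks, np.ones(n))
    tau = 2.0 * num / (n * (n - 1.0))
    z = 3.0 * np.sqrt(n * (n - 1.0) / (2.0 * (2.0 * n + 5.0))) * tau
    return TauResult(tau=float(tau), z=float(z), p=_two_sided_p(z),
                     direction=int(np.sign(tau)), n_overlap=n, scheme=0)


def weighted_tau(pairs: PairedRanks, weights: WeightVector) -> TauResult:
    """Weighted Kendall tau with an exact permutation-null variance z-score.

    When the weight vector carries its set/list factors (all built-in
    schemes), the null variance accounts for the weights co-moving with the
    permuted list ranks; a bare weight vector is treated as fixed under
    permutation.
    """
    _check_pairs(pairs)
    v = np.asarray(weights.v, dtype=float)
    if v.shape != (pairs.n,):
        raise ValueError("weight vector length mismatch")
    if np.count_nonzero(v > 0) < 2:
        raise ValueError("need at least two positive weights")
    s1 = v.sum()
    s2 = (v * v).sum()
    u = _pair_sum(pairs.ranks, v)
    tau = 2.0 * u / (s1 * s1 - s2)
    if weights.alpha is not None and weights.beta is not None:
        var_u = _comoving_null_variance_u(weights.alpha, weights.beta)
        z = u / np.sqrt(var_u) if var_u > 0 else 0.0
    else:
        var = _null_variance(v)
        z = tau / np.sqrt(var) if var > 0 else 0.0
    return TauResult(tau=float(tau), z=float(z), p=_two_sided_p(z),
                     direction=int(np.sign(tau)), n_overlap=pairs.n,
                     scheme=weights.scheme)


def permutation_p(pairs: PairedRanks, weights: WeightVector,
                  n_perm: int = 999, seed: int = 0) -> float:
    """Two-sided permutation p-value, p = (1 + #{|τ_w*| ≥ |τ_w|}) / (B + 1).

    R is permuted uniformly; when the weight vector carries its set/list
    factors the weights co-move with the permuted ranks (matching the
    asymptotic null of :func:`weighted_tau`), otherwise they stay fixed.
    """
    _check_pairs(pairs)
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    comove = weights.alpha is not None and weights.beta is not None

    def _tau_abs(ranks: np.ndarray) -> float:
        if comove:
            v = weights.alpha * weights.beta[ranks - 1]
        else:
            v = np.asarray(weights.v, dtype=float)
        denom = v.sum() ** 2 - (v * v).sum()
        return abs(2.0 * _pair_sum(ranks, v) / denom)

    observed = _tau_abs(pairs.ranks)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        t = _tau_abs(rng.permutation(pairs.ranks))
        if t >= observed - 1e-12:
            hits += 1
    return (1.0 + hits) / (n_perm + 1.0)


def association_test(pairs: PairedRanks, scheme=0,
                     densities: tuple[np.ndarray, np.ndarray] | None = None,
                     null: str = "asymptotic", n_perm: int = 999,
                     seed: int = 0) -> TauResult:
    """One-stop test: build weights for ``scheme``, compute τ_w, z and p.

    ``null="permutation"`` replaces the asymptotic p by the permutation
    reference null (the z and tau are unchanged).
    """
    scheme = normalize_scheme(scheme)
    if scheme == 0:
        res = std_tau(pairs)
        weights = None
    else:
        weights = make_weights(pairs, scheme, densities=densities)
        res = weighted_tau(pairs, weights)
    if null == "permutation":
        if weights is None:
            weights = make_weights(pairs, 0)
        p = permutation_p(pairs, weights, n_perm=n_perm, seed=seed)
        res = TauResult(tau=res.tau, z=res.z, p=p, direction=res.direction,
                        n_overlap=res.n_overlap, scheme=scheme,
                        null="permutation")
    elif null != "asymptotic":
        raise ValueError("null must be 'asymptotic' or 'permutation'")
    return res
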