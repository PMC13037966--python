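"""Per-group gene-pair correlation statistics and S / NS / NA / EXCLUDED calls.

For every unordered gene pair within one treatment group the pipeline computes
the Pearson correlation r, its two-sided parametric P value (t distribution,
n - 2 df), and — for candidate significant pairs — a permutation-based
empirical P value: the fraction of permuted-pairing P values falling strictly
below the observed one.

Labels follow a banding scheme designed for very small n:

* ``NA``       — at least one gene is all-zero across the group's replicates;
  the relationship is unevaluable rather than absent.
* ``S``        — parametric P < p_sig AND empirical P < p_emp_sig AND at least
  ``min_distinct_points`` distinct (x, y) tuples.
* ``NS``       — parametric P > p_nonsig (with enough distinct points).
* ``EXCLUDED`` — everything else: the intermediate P band, a failed empirical
  confirmation, too few distinct points, or an undefined correlation
  (constant but not all-zero vector).

With the defaults (p_sig = p_emp_sig = 0.005, 200 permutations) the empirical
gate is equivalent to requiring that *zero* permuted P values beat the
observed one. r itself is never used as a selection criterion at these sample
sizes; only its sign is stored, for interpretation.

Numerical note: the identity permutation is analytically *tied* with the
observed statistic, so under the strict ``<`` rule it must never count as a
beat. Observed and permuted P values are therefore computed through the same
floating-point path (elementwise dot products, no BLAS matmul), and the
comparison additionally carries a 1e-9 relative guard so that a caller-
supplied ``p_obs`` computed by any other correct method (e.g. the beta-form
used by ``scipy.stats.pearsonr``) cannot turn the tie into a one-ulp beat.
Genuinely distinct orderings of continuous data are separated by far more
than the guard.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy import stats

from ._util import stable_seed
from .expression_data import GroupMatrix

LABEL_S = "S"
LABEL_NS = "NS"
LABEL_NA = "NA"
LABEL_EXCLUDED = "EXCLUDED"
LABELS = (LABEL_S, LABEL_NS, LABEL_NA, LABEL_EXCLUDED)

#: columns of the pair-statistics table emitted by :func:`classify_group`
PAIR_COLUMNS = [
    "gene_a",
    "gene_b",
    "r",
    "p",
    "emp_p",
    "n_valid",
    "n_distinct",
    "label",
    "r_sign",
]

_MAX_EXACT_N = 8  # 8! = 40320 orderings; beyond that exact enumeration is pointless
_TIE_GUARD = 1e-9  # relative slack shielding the strict "<" from float ties


@dataclass(frozen=True)
class Thresholds:
    """Significance banding for pair classification.

    p_sig and p_emp_sig gate the "correlated" call (both strict <), p_nonsig
    gates the "uncorrelated" call (strict >); the band in between is excluded
    to keep the two categories well separated.
    """

    p_sig: float = 0.005
    p_emp_sig: float = 0.005
    p_nonsig: float = 0.05
    n_perm: int = 200
    min_distinct_points: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.p_sig <= self.p_nonsig < 1):
            raise ValueError("need 0 < p_sig <= p_nonsig < 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.min_distinct_points < 1:
            raise ValueError("min_distinct_points must be >= 1")


@dataclass(frozen=True)
class PairStats:
    """Statistics and label for one gene pair in one treatment group.

    Undefined quantities (all-zero or constant vectors, labels where the
    empirical P was never needed) are NaN.
    """

    gene_a: str
    gene_b: str
    r: float
    p: float
    emp_p: float
    n_valid: int
    n_distinct: int
    label: str
    r_sign: str  # "+", "-", or ""


def pearson_p_from_r(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided P for a Pearson correlation of ``r`` at sample size ``n``,
    from the t distribution with n - 2 degrees of freedom."""
    r_arr = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.maximum(1.0 - r_arr * r_arr, 0.0)
        t = np.abs(r_arr) * np.sqrt(df / np.where(denom > 0, denom, np.inf))
        t = np.where(denom > 0, t, np.inf)
    p = 2.0 * stats.t.sf(t, df)
    p = np.where(np.isnan(r_arr), np.nan, np.minimum(p, 1.0))
    return float(p) if np.isscalar(r) or np.ndim(r) == 0 else p


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and its two-sided parametric P.

    Returns (nan, nan) for a constant vector — the caller maps that to
    NA/EXCLUDED according to the classification rules. Length mismatch is a
    hard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    r = _corr_obs(x, y)
    if math.isnan(r):
        return (math.nan, math.nan)
    return (r, float(pearson_p_from_r(r, x.size)))


def _corr_obs(x: np.ndarray, y: np.ndarray) -> float:
    """Observed correlation via the exact code path used for permutations."""
    xc = x - x.mean()
    xn = float(np.sqrt((xc * xc).sum()))
    yc = y - y.mean()
    yn = float(np.sqrt((yc * yc).sum()))
    if xn == 0.0 or yn == 0.0:
        return math.nan
    return float(np.clip((yc * xc).sum() / (xn * yn), -1.0, 1.0))


def _perm_p_values(x: np.ndarray, y: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Parametric P of x against each row-permutation of y.

    Permutations yielding an (impossible via pure reordering, but guarded)
    undefined correlation contribute P = 1, a conservative convention.
    """
    n = x.size
    xc = x - x.mean()
    xn = np.sqrt((xc * xc).sum())
    Y = y[perms]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    yn = np.sqrt((Yc * Yc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc * xc).sum(axis=1) / (xn * yn)
    p = np.asarray(pearson_p_from_r(r, n))
    return np.where(np.isfinite(r), p, 1.0)


def _all_orderings(n: int) -> np.ndarray:
    if n > _MAX_EXACT_N:
        raise ValueError(f"exact enumeration limited to n <= {_MAX_EXACT_N}, got {n}")
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def empirical_p(
    x: np.ndarray,
    y: np.ndarray,
    p_obs: float,
    n_perm: int = 200,
    seed: int | None = None,
    exact: bool = False,
) -> float:
    """Permutation empirical P: fraction of permuted Pi strictly below p_obs.

    Each permutation independently re-orders one gene's replicate vector
    relative to the other (equivalent to shuffling that gene's sample labels).
    ``exact=True`` enumerates all n! relative orderings instead of sampling
    n_perm of them with replacement; at n = 5 that is 120 orderings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if not math.isfinite(p_obs):
        raise ValueError("p_obs must be defined to compute an empirical P")
    n = x.size
    if exact:
        perms = _all_orderings(n)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)], dtype=np.intp)
    pi = _perm_p_values(x, y, perms)
    return float(np.count_nonzero(pi < p_obs * (1.0 - _TIE_GUARD)) / len(perms))


def _n_distinct(x: np.ndarray, y: np.ndarray) -> int:
    """Number of distinct (x_i, y_i) value tuples across replicates."""
    return len(set(zip(x.tolist(), y.tolist())))


def pair_seed(seed: int, gene_a: str, gene_b: str) -> int:
    """Reproducible per-pair permutation seed, symmetric in the gene order."""
    a, b = sorted((str(gene_a), str(gene_b)))
    return stable_seed("perm", seed, a, b)


def classify_pair(
    group: GroupMatrix,
    gene_a: str,
    gene_b: str,
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
    exact: bool = False,
) -> PairStats:
    """Classify one gene pair within one treatment group.

    Evaluation order: NA test, then distinct-points test, then parametric-P
    banding, and only for candidates in the significant band the empirical-P
    confirmation (it cannot change any other label).
    """
    df = group.values
    for g in (gene_a, gene_b):
        if g not in df.index:
            raise KeyError(f"gene {g!r} not present in group {group.key}")
    x = df.loc[gene_a].to_numpy(dtype=float)
    y = df.loc[gene_b].to_numpy(dtype=float)
    n = x.size
    n_valid = int(np.count_nonzero((x != 0) | (y != 0)))
    base = PairStats(
        gene_a=str(gene_a),
        gene_b=str(gene_b),
        r=math.nan,
        p=math.nan,
        emp_p=math.nan,
        n_valid=n_valid,
        n_distinct=_n_distinct(x, y),
        label=LABEL_EXCLUDED,
        r_sign="",
    )
    if not x.any() or not y.any():
        return replace(base, label=LABEL_NA)
    r = _corr_obs(x, y)
    if math.isnan(r):  # constant but not all-zero vector
        return base
    p = float(pearson_p_from_r(r, n))
    sign = "+" if r > 0 else ("-" if r < 0 else "")
    base = replace(base, r=r, p=p, r_sign=sign)
    if base.n_distinct < thresholds.min_distinct_points:
        return base
    if p > thresholds.p_nonsig:
        return replace(base, label=LABEL_NS)
    if p < thresholds.p_sig:
        emp = empirical_p(
            x,
            y,
            p,
            n_perm=thresholds.n_perm,
            seed=pair_seed(seed, gene_a, gene_b),
            exact=exact,
        )
        label = LABEL_S if emp < thresholds.p_emp_sig else LABEL_EXCLUDED
        return replace(base, emp_p=emp, label=label)
    return base  # intermediate band


def _matrix_scheme_emp(
    X: np.ndarray,
    cand_a: np.ndarray,
    cand_b: np.ndarray,
    p_obs: np.ndarray,
    thresholds: Thresholds,
    seed: int,
) -> np.ndarray:
    """Empirical P under the matrix-wide scheme: per round, every gene's
    replicate labels are shuffled once and shared by all pairs."""
    n = X.shape[1]
    genes_needed = np.unique(np.concatenate([cand_a, cand_b]))
    beats = np.zeros(cand_a.size)
    for t in range(thresholds.n_perm):
        perm_of = {
            g: np.random.default_rng(stable_seed("matrix-perm", seed, t, int(g))).permutation(n)
            for g in genes_needed
        }
        for k in range(cand_a.size):
            xa = X[cand_a[k]][perm_of[cand_a[k]]]
            xb = X[cand_b[k]][perm_of[cand_b[k]]]
            pi = _perm_p_values(xa, xb, np.arange(n, dtype=np.intp)[None, :])[0]
            beats[k] += pi < p_obs[k]
    return beats / thresholds.n_perm


def classify_group(
    group: GroupMatrix,
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
    exact: bool = False,
    log_transform: bool = False,
    perm_scheme: Literal["pair", "matrix"] = "pair",
) -> pd.DataFrame:
    """Classify all C(n_genes, 2) unordered pairs of one group.

    Returns a DataFrame with :data:`PAIR_COLUMNS`, one row per pair in the
    deterministic order of ``itertools.combinations`` over the matrix's gene
    order. Permutation draws come from per-pair seeds derived from ``seed``
    and the gene ids, so results are independent of evaluation order.

    ``perm_scheme="matrix"`` switches to a shared per-round shuffle of each
    gene's replicate labels (one shuffle per gene per round, reused by all
    pairs) instead of independent per-pair draws.
    """
    if group.n_replicates < 3:
        raise ValueError("group must have at least 3 replicates")
    genes = group.gene_ids
    X = group.values.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    G, n = X.shape
    ia, ib = np.triu_indices(G, k=1)

    zero_gene = ~X.any(axis=1)
    sd = X.std(axis=1)
    const_gene = sd == 0

    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc * Xc).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc @ Xc.T) / np.outer(safe, safe)
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)

    r_pair = R[ia, ib]
    undef = const_gene[ia] | const_gene[ib]
    r_pair = np.where(undef, np.nan, r_pair)
    p_pair = np.asarray(pearson_p_from_r(r_pair, n))

    # both-zero replicate counts via one boolean matmul
    Z = (X == 0).astype(np.int32)
    both_zero = Z @ Z.T
    n_valid = (n - both_zero[ia, ib]).astype(int)

    # distinct (x, y) tuples: only pairs where *both* genes have internal
    # duplicate values can fall below n
    has_dup = np.array([len(np.unique(row)) < n for row in X])
    n_distinct = np.full(ia.size, n, dtype=int)
    slow = np.nonzero(has_dup[ia] & has_dup[ib])[0]
    for k in slow:
        n_distinct[k] = _n_distinct(X[ia[k]], X[ib[k]])

    na_mask = zero_gene[ia] | zero_gene[ib]
    enough = n_distinct >= thresholds.min_distinct_points
    defined = ~na_mask & ~undef
    ns_mask = defined & enough & (p_pair > thresholds.p_nonsig)
    cand = np.nonzero(defined & enough & (p_pair < thresholds.p_sig))[0]

    emp = np.full(ia.size, np.nan)
    if cand.size:
        # recompute the observed P through the permutation code path so the
        # strict "<" comparison is float-consistent (see module docstring)
        p_obs_cand = np.empty(cand.size)
        for j, k in enumerate(cand):
            p_obs_cand[j] = _perm_p_values(
                X[ia[k]], X[ib[k]], np.arange(n, dtype=np.intp)[None, :]
            )[0]
        if perm_scheme == "matrix":
            emp[cand] = _matrix_scheme_emp(
                X, ia[cand], ib[cand], p_obs_cand, thresholds, seed
            )
        else:
            for j, k in enumerate(cand):
                emp[k] = empirical_p(
                    X[ia[k]],
                    X[ib[k]],
                    p_obs_cand[j],
                    n_perm=thresholds.n_perm,
                    seed=pair_seed(seed, genes[ia[k]], genes[ib[k]]),
                    exact=exact,
                )

    label = np.full(ia.size, LABEL_EXCLUDED, dtype=object)
    label[ns_mask] = LABEL_NS
    s_mask = np.zeros(ia.size, dtype=bool)
    s_mask[cand] = emp[cand] < thresholds.p_emp_sig
    label[s_mask] = LABEL_S
    label[na_mask] = LABEL_NA

    r_out = np.where(na_mask, np.nan, r_pair)
    p_out = np.where(na_mask, np.nan, p_pair)
    sign = np.where(
        np.isnan(r_out), "", np.where(r_out > 0, "+", np.where(r_out < 0, "-", ""))
    )
    gene_arr = np.array(genes, dtype=object)
    return pd.DataFrame(
        {
            "gene_a": gene_arr[ia],
            "gene_b": gene_arr[ib],
            "r": r_out,
            "p": p_out,
            "emp_p": emp,
            "n_valid": n_valid,
            "n_distinct": n_distinct,
            "label": label,
            "r_sign": sign,
        }
    )
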