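"""Permutation inference for behavioral-cluster analyses.

All p-values follow the add-one resampling convention
``p = (b + 1) / (m + 1)`` where ``b`` counts permutation statistics at least
as extreme as the observed one, so the resolution floor at the default
``m = 10,000`` resamples is 1/10001, which prints as 0.0001. Resampling is
without replacement (label permutation / sign flips), seeded, and therefore
exactly reproducible.

Provided tests:

* strain x sex **representation tests** — is a group over- or
  under-represented in a cluster, against cluster-label-shuffled nulls,
  BH-FDR corrected across cells;
* per-fish **overlap scores** — the number of unordered pairs of exposures a
  fish spent in the same cluster — and their permutation null built by
  shuffling every exposure's labels except the first across fish;
* two-day percent overlap with its permutation average;
* permutation t-tests (paired sign-flips / unpaired label shuffles);
* between-subject and mixed (between x within) permutation ANOVAs;
* Benjamini–Hochberg FDR adjustment and Spearman correlations with
  percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "perm_p",
    "fdr_adjust",
    "overlap_score",
    "overlap_test",
    "two_day_overlap",
    "representation_test",
    "perm_t_test",
    "perm_anova",
    "spearman_ci",
]

DEFAULT_M = 10_000


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the resampling p-value."""

    observed: float
    null_sample: np.ndarray
    m: int
    p: float
    seed: int | None = None
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.null_sample = np.asarray(self.null_sample, dtype=float)
        if self.null_sample.size != self.m:
            raise ValueError("null_sample length must equal m")
        if not (0 < self.p <= 1):
            raise ValueError("p must be in (0, 1]")


def perm_p(observed: float, null_sample, alternative: str = "greater") -> float:
    """Add-one permutation p-value.

    ``greater``/``less`` count null values at least as extreme in the stated
    direction; ``two_sided`` doubles the smaller tail, capped at 1. Never
    returns 0: the floor is ``1/(m+1)``.
    """
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    null = np.asarray(null_sample, dtype=float)
    if null.size == 0:
        raise ValueError("null_sample must be nonempty")
    m = null.size
    p_hi = (np.sum(null >= observed) + 1) / (m + 1)
    p_lo = (np.sum(null <= observed) + 1) / (m + 1)
    if alternative == "greater":
        return float(p_hi)
    if alternative == "less":
        return float(p_lo)
    if alternative == "two_sided":
        return float(min(1.0, 2.0 * min(p_hi, p_lo)))
    raise ValueError(f"unknown alternative {alternative!r}")


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# overlap scores: longitudinal cluster consistency
# ---------------------------------------------------------------------------


def overlap_score(assignments) -> int:
    """Number of unordered pairs of exposures with the same cluster label.

    For 5 exposures the score spans 1..10 once any pair matches (10 = all
    pairs agree); for 6 exposures the pigeonhole bound with four clusters
    forces at least 2, with a maximum of 15.
    """
    labels = list(assignments)
    if len(labels) < 2:
        raise ValueError("need >= 2 exposures")
    if any(pd.isna(v) for v in labels):
        raise ValueError("missing cluster label")
    return sum(a == b for a, b in combinations(labels, 2))


def _mean_overlap(matrix: np.ndarray) -> float:
    """Mean per-fish overlap score of an (n_fish, n_exposures) label matrix."""
    t = matrix.shape[1]
    total = 0.0
    for a, b in combinations(range(t), 2):
        total += np.mean(matrix[:, a] == matrix[:, b])
    return float(total)


def overlap_test(
    assignment_matrix, m: int = DEFAULT_M, seed: int = 0
) -> PermutationResult:
    """Is mean longitudinal cluster consistency greater than chance?

    Observed statistic: the cohort-mean per-fish overlap score. The null
    permutes each exposure's labels across fish independently, for every
    exposure except the first, mirroring resampling "for all days/weeks
    except the first".
    """
    mat = np.asarray(assignment_matrix)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("assignment matrix must be (n_fish, >=2 exposures)")
    if mat.shape[0] < 2:
        raise ValueError("need more than one fish to permute")
    rng = np.random.default_rng(seed)
    # encode labels as small ints for fast comparison
    _, codes = np.unique(mat, return_inverse=True)
    mat = codes.reshape(mat.shape)
    observed = _mean_overlap(mat)
    null = np.empty(m)
    work = mat.copy()
    for r in range(m):
        for col in range(1, mat.shape[1]):
            work[:, col] = rng.permutation(mat[:, col])
        null[r] = _mean_overlap(work)
    p = perm_p(observed, null, "greater")
    return PermutationResult(observed=observed, null_sample=null, m=m, p=p, seed=seed)


def two_day_overlap(
    labels_day1, labels_day2, m: int = DEFAULT_M, seed: int = 0
) -> tuple[float, PermutationResult]:
    """Percent of fish in the same cluster on two exposures, with its null.

    The null permutes the second day's labels across fish; the null mean is
    the "permutation average" percent overlap. Returns
    ``(percent_overlap, PermutationResult)``; the result's ``extra`` carries
    ``null_mean_percent``.
    """
    l1 = np.asarray(labels_day1)
    l2 = np.asarray(labels_day2)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("label vectors must be 1-D with equal lengths")
    rng = np.random.default_rng(seed)
    observed = 100.0 * np.mean(l1 == l2)
    null = np.empty(m)
    for r in range(m):
        null[r] = 100.0 * np.mean(l1 == rng.permutation(l2))
    p = perm_p(observed, null, "greater")
    res = PermutationResult(
        observed=observed,
        null_sample=null,
        m=m,
        p=p,
        seed=seed,
        extra={"null_mean_percent": float(null.mean())},
    )
    return float(observed), res


# ---------------------------------------------------------------------------
# representation tests: strain x sex composition of clusters
# ---------------------------------------------------------------------------


def representation_test(
    groups,
    clusters,
    m: int = DEFAULT_M,
    seed: int = 0,
    two_sided: str = "double",
) -> pd.DataFrame:
    """Over/under-representation of each group in each cluster.

    ``groups`` holds one group key per fish (e.g. ``"TL:F"`` or a tuple) and
    ``clusters`` the fish's cluster label. The null shuffles the cluster
    vector over all fish, keeping group memberships fixed, and counts how
    many animals of each group fall into each cluster. Per-cell two-sided
    p-values (``double``: twice the smaller tail; ``abs``: tail of
    ``|count - expected|``) are BH-FDR adjusted across all cells.

    Returns a tidy frame: group, cluster, count, expected, direction,
    p, p_adjusted.
    """
    g = pd.Series(list(groups))
    c = pd.Series(list(clusters))
    if len(g) != len(c) or len(g) == 0:
        raise ValueError("groups and clusters must be equal-length and nonempty")
    if two_sided not in ("double", "abs"):
        raise ValueError("two_sided must be 'double' or 'abs'")
    g_codes, g_levels = pd.factorize(g, sort=True)
    c_codes, c_levels = pd.factorize(c, sort=True)
    G, C = len(g_levels), len(c_levels)
    n = len(g)
    rng = np.random.default_rng(seed)

    obs = np.bincount(g_codes * C + c_codes, minlength=G * C).reshape(G, C)
    null = np.empty((m, G, C), dtype=np.int32)
    for r in range(m):
        perm = rng.permutation(c_codes)
        null[r] = np.bincount(g_codes * C + perm, minlength=G * C).reshape(G, C)

    expected = null.mean(axis=0)
    ge = (null >= obs).sum(axis=0)
    le = (null <= obs).sum(axis=0)
    p_hi = (ge + 1) / (m + 1)
    p_lo = (le + 1) / (m + 1)
    if two_sided == "double":
        p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    else:
        dev = np.abs(null - expected[None])
        b = (dev >= np.abs(obs - expected)[None]).sum(axis=0)
        p = (b + 1) / (m + 1)

    rows = []
    for gi in range(G):
        for ci in range(C):
            rows.append(
                {
                    "group": g_levels[gi],
                    "cluster": c_levels[ci],
                    "count": int(obs[gi, ci]),
                    "expected": float(expected[gi, ci]),
                    "direction": "over" if obs[gi, ci] >= expected[gi, ci] else "under",
                    "p": float(p[gi, ci]),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = fdr_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# permutation t-tests
# ---------------------------------------------------------------------------


def _t_unpaired(x1: np.ndarray, x2: np.ndarray) -> float:
    return float(stats.ttest_ind(x1, x2, equal_var=True).statistic)


def perm_t_test(
    x, y, paired: bool = False, m: int = DEFAULT_M, seed: int = 0
) -> PermutationResult:
    """Two-sided permutation t-test.

    The statistic is the classical t. Paired data use random sign flips of
    the within-pair differences; unpaired data shuffle the pooled group
    memberships. p counts ``|t_null| >= |t_obs|`` with the add-one rule
    (the permutation null of t is symmetric about zero, so this matches the
    doubled-tail convention in distribution).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
        n = d.size
        if n < 2:
            raise ValueError("need >= 2 pairs")
        sd = d.std(ddof=1)
        if sd == 0:
            # identical vectors: t undefined; any permutation is as extreme
            null = np.zeros(m)
            return PermutationResult(observed=0.0, null_sample=null, m=m, p=1.0, seed=seed)
        observed = float(d.mean() / (sd / np.sqrt(n)))
        signs = rng.choice((-1.0, 1.0), size=(m, n))
        ds = signs * d
        mu = ds.mean(axis=1)
        s = ds.std(ddof=1, axis=1)
        null = np.where(s > 0, mu / (s / np.sqrt(n)), 0.0)
    else:
        n1, n2 = x.size, y.size
        if min(n1, n2) < 2:
            raise ValueError("need >= 2 observations per group")
        observed = _t_unpaired(x, y)
        pooled = np.concatenate([x, y])
        perms = rng.permuted(np.tile(pooled, (m, 1)), axis=1)
        a, b = perms[:, :n1], perms[:, n1:]
        va = a.var(ddof=1, axis=1)
        vb = b.var(ddof=1, axis=1)
        sp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
        denom = sp * np.sqrt(1 / n1 + 1 / n2)
        null = np.where(denom > 0, (a.mean(axis=1) - b.mean(axis=1)) / denom, 0.0)
    p = perm_p(abs(observed), np.abs(null), "greater")
    return PermutationResult(observed=observed, null_sample=null, m=m, p=p, seed=seed)


# ---------------------------------------------------------------------------
# permutation ANOVAs
# ---------------------------------------------------------------------------


def _design(factors: list[np.ndarray], interactions: bool, n: int) -> np.ndarray:
    """Dummy-coded design matrix with intercept (and optional full interaction)."""
    cols = [np.ones((n, 1))]
    mains = []
    for f in factors:
        d = pd.get_dummies(pd.Series(f), drop_first=True).to_numpy(dtype=float)
        mains.append(d)
        cols.append(d)
    if interactions and len(mains) == 2:
        a, b = mains
        inter = (a[:, :, None] * b[:, None, :]).reshape(n, -1)
        cols.append(inter)
    return np.hstack(cols)


def _rss_operator(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis Q of X; RSS(y) = y'y - ||Q'y||^2."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _batch_rss(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """RSS of each row of Y (batch of responses) under the basis Q."""
    tot = np.einsum("ij,ij->i", Y, Y)
    proj = Y @ Q
    return tot - np.einsum("ij,ij->i", proj, proj)


def _between_anova(
    y: np.ndarray, fa: np.ndarray, fb: np.ndarray, m: int, rng: np.random.Generator
) -> dict[str, PermutationResult]:
    n = y.size
    la, lb = np.unique(fa), np.unique(fb)
    dfa, dfb = la.size - 1, lb.size - 1
    dfab = dfa * dfb
    Q_a = _rss_operator(_design([fa], False, n))
    Q_b = _rss_operator(_design([fb], False, n))
    Q_ab = _rss_operator(_design([fa, fb], False, n))
    Q_full = _rss_operator(_design([fa, fb], True, n))
    df_res = n - Q_full.shape[1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom; design has empty or singleton cells")

    def f_stats(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rss_full = _batch_rss(Q_full, Y)
        rss_ab = _batch_rss(Q_ab, Y)
        mse = rss_full / df_res
        f_a = (_batch_rss(Q_b, Y) - rss_ab) / dfa / mse
        f_b = (_batch_rss(Q_a, Y) - rss_ab) / dfb / mse
        f_i = (rss_ab - rss_full) / dfab / mse
        return f_a, f_b, f_i

    obs_a, obs_b, obs_i = (float(v[0]) for v in f_stats(y[None, :]))

    # main effects: unrestricted permutation of the response
    Yperm = rng.permuted(np.tile(y, (m, 1)), axis=1)
    null_a, null_b, _ = f_stats(Yperm)

    # interaction: Freedman–Lane — permute residuals of the main-effects model
    proj = Q_ab @ (Q_ab.T @ y)
    resid = y - proj
    Rperm = rng.permuted(np.tile(resid, (m, 1)), axis=1)
    Ystar = proj[None, :] + Rperm
    _, _, null_i = f_stats(Ystar)

    out = {}
    for name, obs, null in (
        ("factor_a", obs_a, null_a),
        ("factor_b", obs_b, null_b),
        ("interaction", obs_i, null_i),
    ):
        out[name] = PermutationResult(
            observed=obs, null_sample=null, m=m, p=perm_p(obs, null, "greater")
        )
    return out


def _mixed_f_batch(
    Y: np.ndarray, g_codes: np.ndarray, G: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """F statistics of a two-way mixed ANOVA for a batch of response matrices.

    ``Y`` is (batch, subjects, levels). Between effect tested against
    subjects-within-groups; within effect and interaction against the
    subject x level residual. Exact for balanced group sizes; the
    unweighted-means approximation otherwise.
    """
    B, n, t = Y.shape
    n_g = np.bincount(g_codes, minlength=G).astype(float)
    gm = Y.mean(axis=(1, 2))
    subj = Y.mean(axis=2)  # (B, n)
    col = Y.mean(axis=1)  # (B, t)
    group_mean = np.stack(
        [subj[:, g_codes == gi].mean(axis=1) for gi in range(G)], axis=1
    )  # (B, G)
    cell = np.stack([Y[:, g_codes == gi, :].mean(axis=1) for gi in range(G)], axis=1)

    ss_a = t * np.einsum("g,bg->b", n_g, (group_mean - gm[:, None]) ** 2)
    ss_s = t * ((subj - group_mean[:, g_codes]) ** 2).sum(axis=1)
    ss_b = n * ((col - gm[:, None]) ** 2).sum(axis=1)
    dev = cell - group_mean[:, :, None] - col[:, None, :] + gm[:, None, None]
    ss_ab = np.einsum("g,bgt->b", n_g, dev**2)
    resid = Y - subj[:, :, None] - cell[:, g_codes, :] + group_mean[:, g_codes, None]
    ss_err = (resid**2).sum(axis=(1, 2))

    df_a, df_s = G - 1, n - G
    df_b = t - 1
    df_ab = df_a * df_b
    df_err = df_s * df_b
    eps = np.finfo(float).tiny
    f_a = (ss_a / df_a) / np.maximum(ss_s / df_s, eps)
    f_b = (ss_b / df_b) / np.maximum(ss_err / df_err, eps)
    f_ab = (ss_ab / df_ab) / np.maximum(ss_err / df_err, eps)
    return f_a, f_b, f_ab


def _mixed_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
    m: int,
    rng: np.random.Generator,
) -> dict[str, PermutationResult]:
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("missing within-subject cells; mixed design must be complete")
    subj_group = data.groupby(subject)[between].first().loc[wide.index]
    g_codes, g_levels = pd.factorize(subj_group, sort=True)
    G = len(g_levels)
    if G < 2:
        raise ValueError("between factor needs >= 2 levels")
    Y = wide.to_numpy(dtype=float)
    n, t = Y.shape

    obs_a, obs_b, obs_ab = (float(v[0]) for v in _mixed_f_batch(Y[None], g_codes, G))

    # between: exchanging group labels across subjects is equivalent to
    # permuting the subject rows of Y against the fixed labels
    perms = np.stack([rng.permutation(n) for _ in range(m)])
    null_a = _mixed_f_batch(Y[perms], g_codes, G)[0]
    # within: shuffle each subject's level order independently
    Yw = rng.permuted(np.broadcast_to(Y, (m, n, t)).copy(), axis=2)
    null_b = _mixed_f_batch(Yw, g_codes, G)[1]
    # interaction: permute the double-centered residuals (rows across
    # subjects, columns within rows), re-adding both main-effect layers
    subj_mean = Y.mean(axis=1)
    col_mean = Y.mean(axis=0)
    resid = Y - subj_mean[:, None] - col_mean[None, :] + Y.mean()
    base = subj_mean[:, None] + col_mean[None, :] - Y.mean()
    rperms = np.stack([rng.permutation(n) for _ in range(m)])
    Rp = rng.permuted(resid[rperms], axis=2)
    null_ab = _mixed_f_batch(base[None] + Rp, g_codes, G)[2]

    out = {}
    for name, obs, null in (
        (between, obs_a, null_a),
        (within, obs_b, null_b),
        (f"{between}:{within}", obs_ab, null_ab),
    ):
        out[name] = PermutationResult(
            observed=obs, null_sample=null, m=m, p=perm_p(obs, null, "greater")
        )
    return out


def perm_anova(
    data: pd.DataFrame,
    dv: str,
    between=None,
    within: str | None = None,
    subject: str | None = None,
    m: int = DEFAULT_M,
    seed: int = 0,
) -> dict[str, PermutationResult]:
    """Permutation ANOVA for the study's two designs.

    * two between factors (e.g. 4x2 strain x sex): F statistics from the
      least-squares decomposition; main effects tested by unrestricted
      permutation of the response, the interaction by Freedman–Lane
      permutation of main-effects-model residuals;
    * one between + one within factor (e.g. 2x6 sex x time interval mixed
      design, ``subject`` required): between effect by permuting subject
      group labels, within effect by shuffling each subject's level order,
      interaction by permuting double-centered residuals.

    Returns a dict effect-name -> PermutationResult. FDR across effects or
    across families is the caller's choice via :func:`fdr_adjust`.
    """
    rng = np.random.default_rng(seed)
    between = list(between) if between is not None else []
    if dv not in data.columns:
        raise ValueError(f"missing dv column {dv!r}")
    y = data[dv].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if within is None:
        if len(between) != 2:
            raise ValueError("between-only design needs exactly two factors")
        fa = data[between[0]].to_numpy()
        fb = data[between[1]].to_numpy()
        cells = pd.crosstab(fa, fb)
        if (cells == 0).any().any():
            raise ValueError("empty cells in the between design")
        res = _between_anova(y, fa, fb, m, rng)
        renamed = {
            between[0]: res["factor_a"],
            between[1]: res["factor_b"],
            f"{between[0]}:{between[1]}": res["interaction"],
        }
        for r, s in zip(renamed.values(), (seed, seed, seed)):
            r.seed = s
        return renamed
    if len(between) != 1 or subject is None:
        raise ValueError("mixed design needs exactly one between factor and a subject column")
    res = _mixed_anova(data, dv, between[0], within, subject, m, rng)
    for r in res.values():
        r.seed = seed
    return res


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------


def spearman_ci(
    x, y, n_boot: int = DEFAULT_M, seed: int = 0, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Spearman's rho with a percentile-bootstrap confidence interval.

    Pairs are resampled with replacement ``n_boot`` times; the CI is the
    percentile interval of the bootstrap rho distribution. Degenerate
    resamples (constant ranks) are dropped from the percentile computation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("need equal-length 1-D samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; Spearman's rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    rx = stats.rankdata(x[idx], axis=1)
    ry = stats.rankdata(y[idx], axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boots = (rx * ry).sum(axis=1) / denom
    boots = boots[np.isfinite(boots)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return rho, (float(lo), float(hi))
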