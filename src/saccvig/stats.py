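"""Inferential machinery for the repeated-measures design.

* :func:`rm_anova` — full-factorial repeated-measures ANOVA on a
  participant × cell means table, fitted as a balanced random-intercept
  linear mixed model with pooled within-subject error.  Wald F tests use
  the residual denominator-df convention (rows − fixed-effect
  parameters), so a 26-participant 2×2×2 table (208 rows, 8 parameters)
  reports df (1, 200) and a 29-participant 2×2 table reports (1, 112).
* :func:`cluster_permutation` — cluster-wise sign-flip permutation test
  for 1-D traces and 2-D time×time matrices, controlling family-wise
  error at the cluster level.
* :func:`within_subject_sem` — Cousineau-centred, Morey-corrected SEM
  for repeated-measures error bars.
* :func:`spearman` — rank correlation with exact small-sample p.
* :func:`sensitivity_mdes` — minimal detectable effect size (Cohen's
  d_z) from the noncentral-t power function.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy import stats as sps

__all__ = [
    "rm_anova",
    "cluster_permutation",
    "within_subject_sem",
    "spearman",
    "sensitivity_mdes",
    "Cluster",
    "ClusterTestResult",
]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA on cell means

def _sum_code(levels: np.ndarray) -> np.ndarray:
    """Deviation (sum-to-zero) coding: k levels → k−1 columns."""
    uniq = np.unique(levels)
    k = len(uniq)
    cols = np.zeros((len(levels), k - 1))
    for j, lev in enumerate(uniq[:-1]):
        cols[levels == lev, j] = 1.0
    cols[levels == uniq[-1], :] = -1.0
    return cols


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "participant_id",
) -> pd.DataFrame:
    """Full-factorial repeated-measures ANOVA on a balanced cell-means table.

    ``table`` holds one row per participant × cell with the cell mean in
    column ``dv`` and factor levels in the ``within`` columns.  The model
    is a linear mixed model with a participant random intercept; because
    the design is balanced and every tested effect is a within-subject
    contrast, the fixed effects equal their OLS estimates and are tested
    against the pooled within-subject residual variance (REML estimate).
    Denominator df follow the residual convention: rows − number of
    fixed-effect parameters.

    Returns a frame with columns ``effect, F, df_num, df_den, p,
    partial_eta_sq``.
    """
    df = table.reset_index(drop=True)
    subjects = df[subject].to_numpy()
    y = df[dv].to_numpy(dtype=float)
    if np.isnan(y).any():
        bad = sorted(set(subjects[np.isnan(y)].tolist()))
        raise ValueError(f"missing cell means for participants: {bad}")

    # balance check: every subject must fill the full factorial once
    cell = df.groupby([subject, *within], sort=False).size()
    if (cell != 1).any():
        offender = cell[cell != 1].index[0][0]
        raise ValueError(
            f"design unbalanced: participant {offender!r} does not have "
            f"exactly one row per cell"
        )
    n_cells = int(np.prod([df[f].nunique() for f in within]))
    per_subj = df.groupby(subject).size()
    if (per_subj != n_cells).any():
        offender = per_subj[per_subj != n_cells].index[0]
        raise ValueError(f"participant {offender!r} is missing cells of the design")

    main = {f: _sum_code(df[f].to_numpy()) for f in within}
    blocks: list[tuple[str, np.ndarray]] = []
    for order in range(1, len(within) + 1):
        for combo in itertools.combinations(within, order):
            cols = main[combo[0]]
            for f in combo[1:]:
                cols = np.einsum("ij,ik->ijk", cols, main[f]).reshape(len(df), -1)
            blocks.append((" * ".join(combo), cols))

    X = np.column_stack([np.ones(len(df))] + [b for _, b in blocks])
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    xtx_inv = np.linalg.inv(X.T @ X)

    # pooled within-subject residual variance (REML): project out subject
    # means and all fixed effects
    subj_dummies = pd.get_dummies(pd.Series(subjects)).to_numpy(dtype=float)
    Z = np.column_stack([X, subj_dummies[:, 1:]])
    resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    n_subj = subj_dummies.shape[1]
    df_within = n - n_subj - (p - 1)
    sigma2 = float(resid @ resid) / df_within

    df_den = n - p
    rows = []
    start = 1
    for name, cols in blocks:
        q = cols.shape[1]
        bJ = beta[start : start + q]
        CJ = xtx_inv[start : start + q, start : start + q]
        wald = float(bJ @ np.linalg.solve(CJ, bJ))
        F = wald / (q * sigma2)
        pval = float(sps.f.sf(F, q, df_den))
        rows.append(
            {
                "effect": name,
                "F": F,
                "df_num": q,
                "df_den": df_den,
                "p": pval,
                "partial_eta_sq": F * q / (F * q + df_den),
            }
        )
        start += q
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cluster-wise sign-flip permutation tests

@dataclass
class Cluster:
    """One supra-threshold cluster of a pointwise t map."""

    indices: np.ndarray = field(repr=False)  # flat indices into the map
    mass: float = 0.0  # summed t (signed)
    p: float = 1.0
    sign: int = 1


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    n_permutations: int
    cluster_forming_alpha: float
    fwer_alpha: float
    threshold: float
    t_map: np.ndarray = field(repr=False)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.fwer_alpha]


def _t_maps(signed_data: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t for each row of sign flips.

    ``signed_data`` is (n_subj, m); ``signs`` is (n_perm, n_subj) of ±1.
    Sign flips leave x² invariant, so only the mean needs recomputing.
    """
    n = signed_data.shape[0]
    means = signs @ signed_data / n
    ssq = np.sum(signed_data**2, axis=0)
    var = (ssq / n - means**2) * n / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return means / np.sqrt(var / n)


def _clusters_of(tmap_flat: np.ndarray, thr: float, shape: tuple) -> list[tuple[np.ndarray, float]]:
    """Sign-separated supra-threshold clusters (1-D runs / 2-D 4-connected)."""
    out: list[tuple[np.ndarray, float]] = []
    for sign in (1, -1):
        mask = (sign * tmap_flat > thr) & np.isfinite(tmap_flat)
        if not mask.any():
            continue
        if len(shape) == 1:
            lab, nlab = ndimage.label(mask)
        else:
            lab, nlab = ndimage.label(mask.reshape(shape))
            lab = lab.ravel()
        for k in range(1, nlab + 1):
            idx = np.flatnonzero(lab == k)
            out.append((idx, float(tmap_flat[idx].sum())))
    return out


def _max_mass(tmap_flat: np.ndarray, thr: float, shape: tuple) -> float:
    cl = _clusters_of(tmap_flat, thr, shape)
    return max((abs(m) for _, m in cl), default=0.0)


def cluster_permutation(
    differences: np.ndarray,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    fwer_alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    exact: Optional[bool] = None,
) -> ClusterTestResult:
    """Cluster-wise sign-flip permutation test of per-participant differences.

    ``differences`` is (n_participants, m) for 1-D traces or
    (n_participants, m, m) for 2-D matrices.  A pointwise one-sample t
    is thresholded at the two-tailed critical value for
    ``cluster_alpha``; contiguous supra-threshold runs (1-D) or
    4-connected regions (2-D), separated by sign, form clusters whose
    mass is the summed t.  The null distribution of the maximum absolute
    cluster mass is built from ``n_perm`` random whole-participant sign
    flips (or, with ``exact=True`` / automatically when 2ⁿ ≤ n_perm, all
    2ⁿ flips); cluster p = (1 + #{null ≥ observed}) / (1 + n_perm).
    NaN cells (e.g. an excluded matrix diagonal) never enter clusters.
    """
    data = np.asarray(differences, dtype=float)
    n = data.shape[0]
    if n < 6:
        raise ValueError("need at least 6 participants for the permutation test")
    shape = data.shape[1:]
    flat = data.reshape(n, -1)
    thr = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, n - 1))

    t_obs = _t_maps(flat, np.ones((1, n)))[0]
    obs_clusters = _clusters_of(t_obs, thr, shape)

    use_exact = exact if exact is not None else (2**n <= n_perm)
    if use_exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = rng or np.random.default_rng()
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    n_eff = len(signs)

    null_max = np.empty(n_eff)
    batch = 256
    for b0 in range(0, n_eff, batch):
        tm = _t_maps(flat, signs[b0 : b0 + batch])
        for j in range(len(tm)):
            null_max[b0 + j] = _max_mass(tm[j], thr, shape)

    clusters = [
        Cluster(
            indices=idx,
            mass=mass,
            p=float((1 + np.sum(null_max >= abs(mass))) / (1 + n_eff)),
            sign=1 if mass > 0 else -1,
        )
        for idx, mass in obs_clusters
    ]
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterTestResult(
        clusters=clusters,
        n_permutations=n_eff,
        cluster_forming_alpha=cluster_alpha,
        fwer_alpha=fwer_alpha,
        threshold=thr,
        t_map=t_obs.reshape(shape),
    )


# ---------------------------------------------------------------------------
# within-subject SEM

def within_subject_sem(values: np.ndarray) -> np.ndarray:
    """Cousineau-Morey within-subject SEM per cell.

    ``values`` is (n_participants, k_cells).  Each participant's mean is
    removed (and the grand mean restored), then the per-cell SD is
    inflated by Morey's √(k/(k−1)) factor and divided by √n.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need an (n ≥ 2 participants, k cells) array")
    n, k = y.shape
    centred = y - y.mean(axis=1, keepdims=True) + y.mean()
    morey = math.sqrt(k / (k - 1))
    return centred.std(axis=0, ddof=1) * morey / math.sqrt(n)


# ---------------------------------------------------------------------------
# Spearman correlation

def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with two-tailed p.

    Ties get average ranks.  For n ≤ ``exact_max_n`` the p-value is
    exact, by enumerating all permutations of one variable's ranks;
    above that a t approximation on ρ is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rx, ry = _rank(x), _rank(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    rho = float(rxc @ ryc) / denom

    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = perms @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * sps.t.sf(abs(tstat), n - 2))


# ---------------------------------------------------------------------------
# sensitivity power analysis

def sensitivity_mdes(
    n: int,
    alpha: float = 0.05,
    power: float = 0.8,
    tails: str = "one",
) -> float:
    """Minimal detectable Cohen's d_z for a paired/one-sample t test.

    Solves the noncentral-t power function for the smallest effect size
    reaching ``power`` at significance ``alpha`` with ``n`` pairs
    (df = n − 1).  One-tailed by default.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not (0 < power < 1):
        raise ValueError("power must lie in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    sqrt_n = math.sqrt(n)

    if tails == "one":
        tcrit = sps.t.ppf(1.0 - alpha, df)

        def achieved(d: float) -> float:
            return float(sps.nct.sf(tcrit, df, d * sqrt_n))

    elif tails == "two":
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)

        def achieved(d: float) -> float:
            nc = d * sqrt_n
            return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))

    else:
        raise ValueError("tails must be 'one' or 'two'")

    return float(optimize.brentq(lambda d: achieved(d) - power, 1e-6, 10.0, xtol=1e-10))
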