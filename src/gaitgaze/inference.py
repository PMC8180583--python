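"""Within-subject inference: paired t-tests and the 2x3 repeated-measures
ANOVA (factors world: VR/RW and sector: corridor/ascending/descending) with
Mauchly's sphericity test and Greenhouse-Geisser correction.

Reporting rule
--------------
For every effect the uncorrected degrees of freedom and F are computed from
the classical within-subject decomposition (each effect tested against its
own subject-by-effect interaction).  Mauchly's test is run per effect on
the covariance of the subject scores under an orthonormal contrast basis;
when it is significant at the 5% level, the reported p-value is the
Greenhouse-Geisser corrected one (F evaluated at epsilon-scaled dfs) and
epsilon_GG accompanies it.  A two-level effect has a single contrast, so it
is spherical by construction and epsilon is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedTTest",
    "EffectResult",
    "AnovaResult",
    "paired_ttest",
    "rm_anova_2x3",
    "rm_anova_oneway",
    "WORLD_LEVELS",
    "SECTOR_LEVELS",
]

WORLD_LEVELS = ("VR", "RW")
SECTOR_LEVELS = ("corridor", "ascending", "descending")


@dataclass
class PairedTTest:
    t: float
    df: int
    p: float


def paired_ttest(a, b) -> PairedTTest:
    """Two-sided paired t-test on per-subject values; df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_ttest needs two equal-length vectors, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    return PairedTTest(t=float(res.statistic), df=a.size - 1, p=float(res.pvalue))


@dataclass
class EffectResult:
    name: str
    F: float
    df_num: int          # uncorrected
    df_den: int
    p_uncorrected: float
    mauchly_w: float     # NaN for 2-level effects (spherical by construction)
    mauchly_p: float
    epsilon_gg: float
    p_gg: float
    gg_applied: bool     # True when mauchly_p < alpha

    @property
    def p_reported(self) -> float:
        return self.p_gg if self.gg_applied else self.p_uncorrected


@dataclass
class AnovaResult:
    effects: dict        # name -> EffectResult
    n_subjects: int

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis of the subspace orthogonal to the constant."""
    H = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, :-1]]))[0]
    return H[:, 1:]


def _mauchly(scores: np.ndarray) -> tuple[float, float]:
    """Mauchly's W and its chi-square p-value for contrast scores (n, k)."""
    n, k = scores.shape
    if k < 2:
        return float("nan"), float("nan")
    S = np.cov(scores, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 1e-300, None)
    W = float(np.prod(eig) / (eig.mean() ** k))
    d = n - 1
    f = 1.0 - (2 * k * k + k + 2) / (6.0 * k * d)
    chi2 = -d * f * math.log(max(W, 1e-300))
    df = k * (k + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return W, p


def _epsilon_gg(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from orthonormal-contrast scores."""
    k = scores.shape[1]
    if k < 2:
        return 1.0
    S = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    if tr2 <= 0:
        return 1.0
    return float(min(1.0, tr * tr / (k * tr2)))


def _effect(name: str, F: float, df1: int, df2: int,
            scores: np.ndarray, alpha: float) -> EffectResult:
    p_unc = float(stats.f.sf(F, df1, df2))
    w, mp = _mauchly(scores)
    eps = _epsilon_gg(scores)
    p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
    applied = bool(np.isfinite(mp) and mp < alpha)
    return EffectResult(name=name, F=float(F), df_num=df1, df_den=df2,
                        p_uncorrected=p_unc, mauchly_w=w, mauchly_p=mp,
                        epsilon_gg=eps, p_gg=p_gg, gg_applied=applied)


def _cells_from_tidy(df: pd.DataFrame, value: str) -> np.ndarray:
    subjects = sorted(df["participant"].unique())
    out = np.full((len(subjects), len(WORLD_LEVELS), len(SECTOR_LEVELS)), np.nan)
    for si, s in enumerate(subjects):
        for wi, w in enumerate(WORLD_LEVELS):
            for ci, c in enumerate(SECTOR_LEVELS):
                sel = df[(df["participant"] == s) & (df["world"] == w)
                         & (df["sector"] == c)][value]
                if len(sel) != 1 or not np.isfinite(sel.iloc[0]):
                    raise ValueError(
                        f"missing or duplicated cell: subject {s!r}, "
                        f"world {w!r}, sector {c!r}"
                    )
                out[si, wi, ci] = sel.iloc[0]
    return out


def rm_anova_2x3(cells, *, alpha: float = 0.05) -> AnovaResult:
    """Two-way repeated-measures ANOVA on a complete balanced table.

    Parameters
    ----------
    cells
        Either an array of shape ``(n_subjects, 2, 3)`` ordered as
        (world: VR, RW) x (sector: corridor, ascending, descending), or a
        tidy DataFrame with columns participant/world/sector/value.
    alpha
        Significance level of Mauchly's test that triggers the
        Greenhouse-Geisser report.
    """
    if isinstance(cells, pd.DataFrame):
        value = "value" if "value" in cells.columns else cells.columns[-1]
        Y = _cells_from_tidy(cells, value)
    else:
        Y = np.asarray(cells, dtype=float)
    if Y.ndim != 3 or Y.shape[1] != 2 or Y.shape[2] != 3:
        raise ValueError("expected cells of shape (n_subjects, 2, 3)")
    n, a, b = Y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(Y).all():
        bad = np.argwhere(~np.isfinite(Y))[0]
        raise ValueError(f"missing cell: subject index {bad[0]}, "
                         f"world {WORLD_LEVELS[bad[1]]}, sector {SECTOR_LEVELS[bad[2]]}")

    gm = Y.mean()
    mean_a = Y.mean(axis=(0, 2))            # (a,)
    mean_b = Y.mean(axis=(0, 1))            # (b,)
    mean_s = Y.mean(axis=(1, 2))            # (n,)
    mean_ab = Y.mean(axis=0)                # (a, b)
    mean_sa = Y.mean(axis=2)                # (n, a)
    mean_sb = Y.mean(axis=1)                # (n, b)

    ss_a = n * b * ((mean_a - gm) ** 2).sum()
    ss_b = n * a * ((mean_b - gm) ** 2).sum()
    ss_ab = n * ((mean_ab - mean_a[:, None] - mean_b[None, :] + gm) ** 2).sum()
    ss_s = a * b * ((mean_s - gm) ** 2).sum()
    ss_sa = b * ((mean_sa - mean_s[:, None] - mean_a[None, :] + gm) ** 2).sum()
    ss_sb = a * ((mean_sb - mean_s[:, None] - mean_b[None, :] + gm) ** 2).sum()
    ss_tot = ((Y - gm) ** 2).sum()
    ss_sab = ss_tot - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb

    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_sa, df_sb, df_sab = df_a * (n - 1), df_b * (n - 1), df_ab * (n - 1)

    F_a = (ss_a / df_a) / (ss_sa / df_sa)
    F_b = (ss_b / df_b) / (ss_sb / df_sb)
    F_ab = (ss_ab / df_ab) / (ss_sab / df_sab)

    Ca = _orthonormal_contrasts(a)
    Cb = _orthonormal_contrasts(b)
    scores_a = mean_sa @ Ca                                 # (n, a-1)
    scores_b = mean_sb @ Cb                                 # (n, b-1)
    scores_ab = Y.reshape(n, a * b) @ np.kron(Ca, Cb)       # (n, (a-1)(b-1))

    effects = {
        "world": _effect("world", F_a, df_a, df_sa, scores_a, alpha),
        "sector": _effect("sector", F_b, df_b, df_sb, scores_b, alpha),
        "interaction": _effect("interaction", F_ab, df_ab, df_sab,
                               scores_ab, alpha),
    }
    return AnovaResult(effects=effects, n_subjects=n)


def rm_anova_oneway(data, *, name: str = "sector",
                    alpha: float = 0.05) -> EffectResult:
    """One-way repeated-measures ANOVA on ``(n_subjects, k_levels)`` data,
    with the same Mauchly / Greenhouse-Geisser reporting as the 2x3 design
    (used for head-movement statistics, which have the sector factor only)."""
    Y = np.asarray(data, dtype=float)
    n, k = Y.shape
    if n < 3 or k < 2:
        raise ValueError("need n >= 3 subjects and k >= 2 levels")
    gm = Y.mean()
    mean_l = Y.mean(axis=0)
    mean_s = Y.mean(axis=1)
    ss_l = n * ((mean_l - gm) ** 2).sum()
    ss_err = ((Y - mean_l[None, :] - mean_s[:, None] + gm) ** 2).sum()
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_l / df1) / (ss_err / df2)
    scores = Y @ _orthonormal_contrasts(k)
    return _effect(name, F, df1, df2, scores, alpha)
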