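"""Group-level inference: sign-flip cluster permutation, t statistics,
repeated-measures ANOVA, Bayes-factor time courses, circular statistics.

The cluster test controls family-wise error over time: clusters are maximal
runs of consecutive samples whose one-sample t exceeds the two-sided
cluster-forming threshold with a consistent sign; the cluster statistic is
the sum of t values, and its null distribution is the maximum absolute
cluster sum over random sign-flips of the participant effects.  Permutation
p values include the observed statistic in the null (+1/+1), so
p >= 1 / (n_perm + 1).

Bayes factors use the default-prior (JZS) t-test formulation with a Cauchy
prior of scale 0.707 on the standardized effect, one-tailed via truncation
of the prior to the hypothesised direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "ClusterResult", "GroupTest", "cluster_permutation", "one_sample_test",
    "rm_anova_2x2", "bf01_timecourse", "jzs_bf01", "rayleigh_test",
    "circular_correlation", "gaussian_smooth",
]


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    sum_t: float
    p_cluster: float


@dataclass(frozen=True)
class ClusterResult:
    clusters: list
    n_permutations: int
    cluster_forming_alpha: float
    null_max: np.ndarray  # null distribution of the max |cluster sum|

    @property
    def min_p(self) -> float:
        return min((c.p_cluster for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_cluster < alpha]


@dataclass(frozen=True)
class GroupTest:
    t: float
    df: int
    p: float
    cohens_d: float
    ci95: tuple
    mean: float


def _t_rows(signed: np.ndarray, ssq: np.ndarray, n: int) -> np.ndarray:
    """One-sample t per column from sign-flipped column sums.

    ``signed`` holds per-permutation column sums Σ s_i x_i; the second moment
    Σ x_i² is sign-invariant, which makes the flipped-sample variance a
    function of the flipped mean alone.
    """
    m = signed / n
    var = (ssq / n - m ** 2) * n / (n - 1)
    var = np.maximum(var, 1e-300)
    return m / np.sqrt(var / n)


def _max_cluster_sums(tmat: np.ndarray, crit: float) -> np.ndarray:
    """Per-row maximum absolute sum of t over sign-consistent suprathreshold
    runs (0 where no sample exceeds the threshold)."""
    R, T = tmat.shape
    out = np.zeros(R)
    # pad a separating column of zeros so runs cannot cross rows
    padded = np.concatenate([tmat, np.zeros((R, 1))], axis=1).ravel()
    for sign in (1.0, -1.0):
        x = sign * padded
        mask = x > crit
        if not mask.any():
            continue
        starts = mask & ~np.concatenate([[False], mask[:-1]])
        seg_id = np.cumsum(starts) * mask  # 0 outside segments
        sums = np.bincount(seg_id, weights=np.where(mask, x, 0.0))[1:]
        seg_start = np.flatnonzero(starts)
        rows = seg_start // (T + 1)
        np.maximum.at(out, rows, sums)
    return out


def _observed_clusters(tvals: np.ndarray, crit: float, time_ms: np.ndarray):
    """Maximal sign-consistent suprathreshold runs of the observed t series."""
    clusters = []
    for sign in (1.0, -1.0):
        mask = sign * tvals > crit
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        splits = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(idx, splits + 1):
            clusters.append((time_ms[seg[0]], time_ms[seg[-1]], float(tvals[seg].sum())))
    clusters.sort(key=lambda c: c[0])
    return clusters


def cluster_permutation(data: np.ndarray, time_ms: np.ndarray | None = None,
                        alpha_sample: float = 0.05, n_perm: int = 20000,
                        seed: int | None = 0, chunk: int = 512) -> ClusterResult:
    """Sign-flip cluster-based permutation test of participant x time data
    against zero.

    ``data`` is (n_participants, n_times); columns that are NaN for any
    participant are treated as absent (t undefined there breaks clusters).
    """
    data = np.asarray(data, float)
    n, T = data.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if time_ms is None:
        time_ms = np.arange(T, dtype=float)
    col_ok = ~np.isnan(data).any(axis=0)
    if not col_ok.any():
        raise ValueError("all time points missing")
    X = data[:, col_ok]
    ssq = (X ** 2).sum(axis=0)
    crit = stats.t.ppf(1.0 - alpha_sample / 2.0, df=n - 1)
    t_obs_ok = _t_rows(X.sum(axis=0), ssq, n)
    t_obs = np.full(T, np.nan)
    t_obs[col_ok] = t_obs_ok

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n))
        tmat = _t_rows(signs @ X, ssq[None, :], n)
        null_max[done:done + m] = _max_cluster_sums(tmat, crit)
        done += m

    obs = _observed_clusters(t_obs_ok, crit, time_ms[col_ok])
    clusters = []
    for (t0, t1, s) in obs:
        p = (np.count_nonzero(null_max >= abs(s)) + 1) / (n_perm + 1)
        clusters.append(Cluster(start_ms=float(t0), end_ms=float(t1), sum_t=s, p_cluster=p))
    return ClusterResult(clusters=clusters, n_permutations=n_perm,
                         cluster_forming_alpha=alpha_sample, null_max=null_max)


def one_sample_test(values, popmean: float = 0.0, tail: str = "two_sided") -> GroupTest:
    """One-sample t test with Cohen's d and the 95% CI of the mean.

    ``tail``: 'two_sided', 'greater' or 'less'.
    """
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[tail]
    res = stats.ttest_1samp(x, popmean, alternative=alt)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return GroupTest(t=float(res.statistic), df=n - 1, p=float(res.pvalue),
                     cohens_d=float((x.mean() - popmean) / sd),
                     ci95=(float(x.mean() - tcrit * se), float(x.mean() + tcrit * se)),
                     mean=float(x.mean()))


def rm_anova_2x2(cells: np.ndarray) -> dict[str, dict]:
    """2 x 2 repeated-measures ANOVA via within-participant contrasts.

    ``cells`` is (n_participants, 2, 2) with factors A (axis 1) and B
    (axis 2).  Each effect's F(1, n-1) equals the squared paired t of the
    corresponding contrast score.  Generalized eta squared uses the effect
    sum of squares over effect-plus-total-error variability.
    """
    cells = np.asarray(cells, float)
    n = cells.shape[0]
    if cells.shape[1:] != (2, 2) or np.isnan(cells).any():
        raise ValueError("need complete 2x2 cells per participant")
    contrasts = {
        "A": (cells[:, 0, :].mean(axis=1) - cells[:, 1, :].mean(axis=1)),
        "B": (cells[:, :, 0].mean(axis=1) - cells[:, :, 1].mean(axis=1)),
        "AxB": (cells[:, 0, 0] - cells[:, 0, 1] - cells[:, 1, 0] + cells[:, 1, 1]) / 2.0,
    }
    # error terms for generalized eta squared: all within-cell residual SS
    grand = cells.mean()
    subj_mean = cells.mean(axis=(1, 2))
    ss_effects = {}
    ss_error = 0.0
    for name, score in contrasts.items():
        ss_effects[name] = n * score.mean() ** 2
        ss_error += ((score - score.mean()) ** 2).sum()
    ss_subj = 2 * 2 * ((subj_mean - grand) ** 2).sum()
    out = {}
    for name, score in contrasts.items():
        if score.std(ddof=1) == 0:
            t = 0.0 if score.mean() == 0 else np.inf
            p = 1.0 if score.mean() == 0 else 0.0
        else:
            res = stats.ttest_1samp(score, 0.0)
            t, p = float(res.statistic), float(res.pvalue)
        denom = ss_effects[name] + ss_subj + ss_error
        out[name] = {"F": t ** 2, "df1": 1, "df2": n - 1, "p": p,
                     "eta_sq_gen": ss_effects[name] / denom if denom > 0 else 0.0}
    return out


# -- Bayes factors ------------------------------------------------------------

def jzs_bf01(tval: float, n: int, prior_scale: float = 0.707,
             tail: str = "greater") -> float:
    """JZS Bayes factor BF01 (evidence for H0) for a one-sample t value.

    H1 places a Cauchy(0, prior_scale) prior on the standardized effect,
    truncated to delta > 0 ('greater'), delta < 0 ('less') or untruncated
    ('two_sided').
    """
    df = n - 1
    f0 = stats.t.pdf(tval, df)

    def integrand(delta):
        return stats.nct.pdf(tval, df, delta * np.sqrt(n)) \
            * stats.cauchy.pdf(delta, scale=prior_scale)

    if tail == "two_sided":
        lo, hi, norm = -np.inf, np.inf, 1.0
    elif tail == "greater":
        lo, hi, norm = 0.0, np.inf, 0.5
    elif tail == "less":
        lo, hi, norm = -np.inf, 0.0, 0.5
    else:
        raise ValueError(f"unknown tail {tail!r}")
    f1, _ = integrate.quad(integrand, lo, hi, limit=200)
    f1 /= norm
    if f1 <= 0:
        return np.inf
    return float(f0 / f1)


def bf01_timecourse(data: np.ndarray, time_ms: np.ndarray | None = None,
                    smoothing_ms: float = 50.0, dt_ms: float | None = None,
                    prior_scale: float = 0.707, tail: str = "greater") -> np.ndarray:
    """log10 BF01 per time point for participant x time difference data.

    Data are Gaussian-smoothed along time (kernel SD = ``smoothing_ms``)
    before testing; the default one-tailed H1 is mean > 0.
    """
    data = np.asarray(data, float)
    n, T = data.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if dt_ms is None:
        dt_ms = float(time_ms[1] - time_ms[0]) if time_ms is not None else 1.0
    sm = gaussian_smooth(data, smoothing_ms, dt_ms)
    out = np.full(T, np.nan)
    for j in range(T):
        col = sm[:, j]
        if np.isnan(col).any() or col.std(ddof=1) == 0:
            continue
        tval = col.mean() / (col.std(ddof=1) / np.sqrt(n))
        out[j] = np.log10(jzs_bf01(tval, n, prior_scale, tail))
    return out


# -- circular statistics ------------------------------------------------------

def rayleigh_test(angles_deg) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: z = n * R̄², with the standard
    finite-n p approximation."""
    a = np.deg2rad(np.asarray(angles_deg, float))
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 angles")
    rbar = np.abs(np.exp(1j * a).mean())
    z = n * rbar ** 2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - (n * rbar) ** 2)) - (1 + 2 * n))
    return float(z), float(min(p, 1.0))


def circular_correlation(a_deg, b_deg, n_perm: int = 0,
                         seed: int | None = 0) -> tuple[float, float | None]:
    """Circular-circular correlation (Jammalamadaka-SenGupta).

    Returns (R, p); p is a permutation p value when ``n_perm`` > 0, else None.
    """
    a = np.deg2rad(np.asarray(a_deg, float))
    b = np.deg2rad(np.asarray(b_deg, float))
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired samples with n >= 3")

    def _r(a, b):
        abar = np.angle(np.exp(1j * a).mean())
        bbar = np.angle(np.exp(1j * b).mean())
        sa, sb = np.sin(a - abar), np.sin(b - bbar)
        denom = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
        if denom == 0:
            raise ValueError("degenerate (constant) angle set")
        return (sa * sb).sum() / denom

    r_obs = _r(a, b)
    if n_perm <= 0:
        return float(r_obs), None
    rng = np.random.default_rng(seed)
    null = np.array([_r(a, rng.permutation(b)) for _ in range(n_perm)])
    p = (np.count_nonzero(np.abs(null) >= abs(r_obs)) + 1) / (n_perm + 1)
    return float(r_obs), float(p)


def gaussian_smooth(data: np.ndarray, kernel_ms: float, dt_ms: float) -> np.ndarray:
    """Gaussian smoothing along the last axis (kernel SD in ms, reflected
    boundaries); NaN samples are excluded with weight renormalization."""
    if kernel_ms < 0:
        raise ValueError("kernel must be non-negative")
    data = np.asarray(data, float)
    if kernel_ms == 0:
        return data.copy()
    sigma = kernel_ms / dt_ms
    nan = np.isnan(data)
    if not nan.any():
        return gaussian_filter1d(data, sigma, axis=-1, mode="reflect")
    filled = np.where(nan, 0.0, data)
    num = gaussian_filter1d(filled, sigma, axis=-1, mode="reflect")
    den = gaussian_filter1d((~nan).astype(float), sigma, axis=-1, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 1e-12] = np.nan
    return out
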