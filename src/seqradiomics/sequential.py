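"""Sequential (trajectory) statistics of texture features.

Each base texture feature, computed per acquisition, yields one trajectory
per subject: six DCE time points or three DWI b-values. Two kinds of
statistics summarize a trajectory:

* per-subject statistics, functions of that subject's trajectory alone —
  mean, population variance, kurtosis, skewness, energy, entropy;
* cohort-interactive statistics, comparing the subject with the remainder of
  the cohort — mean pairwise Kendall tau-b, step-sign conservation,
  inverse-RMSD stability against the others' mean normalized trajectory, and
  per-time-point z-score dispersion.

For DWI (three points) kurtosis and entropy are dropped, leaving eight
statistics; DCE keeps all ten. Moments are population (1/T) moments: a
trajectory is a fixed short sequence, not a sample. Any statistic whose
denominator vanishes returns 0 (except where a different limit is defined).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from seqradiomics.manifest import COHORT_STATS, PER_SUBJECT_STATS


def per_subject_stats(x: np.ndarray, which=PER_SUBJECT_STATS) -> dict[str, float]:
    """Descriptive statistics of one trajectory.

    mean = sum(x)/T; variance = population variance; skewness = m3/m2^1.5
    and kurtosis = m4/m2^2 (both 0 for a constant trajectory);
    energy = sum(x^2); entropy = -sum p log2 p with p_t = |x_t| / sum|x|
    (0 for an all-zero trajectory).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("trajectory needs at least 2 points")
    m = x.mean()
    d = x - m
    m2 = (d ** 2).mean()
    out: dict[str, float] = {}
    for name in which:
        if name == "mean":
            out[name] = float(m)
        elif name == "variance":
            out[name] = float(m2)
        elif name == "skewness":
            out[name] = float((d ** 3).mean() / m2 ** 1.5) if m2 > 0 else 0.0
        elif name == "kurtosis":
            out[name] = float((d ** 4).mean() / m2 ** 2) if m2 > 0 else 0.0
        elif name == "energy":
            out[name] = float((x ** 2).sum())
        elif name == "entropy":
            tot = np.abs(x).sum()
            if tot == 0:
                out[name] = 0.0
            else:
                p = np.abs(x) / tot
                p = p[p > 0]
                out[name] = float(-(p * np.log2(p)).sum())
        else:
            raise KeyError(name)
    return out


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall rank correlation with tie correction, in [-1, 1].

    tau-b = (C - D) / sqrt((n0 - n1)(n0 - n2)); returns 0 when either
    tie-corrected denominator factor vanishes (e.g. a constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    tau = sps.kendalltau(x, y).statistic
    return float(tau) if np.isfinite(tau) else 0.0


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def cohort_interactive_stats(M: np.ndarray, i: int) -> dict[str, float]:
    """Cohort-interactive statistics of subject ``i`` of trajectory matrix ``M``.

    ``M`` is (N, T), one row per subject. With x = M[i] and j running over
    the other subjects:

    * ``kendall_tau_b``: mean over j of tau_b(x, M[j]);
    * ``conservation``: mean over j of the fraction of the T-1 successive
      steps whose difference signs agree between i and j;
    * ``stability``: 1 / (1 + RMSD(x~, c~)) where x~ is the min-max
      normalized trajectory and c~ the mean of the other subjects'
      normalized trajectories;
    * ``dispersion``: sqrt(mean_t z_t^2) with z the per-time-point
      full-cohort z-score (population sd; 0 where the sd is 0).
    """
    M = np.asarray(M, dtype=float)
    n, t = M.shape
    if n < 2:
        raise ValueError("cohort-interactive statistics need N >= 2")
    others = [j for j in range(n) if j != i]
    x = M[i]

    tau = float(np.mean([kendall_tau_b(x, M[j]) for j in others]))

    sx = np.sign(np.diff(x))
    cons = float(np.mean([(sx == np.sign(np.diff(M[j]))).mean() for j in others]))

    xn = _minmax(x)
    cn = np.mean([_minmax(M[j]) for j in others], axis=0)
    rmsd = float(np.sqrt(((xn - cn) ** 2).mean()))
    stab = 1.0 / (1.0 + rmsd)

    mu = M.mean(axis=0)
    sd = M.std(axis=0)  # population sd over the full cohort
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    disp = float(np.sqrt((z ** 2).mean()))

    return {
        "kendall_tau_b": tau,
        "conservation": cons,
        "stability": stab,
        "dispersion": disp,
    }


def _pairwise_tau_b_means(M: np.ndarray) -> np.ndarray:
    """Mean leave-self-out pairwise tau-b per subject, vectorized.

    Uses the sign-vector identity: with s_i the signs of all T(T-1)/2
    within-trajectory differences, C - D between subjects i and j is
    s_i . s_j and the tie-corrected denominator factors are n0 - #ties(i).
    """
    n, t = M.shape
    p_idx, q_idx = np.triu_indices(t, k=1)
    S = np.sign(M[:, q_idx] - M[:, p_idx])  # (N, n0)
    n0 = S.shape[1]
    untied = n0 - (S == 0).sum(axis=1)  # n0 - n1 per subject
    num = S @ S.T
    den = np.sqrt(np.outer(untied, untied))
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(tau, 0.0)
    return tau.sum(axis=1) / (n - 1)


def _conservation_means(M: np.ndarray) -> np.ndarray:
    n, t = M.shape
    D = np.sign(np.diff(M, axis=1))  # (N, T-1)
    agree = np.zeros((n, n))
    for c in (-1.0, 0.0, 1.0):
        A = (D == c).astype(float)
        agree += A @ A.T
    np.fill_diagonal(agree, 0.0)
    return agree.sum(axis=1) / ((n - 1) * (t - 1))


def sequential_stats_for_matrix(M: np.ndarray,
                                stat_names: tuple[str, ...]) -> np.ndarray:
    """All requested sequential statistics for every subject of one matrix,
    computed with vectorized cohort-level identities (equivalent to the
    per-subject definitions above). Returns (N, len(stat_names))."""
    M = np.asarray(M, dtype=float)
    n, t = M.shape
    cols: dict[str, np.ndarray] = {}
    mean = M.mean(axis=1)
    d = M - mean[:, None]
    m2 = (d ** 2).mean(axis=1)
    safe_m2 = np.where(m2 > 0, m2, 1.0)
    cols["mean"] = mean
    cols["variance"] = m2
    cols["skewness"] = np.where(m2 > 0, (d ** 3).mean(axis=1) / safe_m2 ** 1.5, 0.0)
    cols["kurtosis"] = np.where(m2 > 0, (d ** 4).mean(axis=1) / safe_m2 ** 2, 0.0)
    cols["energy"] = (M ** 2).sum(axis=1)
    absM = np.abs(M)
    tot = absM.sum(axis=1)
    p = absM / np.where(tot > 0, tot, 1.0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    cols["entropy"] = np.where(tot > 0, -(p * logp).sum(axis=1), 0.0)

    if any(s in COHORT_STATS for s in stat_names):
        if n < 2:
            raise ValueError("cohort-interactive statistics need N >= 2")
        cols["kendall_tau_b"] = _pairwise_tau_b_means(M)
        cols["conservation"] = _conservation_means(M)
        lo = M.min(axis=1, keepdims=True)
        rng = M.max(axis=1, keepdims=True) - lo
        xn = np.where(rng > 0, (M - lo) / np.where(rng > 0, rng, 1.0), 0.0)
        csum = xn.sum(axis=0)
        c_others = (csum[None, :] - xn) / (n - 1)
        cols["stability"] = 1.0 / (1.0 + np.sqrt(((xn - c_others) ** 2).mean(axis=1)))
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        z = np.where(sd > 0, (M - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        cols["dispersion"] = np.sqrt((z ** 2).mean(axis=1))

    return np.column_stack([cols[s] for s in stat_names])
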