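"""Timewise within-subject permutation tests with adaptive FDR control.

The paired null is built by random sign-flips of each subject's difference
trace, with the flip pattern shared across time points inside a permutation
so the null preserves the temporal correlation of the data.  Two-tailed
p-values use the add-one convention, p = (#{|null| >= |obs|} + 1)/(n_perm+1),
which bounds p away from zero at 1/(n_perm+1).  Multiplicity across time is
controlled at q = 0.05 by the two-stage adaptive linear step-up procedure.
Effect sizes are the probability of superiority for dependent samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TimewiseTestResult:
    times: np.ndarray          # s
    stat: np.ndarray           # group mean of paired differences per time
    p: np.ndarray              # permutation p per time, in (0, 1]
    p_star: float              # adaptive-FDR threshold (largest rejected p); NaN if none
    mask: np.ndarray           # significant time points
    delta_dep: float           # effect size over the significant window; NaN if none
    n_permutations: int
    q: float

    def significant_runs(self) -> list[tuple[float, float]]:
        """Contiguous significant intervals as (start_s, end_s) pairs."""
        runs = []
        idx = np.nonzero(self.mask)[0]
        if idx.size == 0:
            return runs
        dt = self.times[1] - self.times[0] if self.times.size > 1 else 0.0
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        for s, e in zip(starts, ends):
            runs.append((float(self.times[s]), float(self.times[e] + dt)))
        return runs

    def longest_run(self) -> float:
        """Length (s) of the longest contiguous significant interval."""
        runs = self.significant_runs()
        return max((e - s for s, e in runs), default=0.0)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "stat": self.stat, "p": self.p,
                      "significant": self.mask.astype(int)}
                     ).to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {"p_star": None if np.isnan(self.p_star) else self.p_star,
                "delta_dep": None if np.isnan(self.delta_dep) else self.delta_dep,
                "n_significant": int(self.mask.sum()),
                "longest_run_s": self.longest_run(),
                "n_permutations": self.n_permutations, "q": self.q}


def adaptive_fdr(p: np.ndarray, q: float = 0.05
                 ) -> tuple[float, np.ndarray]:
    """Two-stage adaptive linear step-up FDR control.

    Stage 1 runs an ordinary linear step-up at level q/(1+q); the number of
    non-rejections estimates the true-null count m0.  Stage 2 reruns the
    step-up at level q/(1+q) * m/m0.  Returns (p_star, mask) where p_star
    is the largest rejected p-value (NaN when nothing is rejected).
    """
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size

    def step_up(level: float) -> np.ndarray:
        order = np.argsort(p)
        below = np.nonzero(p[order] <= level * np.arange(1, m + 1) / m)[0]
        mask = np.zeros(m, bool)
        if below.size:
            mask[order[:below[-1] + 1]] = True
        return mask

    q1 = q / (1.0 + q)
    r1 = int(step_up(q1).sum())
    if r1 == 0:
        return np.nan, np.zeros(m, bool)
    if r1 == m:
        return float(p.max()), np.ones(m, bool)
    m0 = m - r1
    mask = step_up(q1 * m / m0)
    p_star = float(p[mask].max()) if mask.any() else np.nan
    return p_star, mask


def delta_dep(x: np.ndarray, y: np.ndarray) -> float:
    """Probability of superiority for dependent samples.

    Proportion of pairs with x_i > y_i, ties counted half:
    (#{x > y} + 0.5 * #{x == y}) / n.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D samples of n >= 2 pairs")
    n = x.size
    return float((np.sum(x > y) + 0.5 * np.sum(x == y)) / n)


def timewise_perm_test(cond_a: np.ndarray, cond_b: np.ndarray,
                       times: np.ndarray | None = None,
                       n_perm: int = 500, q: float = 0.05,
                       statistic: str = "mean",
                       rng: np.random.Generator | int | None = None
                       ) -> TimewiseTestResult:
    """Paired timewise permutation test across subjects with adaptive FDR.

    ``cond_a`` and ``cond_b`` are (n_subjects, n_times) subject-level
    averages.  The observed statistic is the group mean difference per time
    point (``statistic='t'`` uses the one-sample t on the differences).
    Delta_dep is computed on subject values averaged over the significant
    window when one exists.
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("conditions must share shape (n_subjects, n_times)")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("conditions contain NaN or infinite values")
    n_subj, n_times = a.shape
    if n_subj < 5:
        raise ValueError("need at least 5 subjects for the paired test")
    if times is None:
        times = np.arange(n_times, dtype=float)
    rng = np.random.default_rng(rng)

    d = a - b

    def stat_of(diffs: np.ndarray) -> np.ndarray:
        # diffs: (..., n_subj, n_times) -> statistic over subjects
        mean = diffs.mean(axis=-2)
        if statistic == "mean":
            return mean
        if statistic == "t":
            sem = diffs.std(axis=-2, ddof=1) / np.sqrt(n_subj)
            return np.where(sem > 0, mean / np.where(sem > 0, sem, 1.0), 0.0)
        raise ValueError(f"unknown statistic {statistic!r}")

    obs = stat_of(d)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null = stat_of(flips[:, :, None] * d[None, :, :])
    p = (np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0) + 1.0) / (n_perm + 1.0)
    p_star, mask = adaptive_fdr(p, q)
    dd = np.nan
    if mask.any():
        dd = delta_dep(a[:, mask].mean(axis=1), b[:, mask].mean(axis=1))
    return TimewiseTestResult(times=np.asarray(times, float), stat=obs, p=p,
                              p_star=p_star, mask=mask, delta_dep=dd,
                              n_permutations=n_perm, q=q)


def balanced_control_runs(pool: np.ndarray, n_target: int,
                          n_runs: int = 10,
                          rng: np.random.Generator | int | None = None
                          ) -> list[np.ndarray]:
    """Trial-count-balancing resamples: ``n_runs`` multisets of ``n_target``
    indices drawn with replacement from ``pool``."""
    pool = np.asarray(pool)
    if pool.size == 0:
        raise ValueError("empty trial pool")
    if n_target < 1:
        raise ValueError("n_target must be at least 1")
    rng = np.random.default_rng(rng)
    return [rng.choice(pool, size=n_target, replace=True)
            for _ in range(n_runs)]
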