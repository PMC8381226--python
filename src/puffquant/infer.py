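"""Significance tests for repeated-measures drug comparisons.

Two conditions are compared with a within-cell (block) permutation
test: under the null, each cell's pair of labels can be swapped
independently, which is equivalent to flipping the sign of its paired
difference.  The Monte-Carlo null uses 10,000 resamples and the
add-one p-value estimator, so p is never exactly zero.

Three or more conditions use the balanced repeated-measures
random-intercept model (drug treatment fixed, cell random).  With
complete balanced data the REML solution is available in closed form
from the two-way mean squares; the treatment F statistic carries
(k - 1, (k - 1)(n - 1)) degrees of freedom and each treatment-vs-control
contrast a t statistic on (k - 1)(n - 1) df — which is exactly the
Satterthwaite df in this balanced case.  Unbalanced or incomplete data
are rejected, not approximated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .effects import PairedDataset

__all__ = [
    "PermutationResult",
    "ContrastResult",
    "ModelFit",
    "block_permutation_test",
    "fit_repeated_measures",
]

DEFAULT_N_MC = 10_000


@dataclass(frozen=True)
class PermutationResult:
    """Within-block Monte-Carlo permutation test outcome."""

    observed: float  # mean paired difference
    z: float  # standardized against the permutation null
    p_value: float  # two-sided, add-one corrected
    n_mc: int
    seed: int
    n_cells: int


@dataclass(frozen=True)
class ContrastResult:
    """One treatment-vs-control contrast from the mixed model."""

    treatment: str
    estimate: float
    t: float
    df: int
    p_value: float


@dataclass
class ModelFit:
    """Balanced repeated-measures random-intercept model fit."""

    f_statistic: float
    df1: int
    df2: int
    p_value: float
    contrasts: list[ContrastResult]
    between_cell_variance: float
    residual_variance: float
    n_cells: int
    n_conditions: int
    condition_means: dict[str, float] = field(default_factory=dict)


def block_permutation_test(
    dataset: PairedDataset,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> PermutationResult:
    """Two-condition paired permutation test via within-cell sign flips.

    The statistic is the mean paired difference; under within-block
    label permutation it is monotone-equivalent to the zero-correlation
    linear statistic, so the two formulations give identical p-values.
    Two-sided p = (#{|null| >= |observed|} + 1) / (n_mc + 1).
    """
    if dataset.n_conditions != 2:
        raise ValueError(
            "block permutation test handles exactly 2 conditions; "
            "use fit_repeated_measures for 3 or more"
        )
    if n_mc < 1:
        raise ValueError("n_mc must be positive")
    d = dataset.differences(dataset.treatments[0])
    n = d.size
    obs = float(np.mean(d))
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_mc, n)) * 2 - 1
    null = (signs * d).mean(axis=1)
    exceed = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
    p = (exceed + 1) / (n_mc + 1)
    sd = float(null.std(ddof=0))
    z = (obs - float(null.mean())) / sd if sd > 0 else 0.0
    return PermutationResult(
        observed=obs, z=z, p_value=float(p), n_mc=n_mc, seed=seed, n_cells=n
    )


def fit_repeated_measures(dataset: PairedDataset) -> ModelFit:
    """Closed-form balanced repeated-measures random-intercept model.

    Requires a complete cells x conditions matrix with k >= 3
    conditions.  Treatment F = MS_treatment / MS_residual with
    df = (k - 1, (k - 1)(n - 1)); contrast t for treatment j is
    (mean_j - mean_control) / sqrt(2 * MS_residual / n) on
    (k - 1)(n - 1) df.  Contrast p-values are unadjusted.
    """
    k = dataset.n_conditions
    n = dataset.n_cells
    if k < 3:
        raise ValueError(
            "repeated-measures model needs >= 3 conditions; "
            "use block_permutation_test for 2"
        )
    y = dataset.responses.to_numpy(dtype=float)  # n cells x k conditions
    grand = y.mean()
    cond_means = y.mean(axis=0)
    cell_means = y.mean(axis=1)
    ss_treat = n * np.sum((cond_means - grand) ** 2)
    ss_cells = k * np.sum((cell_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_resid = ss_total - ss_treat - ss_cells
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_treat = ss_treat / df1
    ms_resid = max(ss_resid / df2, 0.0)
    if ms_resid > 0:
        f = ms_treat / ms_resid
        p = float(stats.f.sf(f, df1, df2))
    else:
        f = 0.0 if ms_treat == 0 else float("inf")
        p = 1.0 if ms_treat == 0 else 0.0
    ctrl_mean = float(dataset.responses[dataset.control].mean())
    contrasts = []
    for treatment in dataset.treatments:
        est = float(dataset.responses[treatment].mean()) - ctrl_mean
        if ms_resid > 0:
            t = est / np.sqrt(2.0 * ms_resid / n)
            pt = float(2.0 * stats.t.sf(abs(t), df2))
        else:
            t = 0.0 if est == 0 else float(np.sign(est)) * float("inf")
            pt = 1.0 if est == 0 else 0.0
        contrasts.append(
            ContrastResult(
                treatment=treatment, estimate=est, t=float(t), df=df2, p_value=pt
            )
        )
    between = max((ss_cells / (n - 1) - ms_resid) / k, 0.0)
    return ModelFit(
        f_statistic=float(f),
        df1=df1,
        df2=df2,
        p_value=p,
        contrasts=contrasts,
        between_cell_variance=float(between),
        residual_variance=float(ms_resid),
        n_cells=n,
        n_conditions=k,
        condition_means={
            c: float(m) for c, m in zip(dataset.conditions, cond_means)
        },
    )
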