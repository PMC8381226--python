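"""Estimation statistics for repeated-measures drug comparisons.

Each cell is measured under every condition (control plus one or more
drug treatments), so the unit of analysis is the cell's paired
difference.  Effects are summarised as paired mean differences with
bias-corrected and accelerated (BCa) 95% bootstrap confidence
intervals over 10,000 resamples of the cells, plus the resampling
distribution itself (raw and kernel-smoothed) and the per-cell
parallel-coordinates data needed for Gardner-Altman / Cumming style
estimation plots.  Only plot *data* is produced here; rendering is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedDataset",
    "PairedEffect",
    "paired_mean_difference",
    "bca_ci",
    "bca_from_bootstrap",
    "estimation_summary",
]

DEFAULT_N_BOOT = 10_000
DEFAULT_LEVEL = 0.95


@dataclass
class PairedDataset:
    """Complete cells x conditions response matrix.

    ``responses`` is a DataFrame indexed by cell id with one column per
    condition.  Every cell must be measured in every condition and at
    least two cells are required.
    """

    responses: pd.DataFrame
    control: str = "control"

    def __post_init__(self) -> None:
        if self.responses.shape[0] < 2:
            raise ValueError("need at least 2 cells")
        if self.responses.shape[1] < 2:
            raise ValueError("need control plus at least one treatment")
        if self.control not in self.responses.columns:
            raise ValueError(f"control condition {self.control!r} not present")
        if self.responses.isna().any().any():
            raise ValueError("dataset is incomplete: every cell must be "
                             "measured in every condition")

    @property
    def cell_ids(self) -> list:
        return list(self.responses.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.responses.columns)

    @property
    def treatments(self) -> list[str]:
        return [c for c in self.conditions if c != self.control]

    @property
    def n_cells(self) -> int:
        return int(self.responses.shape[0])

    @property
    def n_conditions(self) -> int:
        return int(self.responses.shape[1])

    def differences(self, treatment: str) -> np.ndarray:
        """Per-cell (treatment - control) differences."""
        if treatment not in self.responses.columns:
            raise ValueError(f"treatment {treatment!r} not in dataset")
        return (
            self.responses[treatment] - self.responses[self.control]
        ).to_numpy(dtype=float)

    @classmethod
    def from_tidy(
        cls,
        table: pd.DataFrame,
        value: str = "mean_area",
        control: str = "control",
    ) -> "PairedDataset":
        """Build from a tidy table with cell_id / condition / value columns."""
        wide = table.pivot(index="cell_id", columns="condition", values=value)
        return cls(responses=wide, control=control)


@dataclass
class PairedEffect:
    """Paired mean difference with its BCa bootstrap interval."""

    treatment: str
    control: str
    control_mean: float
    treatment_mean: float
    mean_difference: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int
    z0: float
    acceleration: float
    n_cells: int
    degenerate: bool = False
    bootstrap_distribution: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.treatment} - {self.control}: {self.mean_difference:+.4g} "
            f"[{self.ci_low:.4g}, {self.ci_high:.4g}] "
            f"({self.level:.0%} BCa, n={self.n_cells})"
        )


def bca_from_bootstrap(
    differences: np.ndarray, boot: np.ndarray, level: float = DEFAULT_LEVEL
) -> tuple[float, float, float, float]:
    """BCa adjustment given an explicit bootstrap distribution.

    Returns ``(z0, acceleration, ci_low, ci_high)``.  Factored out so the
    same adjustment can be applied to a Monte-Carlo bootstrap or to the
    exhaustively enumerated resampling distribution of a tiny sample.
    The bias term counts bootstrap statistics tied with the point
    estimate at half weight.
    """
    d = np.asarray(differences, dtype=float)
    boot = np.asarray(boot, dtype=float)
    n = d.size
    n_boot = boot.size
    obs = float(np.mean(d))
    prop = (np.sum(boot < obs) + 0.5 * np.sum(boot == obs)) / n_boot
    prop = min(max(prop, 0.5 / n_boot), 1.0 - 0.5 / n_boot)
    z0 = float(stats.norm.ppf(prop))

    # acceleration via jackknife skewness of the mean
    jack = (np.sum(d) - d) / (n - 1)
    dev = jack.mean() - jack
    denom = np.sum(dev**2) ** 1.5
    a = float(np.sum(dev**3) / (6.0 * denom)) if denom > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    z_lo, z_hi = stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)

    def adjusted(z: float) -> float:
        num = z0 + z
        return float(stats.norm.cdf(z0 + num / (1.0 - a * num)))

    lo, hi = np.quantile(boot, [adjusted(z_lo), adjusted(z_hi)])
    return z0, a, float(lo), float(hi)


def paired_mean_difference(dataset: PairedDataset, treatment: str) -> float:
    """Mean over cells of (treatment - control).

    For complete paired data this equals the difference of the condition
    means.
    """
    return float(np.mean(dataset.differences(treatment)))


def bca_ci(
    differences: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
    treatment: str = "treatment",
    control: str = "control",
    keep_distribution: bool = True,
    control_mean: float = float("nan"),
    treatment_mean: float = float("nan"),
) -> PairedEffect:
    """Bias-corrected and accelerated bootstrap CI of a mean difference.

    Cells (their paired differences) are resampled with replacement
    ``n_boot`` times.  The bias term z0 comes from the proportion of
    bootstrap statistics below the point estimate, counting ties with
    half weight; the acceleration from the jackknife skewness of the
    statistic.  All-identical differences give the degenerate interval
    [x, x] with ``degenerate=True``.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    obs = float(np.mean(d))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = d[idx].mean(axis=1)

    if np.ptp(d) == 0.0:
        return PairedEffect(
            treatment=treatment,
            control=control,
            control_mean=control_mean,
            treatment_mean=treatment_mean,
            mean_difference=obs,
            ci_low=obs,
            ci_high=obs,
            level=level,
            n_boot=n_boot,
            seed=seed,
            z0=0.0,
            acceleration=0.0,
            n_cells=n,
            degenerate=True,
            bootstrap_distribution=boot if keep_distribution else np.empty(0),
        )

    z0, a, ci_low, ci_high = bca_from_bootstrap(d, boot, level)
    return PairedEffect(
        treatment=treatment,
        control=control,
        control_mean=control_mean,
        treatment_mean=treatment_mean,
        mean_difference=obs,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        level=level,
        n_boot=n_boot,
        seed=seed,
        z0=z0,
        acceleration=a,
        n_cells=n,
        bootstrap_distribution=boot if keep_distribution else np.empty(0),
    )


def smoothed_density(
    samples: np.ndarray, n_grid: int = 256, pad_bw: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normal-kernel density of a bootstrap distribution on a fixed grid.

    Bandwidth follows Silverman's rule (the scipy default).  Returns
    ``(x, density)``; the density integrates to ~1 over the grid.
    """
    s = np.asarray(samples, dtype=float)
    if np.ptp(s) == 0.0:
        # degenerate distribution: a single spike
        x = np.linspace(s[0] - 1.0, s[0] + 1.0, n_grid)
        y = np.zeros(n_grid)
        y[n_grid // 2] = 1.0 / (x[1] - x[0])
        return x, y
    kde = stats.gaussian_kde(s, bw_method="silverman")
    bw = kde.factor * s.std(ddof=1)
    x = np.linspace(s.min() - pad_bw * bw, s.max() + pad_bw * bw, n_grid)
    return x, kde(x)


def estimation_summary(
    dataset: PairedDataset,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
) -> dict:
    """One PairedEffect per treatment plus plot-ready data.

    A two-condition dataset yields a single effect (Gardner-Altman
    layout); three or more conditions yield one effect per treatment
    sharing the control column (Cumming layout).  Each effect's
    bootstrap distribution is exported raw and as a normal-kernel
    smoothed density; the per-cell response matrix doubles as the
    parallel-coordinates line data.
    """
    effects: list[PairedEffect] = []
    densities: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ctrl_mean = float(dataset.responses[dataset.control].mean())
    for j, treatment in enumerate(dataset.treatments):
        eff = bca_ci(
            dataset.differences(treatment),
            n_boot=n_boot,
            level=level,
            seed=seed + j,
            treatment=treatment,
            control=dataset.control,
            control_mean=ctrl_mean,
            treatment_mean=float(dataset.responses[treatment].mean()),
        )
        effects.append(eff)
        densities[treatment] = smoothed_density(eff.bootstrap_distribution)
    return {
        "effects": effects,
        "densities": densities,
        "parallel_coordinates": dataset.responses.copy(),
        "layout": "gardner-altman" if dataset.n_conditions == 2 else "cumming",
    }
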