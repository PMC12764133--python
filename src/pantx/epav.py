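"""Expression presence–absence (ePAV) pan-transcriptome structure.

A gene family counts as present in a line iff its TPM is at or above a
threshold (low expression, TPM < threshold, is excluded).  Families are
partitioned by occupancy into core (present in 100% of lines), shell
(10%–<100%) and cloud (<10%, at least one line).  Saturation behaviour is
summarised by permutation rarefaction curves (pan = cumulative union,
core = cumulative intersection) and the novel-gain curve is fitted with the
power law n(N) = kappa * N^(-alpha) + tg_theta; alpha <= 1 marks an open
pan-transcriptome, alpha > 1 a closed one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CORE, SHELL, CLOUD, ABSENT = "core", "shell", "cloud", "absent"
CLOUD_MAX = 0.10  # occupancy strictly below this is cloud


@dataclass
class PresenceAbsenceMatrix:
    """Binary family x line matrix plus the TPM threshold that produced it."""

    values: pd.DataFrame  # bool, families x lines
    threshold: float
    all_zero_families: list[str] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return self.values.shape[1]

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PanPartition:
    occupancy: pd.Series  # fraction per family
    labels: pd.Series  # core/shell/cloud/absent per family
    counts: dict[str, int]
    fractions: dict[str, float]  # over labelled (non-absent) families


@dataclass
class RarefactionCurves:
    """Per-permutation pan/core/novel sizes at each sample size N."""

    table: pd.DataFrame  # columns: perm, N, pan, core, novel
    permutations: int
    seed: int

    def mean(self, col: str) -> pd.Series:
        return self.table.groupby("N")[col].mean()

    def median(self, col: str) -> pd.Series:
        return self.table.groupby("N")[col].median()


@dataclass
class PowerLawFit:
    kappa: float
    alpha: float
    tg_theta: float
    residual_norm: float
    openness: str
    model: str  # "2p" or "3p"
    degenerate: bool = False
    alt: dict = field(default_factory=dict)  # the non-selected model's fit


def build_epav(expr: pd.DataFrame, threshold: float = 1.0) -> PresenceAbsenceMatrix:
    """Presence = TPM >= threshold; all-zero families retained but flagged."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if expr.size == 0:
        raise ValueError("empty expression matrix")
    if (expr.to_numpy() < 0).any():
        raise ValueError("TPM values must be >= 0")
    pres = expr >= threshold
    all_zero = list(expr.index[(expr == 0).all(axis=1)])
    return PresenceAbsenceMatrix(values=pres, threshold=threshold, all_zero_families=all_zero)


def partition(pam: PresenceAbsenceMatrix) -> PanPartition:
    """Occupancy-band partition of families into core/shell/cloud.

    Core requires occupancy exactly 1; cloud is occupancy in (0, 0.10); shell
    covers [0.10, 1.0) — the paper's bands leave (0.90, 1.00) unassigned, and
    shell is the only assignment consistent with the three classes summing to
    100%.  Never-expressed families are excluded from all three labels and
    reported as "absent".
    """
    L = pam.n_lines
    if L < 10:
        warnings.warn("fewer than 10 lines: occupancy bands are degenerate", stacklevel=2)
    occ = pam.values.sum(axis=1) / L
    labels = pd.Series(SHELL, index=occ.index, dtype=object)
    labels[occ == 1.0] = CORE
    labels[occ < CLOUD_MAX] = CLOUD
    labels[occ == 0.0] = ABSENT
    counts = {k: int((labels == k).sum()) for k in (CORE, SHELL, CLOUD, ABSENT)}
    n_labelled = counts[CORE] + counts[SHELL] + counts[CLOUD]
    fracs = {
        k: (counts[k] / n_labelled if n_labelled else math.nan) for k in (CORE, SHELL, CLOUD)
    }
    return PanPartition(occupancy=occ, labels=labels, counts=counts, fractions=fracs)


def per_line_composition(pam: PresenceAbsenceMatrix, part: PanPartition) -> pd.DataFrame:
    """Per line, the fraction of its present families in each compartment.

    Lines with zero present families get NaN fractions.
    """
    rows = []
    for line in pam.values.columns:
        present = pam.values.index[pam.values[line]]
        n = len(present)
        if n == 0:
            rows.append({"line": line, CORE: math.nan, SHELL: math.nan, CLOUD: math.nan})
            continue
        lab = part.labels.loc[present]
        rows.append({"line": line, **{k: float((lab == k).mean()) for k in (CORE, SHELL, CLOUD)}})
    return pd.DataFrame(rows).set_index("line")


def rarefy(pam: PresenceAbsenceMatrix, permutations: int = 100, seed: int = 0) -> RarefactionCurves:
    """Permutation rarefaction: cumulative pan (union) and core (intersection)
    sizes over random line orderings, with per-step novel counts."""
    if permutations < 1:
        raise ValueError("need >= 1 permutation")
    M = pam.values.to_numpy(dtype=bool)
    L = M.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(permutations):
        order = rng.permutation(L)
        cols = M[:, order]
        pan = np.logical_or.accumulate(cols, axis=1).sum(axis=0)
        core = np.logical_and.accumulate(cols, axis=1).sum(axis=0)
        novel = np.diff(pan, prepend=0)
        for n in range(L):
            rows.append((p, n + 1, int(pan[n]), int(core[n]), int(novel[n])))
    table = pd.DataFrame(rows, columns=["perm", "N", "pan", "core", "novel"])
    return RarefactionCurves(table=table, permutations=permutations, seed=seed)


def _fit(N: np.ndarray, y: np.ndarray, three_param: bool):
    mask = y > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(np.log(N[mask]), np.log(y[mask]), 1)
        a0, k0 = -slope, math.exp(intercept)
    else:
        a0, k0 = 1.0, max(y.max(), 1.0)
    k0 = max(k0, 1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if three_param:
            f = lambda n, k, a, t: k * n ** (-a) + t
            p0 = (k0, a0, max(float(y.min()), 0.0))
            bounds = ([1e-12, -10.0, 0.0], [np.inf, 50.0, np.inf])
        else:
            f = lambda n, k, a: k * n ** (-a)
            p0 = (k0, a0)
            bounds = ([1e-12, -10.0], [np.inf, 50.0])
        popt, _ = curve_fit(f, N, y, p0=p0, bounds=bounds, maxfev=20_000)
    resid = float(np.linalg.norm(f(N, *popt) - y))
    return popt, resid


def fit_power_law(curves: RarefactionCurves, use: str = "mean") -> PowerLawFit:
    """Fit n(N) = kappa * N^(-alpha) + tg_theta to the novel-gain curve.

    The fit uses the per-N mean (or median) novel count over permutations for
    N >= 2.  A two-parameter variant (tg_theta fixed at 0) is fitted alongside;
    the model with the lower residual norm is selected (ties favour the
    three-parameter form).  All-zero novel counts yield a degenerate fit
    flagged "closed" with alpha = +inf.
    """
    agg = curves.mean("novel") if use == "mean" else curves.median("novel")
    agg = agg[agg.index >= 2]
    N = agg.index.to_numpy(dtype=float)
    y = agg.to_numpy(dtype=float)
    if len(N) < 2 or (y == 0).all():
        return PowerLawFit(
            kappa=0.0, alpha=math.inf, tg_theta=0.0, residual_norm=0.0,
            openness="closed", model="degenerate", degenerate=True,
        )
    (k3, a3, t3), r3 = _fit(N, y, three_param=True)
    (k2, a2), r2 = _fit(N, y, three_param=False)
    if r3 <= r2:
        sel = PowerLawFit(
            kappa=float(k3), alpha=float(a3), tg_theta=float(t3), residual_norm=r3,
            openness=classify_openness(a3), model="3p",
            alt={"kappa": float(k2), "alpha": float(a2), "tg_theta": 0.0, "residual_norm": r2},
        )
    else:
        sel = PowerLawFit(
            kappa=float(k2), alpha=float(a2), tg_theta=0.0, residual_norm=r2,
            openness=classify_openness(a2), model="2p",
            alt={"kappa": float(k3), "alpha": float(a3), "tg_theta": float(t3), "residual_norm": r3},
        )
    return sel


def classify_openness(alpha: float) -> str:
    """alpha <= 1: open (novel genes keep accruing); alpha > 1: closed."""
    return "open" if alpha <= 1.0 else "closed"


def lines_to_coverage(curves: RarefactionCurves, q: float, use: str = "mean") -> int:
    """Smallest N whose average pan size reaches a fraction q of the full pan."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    agg = curves.mean("pan") if use == "mean" else curves.median("pan")
    total = agg.iloc[-1]
    target = q * total
    for n, v in agg.items():
        if v >= target:
            return int(n)
    return int(agg.index[-1])
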