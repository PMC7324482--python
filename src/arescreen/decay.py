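"""mRNA decay kinetics from transcription-chase time courses.

After transcription is blocked (actinomycin D), the remaining mRNA of a
transcript decays approximately as a one-phase exponential
``Y(t) = y0 * exp(-k t)`` with plateau zero; the half-life is
``t_1/2 = ln(2) / k``.  This module normalises raw time courses to
percent-of-baseline, fits the exponential by nonlinear least squares,
and compares half-lives between conditions with bootstrap confidence
intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

DECAY_COLUMNS = ("condition", "replicate", "time_h", "value")

#: Rates below this (per hour; half-life ~ 80 years) are treated as
#: non-decaying: least squares on flat data can land at k = +epsilon.
K_MIN = 1e-6


@dataclass
class DecayCourse:
    """A decay time course for one condition.

    ``data`` is long-format with columns replicate, time_h, value.  All
    replicates must include a measurement at t = 0 and strictly positive
    values; times within a replicate are strictly increasing.
    """

    condition: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.loc[:, ["replicate", "time_h", "value"]].copy()
        df = df.sort_values(["replicate", "time_h"], kind="stable").reset_index(drop=True)
        if (df["value"] <= 0).any():
            bad = df.loc[df["value"] <= 0].iloc[0]
            raise ValueError(
                f"{self.condition}: non-positive value at t={bad['time_h']} "
                f"(replicate {bad['replicate']})"
            )
        for rep, grp in df.groupby("replicate"):
            t = grp["time_h"].to_numpy(dtype=float)
            if (t < 0).any():
                raise ValueError(f"{self.condition}: negative time in replicate {rep}")
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"{self.condition}: times not strictly increasing in replicate {rep}"
                )
            if t[0] != 0:
                raise ValueError(
                    f"{self.condition}: replicate {rep} has no t=0 measurement"
                )
        self.data = df

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique())

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time_h"].unique())


def read_decay_table(path: str | Path) -> dict[str, DecayCourse]:
    """Read a long-format TSV (condition, replicate, time_h, value)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(DECAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        str(cond): DecayCourse(condition=str(cond), data=grp)
        for cond, grp in df.groupby("condition")
    }


def normalize_to_baseline(course: DecayCourse) -> DecayCourse:
    """Express each replicate as percent of its own t=0 value.

    After normalisation every replicate starts at exactly 100; the
    operation is idempotent on already-percent input whose baseline is
    100.
    """
    df = course.data.copy()
    for rep, grp in df.groupby("replicate"):
        baseline = grp.loc[grp["time_h"] == 0, "value"].iloc[0]
        if baseline <= 0:
            raise ValueError(
                f"{course.condition}: replicate {rep} has non-positive baseline"
            )
        df.loc[grp.index, "value"] = grp["value"] / baseline * 100.0
    return DecayCourse(condition=course.condition, data=df)


@dataclass
class DecayFit:
    """A fitted one-phase exponential decay.

    ``t_half`` is infinite (and ``decaying`` False) when the fitted rate
    is non-positive.  ``ci_t_half`` is a bootstrap percentile interval,
    present when a seed was supplied.
    """

    condition: str
    k: float
    y0: float
    t_half: float
    rss: float
    decaying: bool
    ci_t_half: tuple[float, float] | None = None
    n_boot: int = 0

    def __post_init__(self) -> None:
        if self.decaying and self.t_half <= 0:
            raise ValueError("decaying fit must have positive half-life")


def _exp_model(t: np.ndarray, y0: float, k: float) -> np.ndarray:
    return y0 * np.exp(-k * t)


def _exp_model_plateau(t: np.ndarray, y0: float, k: float, c: float) -> np.ndarray:
    return c + (y0 - c) * np.exp(-k * t)


def _initial_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Log-linear regression slope as the starting decay rate."""
    slope, _ = np.polyfit(t, np.log(y), 1)
    return max(-slope, 1e-6)


def _fit_arrays(
    t: np.ndarray,
    y: np.ndarray,
    fix_y0: bool,
    free_plateau: bool,
) -> tuple[float, float, float, float]:
    """Least-squares fit; returns (y0, k, plateau, rss)."""
    k0 = _initial_rate(t, y)
    if free_plateau:
        p0 = [y[t == 0].mean() if not fix_y0 else 100.0, k0, 0.0]
        popt, _ = optimize.curve_fit(
            _exp_model_plateau, t, y, p0=p0, maxfev=10000
        )
        y0, k, c = popt
    elif fix_y0:
        popt, _ = optimize.curve_fit(
            lambda tt, kk: _exp_model(tt, 100.0, kk), t, y, p0=[k0], maxfev=10000
        )
        y0, k, c = 100.0, popt[0], 0.0
    else:
        popt, _ = optimize.curve_fit(
            _exp_model, t, y, p0=[y[t == 0].mean(), k0], maxfev=10000
        )
        y0, k, c = popt[0], popt[1], 0.0
    resid = y - (_exp_model_plateau(t, y0, k, c) if free_plateau else _exp_model(t, y0, k))
    return float(y0), float(k), float(c), float(np.sum(resid**2))


def fit_one_phase_decay(
    course: DecayCourse,
    *,
    fix_y0: bool = False,
    free_plateau: bool = False,
    n_boot: int = 0,
    seed: int | None = None,
) -> DecayFit:
    """Fit ``Y(t) = y0 exp(-k t)`` to a percent-remaining course.

    The plateau is fixed at zero (a free plateau is available but off by
    default).  y0 is estimated unless ``fix_y0`` pins it at 100.  The
    fit minimises untransformed squared error over all replicate points
    pooled; the rate is initialised from a log-linear regression.

    With ``n_boot > 0`` a percentile confidence interval for the
    half-life is computed by resampling replicates with replacement
    (residual bootstrap when there is a single replicate); ``seed`` is
    required in that case.
    """
    df = course.data
    t = df["time_h"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time points to fit a decay")

    y0, k, _, rss = _fit_arrays(t, y, fix_y0, free_plateau)
    decaying = k > K_MIN
    t_half = math.log(2) / k if decaying else math.inf

    ci = None
    if n_boot > 0 and decaying:
        if seed is None:
            raise ValueError("bootstrap requires a seed")
        rng = np.random.default_rng(seed)
        reps = course.replicates
        halves = []
        fitted = y0 * np.exp(-k * t)
        resid = y - fitted
        for _ in range(n_boot):
            if len(reps) > 1:
                chosen = rng.choice(len(reps), size=len(reps), replace=True)
                parts = [df[df["replicate"] == reps[i]] for i in chosen]
                bt = np.concatenate([p["time_h"].to_numpy(float) for p in parts])
                by = np.concatenate([p["value"].to_numpy(float) for p in parts])
            else:
                bt = t
                by = fitted + rng.choice(resid, size=len(resid), replace=True)
                by = np.clip(by, 1e-9, None)
            try:
                _, bk, _, _ = _fit_arrays(bt, by, fix_y0, free_plateau)
            except RuntimeError:
                continue
            if bk > 0:
                halves.append(math.log(2) / bk)
        if halves:
            lo, hi = np.percentile(halves, [2.5, 97.5])
            ci = (float(lo), float(hi))

    return DecayFit(
        condition=course.condition,
        k=k,
        y0=y0,
        t_half=t_half,
        rss=rss,
        decaying=decaying,
        ci_t_half=ci,
        n_boot=n_boot,
    )


@dataclass
class HalfLifeComparison:
    """Ratio of half-lives between two conditions with uncertainty."""

    ratio: float
    ci: tuple[float, float] | None
    p_value: float
    t_half_a: float
    t_half_b: float
    p_method: str


def _per_replicate_halves(
    course: DecayCourse, fix_y0: bool
) -> list[float] | None:
    """Individual-replicate half-lives, or None if any replicate cannot
    support its own fit."""
    halves = []
    for rep in course.replicates:
        grp = course.data[course.data["replicate"] == rep]
        t = grp["time_h"].to_numpy(float)
        y = grp["value"].to_numpy(float)
        if len(np.unique(t)) < 2:
            return None
        try:
            _, k, _, _ = _fit_arrays(t, y, fix_y0, False)
        except RuntimeError:
            return None
        if k <= 0:
            return None
        halves.append(math.log(2) / k)
    return halves


def compare_half_lives(
    course_a: DecayCourse,
    course_b: DecayCourse,
    *,
    fix_y0: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> HalfLifeComparison:
    """Ratio t_half(a) / t_half(b) with bootstrap CI and a p-value.

    Both courses must fit as decaying.  The CI resamples each course's
    replicates independently and refits the pair.  The p-value is a
    two-sided equal-variance t-test on per-replicate log half-lives when
    every replicate supports an individual fit (>= 2 replicates per
    condition); otherwise it falls back to the bootstrap null (the
    fraction of bootstrap log-ratios crossing zero).
    """
    fit_a = fit_one_phase_decay(course_a, fix_y0=fix_y0)
    fit_b = fit_one_phase_decay(course_b, fix_y0=fix_y0)
    if not (fit_a.decaying and fit_b.decaying):
        raise ValueError("both courses must be decaying to compare half-lives")
    ratio = fit_a.t_half / fit_b.t_half

    rng = np.random.default_rng(seed)
    log_ratios = []
    for _ in range(n_boot):
        pair = []
        ok = True
        for course, fit in ((course_a, fit_a), (course_b, fit_b)):
            df = course.data
            reps = course.replicates
            if len(reps) > 1:
                chosen = rng.choice(len(reps), size=len(reps), replace=True)
                parts = [df[df["replicate"] == reps[i]] for i in chosen]
                bt = np.concatenate([p["time_h"].to_numpy(float) for p in parts])
                by = np.concatenate([p["value"].to_numpy(float) for p in parts])
            else:
                bt = df["time_h"].to_numpy(float)
                fitted = fit.y0 * np.exp(-fit.k * bt)
                resid = df["value"].to_numpy(float) - fitted
                by = np.clip(
                    fitted + rng.choice(resid, size=len(resid), replace=True),
                    1e-9,
                    None,
                )
            try:
                _, bk, _, _ = _fit_arrays(bt, by, fix_y0, False)
            except RuntimeError:
                ok = False
                break
            if bk <= 0:
                ok = False
                break
            pair.append(math.log(2) / bk)
        if ok:
            log_ratios.append(math.log(pair[0] / pair[1]))

    ci = None
    if log_ratios:
        lo, hi = np.percentile(log_ratios, [2.5, 97.5])
        ci = (float(math.exp(lo)), float(math.exp(hi)))

    halves_a = _per_replicate_halves(course_a, fix_y0)
    halves_b = _per_replicate_halves(course_b, fix_y0)
    if (
        halves_a is not None
        and halves_b is not None
        and len(halves_a) >= 2
        and len(halves_b) >= 2
    ):
        _, p = stats.ttest_ind(np.log(halves_a), np.log(halves_b), equal_var=True)
        p_method = "t_test_log_halflives"
    else:
        arr = np.asarray(log_ratios)
        frac = min((arr <= 0).mean(), (arr >= 0).mean()) if arr.size else float("nan")
        p = min(1.0, 2 * frac)
        p_method = "bootstrap"

    return HalfLifeComparison(
        ratio=float(ratio),
        ci=ci,
        p_value=float(p),
        t_half_a=fit_a.t_half,
        t_half_b=fit_b.t_half,
        p_method=p_method,
    )
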