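"""Segmented (piecewise-linear) regression of liveweight / value on age.

The model is a continuous piecewise-linear function of age in days with
``K`` break-points, plus additive offsets for breed category, calendar
month and year::

    E[y] = b0 + b1 * age + sum_k d_k * (age - psi_k)_+ + breed + month + year

where ``(x)_+ = max(x, 0)``.  ``psi_k`` are the break-point ages, ``b1``
the slope of the first segment and ``d_k`` the change in slope at
``psi_k``.  Break-points are estimated by iterative linearization: each
step adds, per break-point, an indicator column ``-1{age > psi_k}`` whose
coefficient (divided by the slope-change coefficient) gives the update to
``psi_k``; iteration stops when the break-points move by less than a
relative tolerance.  When the iteration fails, a profiled grid search on a
1-day age lattice minimising residual sum of squares is used instead.

Separate models are fitted per sex; the number of break-points is chosen
by incrementing ``K`` from 1 to 3 and keeping the smallest ``K`` beyond
which the gain in R-squared falls below a threshold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InsufficientStratumError,
    NonConvergenceError,
    SingularDesignError,
)

log = logging.getLogger(__name__)

#: covariates entering the model as unordered categoricals, in design order
CATEGORICAL_COVARIATES = ("breed_category", "month", "year")


# ---------------------------------------------------------------------------
# containers


@dataclass
class FitSpec:
    """Controls for one segmented fit.

    Parameters
    ----------
    n_breakpoints:
        Requested number of break-points ``K`` (1-3).
    init_psi:
        Starting break-points; defaults to the ``k/(K+1)`` age quantiles.
    tol:
        Convergence threshold on the largest break-point move, relative to
        the observed age range.
    max_iter:
        Iteration cap before the fallback kicks in.
    fallback:
        ``"grid_search"`` (profiled RSS search on a 1-day lattice) or
        ``"fail"`` (raise on non-convergence).
    """

    n_breakpoints: int = 2
    init_psi: Sequence[float] | None = None
    tol: float = 1e-4
    max_iter: int = 50
    fallback: str = "grid_search"

    def __post_init__(self) -> None:
        if not 1 <= self.n_breakpoints <= 3:
            raise ConfigurationError("n_breakpoints must be 1, 2 or 3")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")
        if self.fallback not in ("grid_search", "fail"):
            raise ConfigurationError("fallback must be 'grid_search' or 'fail'")


@dataclass
class SegmentedFit:
    """A fitted sex-specific segmented model for one response."""

    response: str
    sex: str
    breakpoints: np.ndarray          # psi_k, strictly increasing, age-days
    intercept: float                 # b0 at age 0, reference covariate levels
    base_slope: float                # b1, first-segment slope (per day)
    slope_changes: np.ndarray        # d_k, change in slope at each psi_k
    effects: dict                    # covariate -> {level -> additive offset}
    reference_levels: dict           # covariate -> reference level
    r_squared: float
    rss: float
    n_obs: int
    converged: bool
    iterations: int
    method: str = "iterative"        # "iterative" or "grid_search"
    candidates: dict = field(default_factory=dict, repr=False, compare=False)

    # -- prediction ---------------------------------------------------------

    def segment_slopes(self) -> np.ndarray:
        """Slopes of the K+1 segments, left to right."""
        return self.base_slope + np.concatenate([[0.0], np.cumsum(self.slope_changes)])

    def predict(self, age_days, breed_category=None, month=None, year=None):
        """Predict the response for scalar or array inputs.

        Covariate levels unseen during fitting fall back to the reference
        level (offset 0) with a logged warning; ``None`` means reference.
        """
        ages = np.asarray(age_days, dtype=float)
        if np.any(ages < 0):
            raise ValueError("negative age_days")
        out = self.intercept + self.base_slope * ages
        for psi, d in zip(self.breakpoints, self.slope_changes):
            out = out + d * np.clip(ages - psi, 0.0, None)
        covs = {"breed_category": breed_category, "month": month, "year": year}
        for cov, values in covs.items():
            if values is None:
                continue
            offsets = self.effects.get(cov, {})
            vals = np.asarray(values, dtype=object).ravel()
            mapped = np.empty(vals.shape, dtype=float)
            unseen = set()
            for i, v in enumerate(vals):
                key = str(v)
                if key in offsets:
                    mapped[i] = offsets[key]
                elif key == str(self.reference_levels.get(cov)):
                    mapped[i] = 0.0
                else:
                    mapped[i] = 0.0
                    unseen.add(key)
            if unseen:
                log.warning(
                    "%s levels %s unseen in the %s/%s fit; using reference level %s",
                    cov, sorted(unseen), self.response, self.sex,
                    self.reference_levels.get(cov),
                )
            mapped = mapped.reshape(np.shape(values)) if np.ndim(values) else mapped[0]
            out = out + mapped
        return float(out) if np.ndim(age_days) == 0 else out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "herdmass-segmented-fit/1",
            "response": self.response,
            "sex": self.sex,
            "breakpoints": [float(p) for p in self.breakpoints],
            "intercept": self.intercept,
            "base_slope": self.base_slope,
            "slope_changes": [float(d) for d in self.slope_changes],
            "effects": self.effects,
            "reference_levels": self.reference_levels,
            "r_squared": self.r_squared,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "iterations": self.iterations,
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SegmentedFit":
        return cls(
            response=d["response"],
            sex=d["sex"],
            breakpoints=np.asarray(d["breakpoints"], dtype=float),
            intercept=float(d["intercept"]),
            base_slope=float(d["base_slope"]),
            slope_changes=np.asarray(d["slope_changes"], dtype=float),
            effects={k: dict(v) for k, v in d["effects"].items()},
            reference_levels=dict(d["reference_levels"]),
            r_squared=float(d["r_squared"]),
            rss=float(d["rss"]),
            n_obs=int(d["n_obs"]),
            converged=bool(d["converged"]),
            iterations=int(d["iterations"]),
            method=d.get("method", "iterative"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SegmentedFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# sampling


def stratified_sample(records: pd.DataFrame, per_class_n: int, seed: int,
                      class_col: str = "animal_class") -> pd.DataFrame:
    """Draw ``per_class_n`` records per animal class, without replacement.

    The training samples are balanced across the six animal classes so that
    no class dominates the age axis; the sample size is set by the least
    frequent class.
    """
    if per_class_n < 1:
        raise ConfigurationError("per_class_n must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    for cls_name, grp in records.groupby(class_col, sort=True):
        if len(grp) < per_class_n:
            raise InsufficientStratumError(str(cls_name), len(grp), per_class_n)
        idx = rng.choice(len(grp), size=per_class_n, replace=False)
        parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# design matrix


def _dummy_design(df: pd.DataFrame) -> tuple[np.ndarray, list, dict]:
    """Reference-coded dummies for the categorical covariates.

    Returns the dummy block, column labels ``(covariate, level)`` and the
    reference level per covariate (earliest in sorted order).
    """
    blocks, labels, refs = [], [], {}
    for cov in CATEGORICAL_COVARIATES:
        levels = sorted(df[cov].astype(str).unique(), key=_level_key)
        refs[cov] = levels[0]
        vals = df[cov].astype(str).to_numpy()
        for lev in levels[1:]:
            blocks.append((vals == lev).astype(float))
            labels.append((cov, lev))
    block = np.column_stack(blocks) if blocks else np.empty((len(df), 0))
    return block, labels, refs


def _level_key(level: str):
    try:
        return (0, float(level), "")
    except ValueError:
        return (1, 0.0, level)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), rank


def _final_fit(ages, y, psi, dummies, labels, refs, response, sex,
               n_iter, converged, method) -> SegmentedFit:
    """OLS at fixed break-points; package coefficients into a SegmentedFit."""
    K = len(psi)
    U = np.clip(ages[:, None] - np.asarray(psi)[None, :], 0.0, None)
    X = np.column_stack([np.ones_like(ages), ages, U, dummies])
    beta, rss, rank = _ols(X, y)
    if rank < X.shape[1]:
        raise SingularDesignError(f"design rank {rank} < {X.shape[1]} columns")
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    effects: dict[str, dict[str, float]] = {c: {} for c in CATEGORICAL_COVARIATES}
    for (cov, lev), b in zip(labels, beta[2 + K:]):
        effects[cov][lev] = float(b)
    return SegmentedFit(
        response=response, sex=sex,
        breakpoints=np.asarray(psi, dtype=float),
        intercept=float(beta[0]), base_slope=float(beta[1]),
        slope_changes=np.asarray(beta[2:2 + K], dtype=float),
        effects=effects, reference_levels=refs,
        r_squared=r2, rss=rss, n_obs=len(y),
        converged=converged, iterations=n_iter, method=method,
    )


# ---------------------------------------------------------------------------
# iterative estimation


def fit_segmented(table: pd.DataFrame, response_col: str, spec: FitSpec | None = None,
                  *, sex: str = "all", response: str | None = None) -> SegmentedFit:
    """Fit a segmented regression of ``response_col`` on ``age_days``.

    ``table`` must carry ``age_days``, the response column and the
    categorical covariates ``breed_category``, ``month``, ``year``.
    """
    spec = spec or FitSpec()
    response = response or response_col
    df = table.dropna(subset=["age_days", response_col]).reset_index(drop=True)
    ages = df["age_days"].to_numpy(dtype=float)
    y = df[response_col].to_numpy(dtype=float)
    dummies, labels, refs = _dummy_design(df)
    K = spec.n_breakpoints
    n_params = 2 + K + dummies.shape[1]
    if len(y) <= n_params + 10:
        raise ConfigurationError(
            f"{len(y)} observations for {n_params} parameters; need > {n_params + 10}"
        )
    amin, amax = float(ages.min()), float(ages.max())
    if amax - amin < 2 * (K + 1):
        raise ConfigurationError("age range too narrow for the requested segments")

    if spec.init_psi is not None:
        psi = np.sort(np.asarray(spec.init_psi, dtype=float))
        if len(psi) != K:
            raise ConfigurationError("init_psi length must equal n_breakpoints")
    else:
        psi = np.quantile(ages, [(k + 1) / (K + 1) for k in range(K)])

    result = _iterate_psi(ages, y, psi, dummies, spec, amin, amax)
    if result is not None:
        psi_hat, n_iter = result
        return _final_fit(ages, y, psi_hat, dummies, labels, refs,
                          response, sex, n_iter, True, "iterative")
    if spec.fallback == "fail":
        raise NonConvergenceError(
            f"break-point iteration did not converge in {spec.max_iter} steps"
        )
    psi_hat = grid_search_breakpoints(ages, y, dummies, K)
    return _final_fit(ages, y, psi_hat, dummies, labels, refs,
                      response, sex, spec.max_iter, True, "grid_search")


def _iterate_psi(ages, y, psi, dummies, spec, amin, amax):
    """Muggeo-style update loop; returns (psi, iterations) or None on failure."""
    span = amax - amin
    # keep break-points a few observations away from either boundary
    srt = np.sort(ages)
    margin = min(5, len(srt) // 4)
    lo, hi = srt[margin] + 0.5, srt[-margin - 1] - 0.5
    ones = np.ones_like(ages)
    for it in range(1, spec.max_iter + 1):
        U = np.clip(ages[:, None] - psi[None, :], 0.0, None)
        V = -(ages[:, None] > psi[None, :]).astype(float)
        X = np.column_stack([ones, ages, U, V, dummies])
        beta, _, rank = _ols(X, y)
        if rank < X.shape[1]:
            return None
        K = len(psi)
        delta = beta[2:2 + K]
        gamma = beta[2 + K:2 + 2 * K]
        # a near-zero slope change leaves its break-point unidentified:
        # freeze that component instead of failing the whole iteration
        scale = max(np.max(np.abs(delta)), 1e-12)
        free = np.abs(delta) > 1e-8 * scale
        if not free.any():
            return psi, it
        step = np.where(free, gamma / np.where(free, delta, 1.0), 0.0)
        # step-halve until the updated break-points are ordered and interior
        factor = 1.0
        for _ in range(12):
            cand = psi + factor * step
            if np.all(cand > lo) and np.all(cand < hi) and np.all(np.diff(cand) > 1.0):
                break
            factor *= 0.5
        else:
            return None
        move = float(np.max(np.abs(factor * step)))
        psi = np.sort(psi + factor * step)
        if move / span < spec.tol:
            return psi, it
    return None


# ---------------------------------------------------------------------------
# profiled grid search (fallback and oracle route)


def grid_search_breakpoints(ages, y, dummies, K, lattice_step: float = 1.0,
                            min_gap: float = 2.0,
                            max_exhaustive: int = 500) -> np.ndarray:
    """Profiled RSS search for the break-points on an age lattice.

    For fixed break-points the model is linear, so the RSS is profiled by
    projecting the remaining hinge column(s) onto the orthogonal complement
    of the current design.  ``K = 1`` (any lattice) and small multi-break
    lattices are searched exhaustively; larger ``K >= 2`` problems use a
    coarse exhaustive pass followed by coordinate-wise refinement down to
    ``lattice_step`` resolution, which reaches the same optimum whenever
    the profiled RSS surface is locally well-behaved around the coarse
    minimum.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    srt = np.sort(ages)
    obs_margin = min(5, len(srt) // 4)
    amin, amax = srt[obs_margin], srt[-obs_margin - 1]
    full = np.arange(math.ceil(amin + 1), math.floor(amax - 1) + 1e-9, lattice_step)
    if len(full) < K:
        raise ConfigurationError("age range too narrow for grid search")

    X0 = np.column_stack([np.ones_like(ages), ages, dummies])
    Q0, _ = np.linalg.qr(X0)

    if K == 1 or len(full) <= max_exhaustive:
        best = _grid_recurse(ages, y, Q0, full, K, min_gap)
        if best is None:
            raise NonConvergenceError("grid search found no admissible break-points")
        return np.sort(np.asarray(best[1], dtype=float))

    # coarse exhaustive pass, then coordinate-wise local refinement
    coarse_step = (amax - amin) / (120.0 if K == 2 else 60.0)
    coarse = np.arange(math.ceil(amin + 1), math.floor(amax - 1) + 1e-9, coarse_step)
    best = _grid_recurse(ages, y, Q0, coarse, K, max(min_gap, coarse_step))
    if best is None:
        raise NonConvergenceError("grid search found no admissible break-points")
    psi = np.sort(np.asarray(best[1], dtype=float))
    for _ in range(2):   # two refinement sweeps are enough to stabilise
        for k in range(K):
            local = full[(full >= psi[k] - coarse_step) & (full <= psi[k] + coarse_step)]
            best_rss, best_p = np.inf, psi[k]
            for p in local:
                cand = np.sort(np.concatenate([psi[:k], [p], psi[k + 1:]]))
                if np.any(np.diff(cand) < min_gap):
                    continue
                rss = _rss_at(ages, y, Q0, cand)
                if rss < best_rss:
                    best_rss, best_p = rss, p
            psi[k] = best_p
            psi = np.sort(psi)
    return psi


def _gram_schmidt_append(Q, u):
    u_perp = u - Q @ (Q.T @ u)
    nrm = np.linalg.norm(u_perp)
    if nrm < 1e-10 * max(1.0, np.linalg.norm(u)):
        return None
    return np.column_stack([Q, u_perp / nrm])


def _rss_at(ages, y, Q0, psi):
    Q = Q0
    for p in psi:
        Q2 = _gram_schmidt_append(Q, np.clip(ages - p, 0.0, None))
        if Q2 is None:
            return np.inf
        Q = Q2
    r = y - Q @ (Q.T @ y)
    return float(r @ r)


def _grid_recurse(ages, y, Q, lattice, K, min_gap, start=0.0):
    """Best (rss, psi-list) over ordered lattice tuples; last level vectorised."""
    cand = lattice[lattice >= start]
    if K == 1:
        if len(cand) == 0:
            return None
        U = np.clip(ages[:, None] - cand[None, :], 0.0, None)
        U_perp = U - Q @ (Q.T @ U)
        norms2 = np.einsum("ij,ij->j", U_perp, U_perp)
        r = y - Q @ (Q.T @ y)
        proj = U_perp.T @ r
        rss0 = float(r @ r)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = np.where(norms2 > 1e-12, rss0 - proj**2 / norms2, np.inf)
        j = int(np.argmin(rss))
        if not np.isfinite(rss[j]):
            return None
        return float(rss[j]), [float(cand[j])]
    best = None
    for p in cand:
        Q2 = _gram_schmidt_append(Q, np.clip(ages - p, 0.0, None))
        if Q2 is None:
            continue
        sub = _grid_recurse(ages, y, Q2, lattice, K - 1, min_gap, start=p + min_gap)
        if sub is not None and (best is None or sub[0] < best[0]):
            best = (sub[0], [float(p)] + sub[1])
    return best


# ---------------------------------------------------------------------------
# break-point count selection


def select_breakpoint_count(table: pd.DataFrame, response_col: str,
                            spec: FitSpec | None = None, kmax: int = 3,
                            delta_r2_threshold: float = 0.01,
                            *, sex: str = "all",
                            response: str | None = None) -> SegmentedFit:
    """Choose the number of break-points by incremental R-squared.

    Fits ``K = 1 .. kmax`` and returns the smallest ``K`` whose successor
    improves R-squared by less than ``delta_r2_threshold`` — i.e. the point
    beyond which only minor improvements in fit occur.  All candidate fits
    are retained on the returned fit's ``candidates`` for audit.
    """
    if kmax > 3:
        raise ConfigurationError("kmax must be <= 3")
    base = spec or FitSpec()
    fits: dict[int, SegmentedFit] = {}
    ages = table["age_days"].dropna().to_numpy(dtype=float)
    for K in range(1, kmax + 1):
        starts: list = [None]   # default quantile initialisation
        if K - 1 in fits:
            # warm start: keep the previous break-points, seed the new one
            # in the widest remaining gap (keeps R-squared non-decreasing)
            prev = list(fits[K - 1].breakpoints)
            edges = [float(ages.min())] + prev + [float(ages.max())]
            gaps = np.diff(edges)
            j = int(np.argmax(gaps))
            starts.append(sorted(prev + [edges[j] + gaps[j] / 2.0]))
        for init in starts:
            kspec = FitSpec(n_breakpoints=K, init_psi=init, tol=base.tol,
                            max_iter=base.max_iter, fallback=base.fallback)
            try:
                cand = fit_segmented(table, response_col, kspec, sex=sex,
                                     response=response)
            except (NonConvergenceError, SingularDesignError,
                    ConfigurationError) as exc:
                log.warning("K=%d fit failed (%s); skipping start", K, exc)
                continue
            if K not in fits or cand.rss < fits[K].rss:
                fits[K] = cand
    if not fits:
        raise NonConvergenceError("no break-point count produced a valid fit")
    ks = sorted(fits)
    chosen = ks[-1]
    for i, K in enumerate(ks[:-1]):
        gain = fits[ks[i + 1]].r_squared - fits[K].r_squared
        if gain < delta_r2_threshold:
            chosen = K
            break
    fit = fits[chosen]
    fit.candidates = {K: f for K, f in fits.items()}
    return fit


# ---------------------------------------------------------------------------
# four-model convenience


def fit_by_sex(table: pd.DataFrame, response_col: str, spec: FitSpec | None = None,
               auto_select: bool = True, delta_r2_threshold: float = 0.01,
               response: str | None = None) -> dict[str, SegmentedFit]:
    """Fit one model per sex (the standard four-model layout: two responses
    x two sexes, with this called once per response)."""
    out = {}
    for sex_level, grp in table.groupby("sex", sort=True):
        if auto_select:
            out[str(sex_level)] = select_breakpoint_count(
                grp, response_col, spec, delta_r2_threshold=delta_r2_threshold,
                sex=str(sex_level), response=response)
        else:
            out[str(sex_level)] = fit_segmented(grp, response_col, spec,
                                                sex=str(sex_level), response=response)
    return out
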