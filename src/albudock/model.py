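"""Albumin binding model: fraction-bound algebra, the combined
docking-score/logP linear score, binder classification, and the
site-preference statistic.

The combined score is an affine combination of the ensemble-best docking
score (kcal/mol, more negative = better) and the octanol/water logP::

    combined = intercept + alpha * score + beta * logP

with published coefficients intercept = 25.41, alpha = -1.95,
beta = 7.68, fit by ordinary least squares of %HSA on the two
predictors.  Higher combined score means stronger predicted albumin
binding: alpha < 0 rewards more favorable docking, beta > 0 rewards
lipophilicity.

Fraction bound follows the single-site equilibrium isotherm at a fixed
physiological albumin concentration of 0.6 mM:

    fb = Ka [HSA] / (1 + Ka [HSA]),     Ki = 1 / Ka
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .docking import EnsembleScore

logger = logging.getLogger(__name__)

#: Physiological serum albumin concentration, molar (0.6 mM).
DEFAULT_ALBUMIN_CONC_M = 0.6e-3

#: Binder classification cutoffs on %HSA (strict inequalities; boundary
#: cases are logged).
WEAK_CUTOFF_PERCENT = 25.0
BINDER_CUTOFF_PERCENT = 80.0

#: Default |delta| threshold (kcal/mol) separating a "minimal" site II -
#: site I score gap (site I binder) from a significant one (site II).
DEFAULT_SITE_THRESHOLD = 2.0


# ---------------------------------------------------------------------------
# Fraction-bound algebra


def fb_from_percent(hsa_percent: float) -> float:
    """%HSA -> fraction bound (exact division by 100)."""
    if not 0.0 <= hsa_percent <= 100.0:
        raise ValueError(f"%HSA {hsa_percent} outside [0, 100]")
    return hsa_percent / 100.0


def percent_from_fb(fb: float) -> float:
    """Fraction bound -> %HSA (exact multiplication by 100)."""
    if not 0.0 <= fb <= 1.0:
        raise ValueError(f"fraction bound {fb} outside [0, 1]")
    return fb * 100.0


def ka_from_fb(fb: float, albumin_conc: float = DEFAULT_ALBUMIN_CONC_M) -> float:
    """Association constant (inverse concentration) from fraction bound.

    Inverts the single-site isotherm; ``fb = 1`` would require infinite
    affinity and raises.
    """
    if albumin_conc <= 0:
        raise ValueError("albumin concentration must be positive")
    if not 0.0 <= fb < 1.0:
        raise ValueError(f"fraction bound {fb} outside [0, 1)")
    return fb / ((1.0 - fb) * albumin_conc)


def fb_from_ka(ka: float, albumin_conc: float = DEFAULT_ALBUMIN_CONC_M) -> float:
    """Fraction bound from the association constant (single-site isotherm)."""
    if albumin_conc <= 0:
        raise ValueError("albumin concentration must be positive")
    if ka < 0:
        raise ValueError("association constant must be non-negative")
    x = ka * albumin_conc
    return x / (1.0 + x)


def ki_from_ka(ka: float) -> float:
    """Dissociation-type constant: Ki = 1/Ka."""
    if ka <= 0:
        raise ValueError("Ka must be positive to invert")
    return 1.0 / ka


def ka_from_ki(ki: float) -> float:
    if ki <= 0:
        raise ValueError("Ki must be positive to invert")
    return 1.0 / ki


@dataclass
class BindingConstants:
    """Equilibrium description of one ligand's albumin binding."""

    fb: float
    albumin_conc: float = DEFAULT_ALBUMIN_CONC_M

    def __post_init__(self) -> None:
        if not 0.0 <= self.fb <= 1.0:
            raise ValueError(f"fb {self.fb} outside [0, 1]")

    @property
    def hsa_percent(self) -> float:
        return percent_from_fb(self.fb)

    @property
    def ka(self) -> float:
        return ka_from_fb(self.fb, self.albumin_conc)

    @property
    def ki(self) -> float:
        return ki_from_ka(self.ka)


# ---------------------------------------------------------------------------
# Combined linear score


@dataclass
class CombinedModel:
    """The linear scorer over (docking score, logP), with fit metadata."""

    intercept: float = 25.41
    alpha: float = -1.95  # weight on docking score (kcal/mol)
    beta: float = 7.68    # weight on logP
    fit_meta: Optional[dict] = None

    def __post_init__(self) -> None:
        for name in ("intercept", "alpha", "beta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def save(self, path: Path | str) -> None:
        lines = [
            f"intercept = {self.intercept!r}",
            f"alpha = {self.alpha!r}",
            f"beta = {self.beta!r}",
        ]
        if self.fit_meta:
            for key in ("n", "n_boot", "seed"):
                if key in self.fit_meta:
                    lines.append(f"{key} = {self.fit_meta[key]!r}")
            for coef, (lo, hi) in self.fit_meta.get("ci95", {}).items():
                lines.append(f"ci95_{coef} = {lo!r} {hi!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: Path | str) -> "CombinedModel":
        values: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            key, val = (tok.strip() for tok in line.split("=", 1))
            values[key] = val
        meta: dict = {}
        ci = {
            key[5:]: tuple(float(t) for t in val.split())
            for key, val in values.items()
            if key.startswith("ci95_")
        }
        if ci:
            meta["ci95"] = ci
        for key in ("n", "n_boot", "seed"):
            if key in values:
                meta[key] = int(values[key])
        return cls(
            intercept=float(values["intercept"]),
            alpha=float(values["alpha"]),
            beta=float(values["beta"]),
            fit_meta=meta or None,
        )


def combined_score(
    xp_score, logp, model: Optional[CombinedModel] = None
):
    """Evaluate the combined score; accepts scalars or arrays.

    Raises on non-finite input — a missing docking score must be handled
    upstream, not propagated as NaN.
    """
    if model is None:
        model = CombinedModel()
    xp = np.asarray(xp_score, dtype=float)
    lp = np.asarray(logp, dtype=float)
    if not (np.all(np.isfinite(xp)) and np.all(np.isfinite(lp))):
        raise ValueError("combined_score requires finite inputs")
    out = model.intercept + model.alpha * xp + model.beta * lp
    if out.ndim == 0:
        return float(out)
    return out


def fit_combined(
    xp_score: Sequence[float],
    logp: Sequence[float],
    hsa_percent: Sequence[float],
    *,
    n_boot: int = 1000,
    seed: int = 0,
) -> CombinedModel:
    """Fit (intercept, alpha, beta) by OLS of %HSA on (score, logP).

    Coefficient uncertainty comes from a seeded case-resampling
    bootstrap: rows are resampled with replacement ``n_boot`` times and
    95% percentile intervals of the refit coefficients are stored in
    ``fit_meta['ci95']``.

    Raises on fewer than 3 records or exactly collinear predictors.
    """
    xp = np.asarray(xp_score, dtype=float)
    lp = np.asarray(logp, dtype=float)
    y = np.asarray(hsa_percent, dtype=float)
    if not (xp.shape == lp.shape == y.shape):
        raise ValueError("xp_score, logp, hsa_percent must have equal length")
    n = xp.size
    if n < 3:
        raise ValueError(f"need at least 3 records to fit, got {n}")
    X = np.column_stack([np.ones(n), xp, lp])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("predictors are collinear; cannot fit")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        if np.linalg.matrix_rank(Xb) < 3:  # degenerate resample; redraw
            idx = rng.integers(0, n, size=n)
            Xb, yb = X[idx], y[idx]
        boot[b], *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    names = ("intercept", "alpha", "beta")
    meta = {
        "n": int(n),
        "n_boot": int(n_boot),
        "seed": int(seed),
        "ci95": {name: (float(l), float(h)) for name, l, h in zip(names, lo, hi)},
    }
    return CombinedModel(
        intercept=float(coef[0]), alpha=float(coef[1]), beta=float(coef[2]),
        fit_meta=meta,
    )


# ---------------------------------------------------------------------------
# Classification


def classify_binder(hsa_percent: float) -> str:
    """Map %HSA to ``weak`` (<25), ``binder`` (>80) or ``intermediate``.

    Inequalities are strict; compounds sitting exactly on a cutoff are
    classified intermediate and logged so boundary handling is auditable.
    """
    if not 0.0 <= hsa_percent <= 100.0:
        raise ValueError(f"%HSA {hsa_percent} outside [0, 100]")
    if hsa_percent in (WEAK_CUTOFF_PERCENT, BINDER_CUTOFF_PERCENT):
        logger.info("boundary %%HSA value %s classified intermediate", hsa_percent)
    if hsa_percent < WEAK_CUTOFF_PERCENT:
        return "weak"
    if hsa_percent > BINDER_CUTOFF_PERCENT:
        return "binder"
    return "intermediate"


@dataclass
class SitePreference:
    """Site I vs site II call from the per-site score gap.

    ``delta`` is best site II score minus best site I score (kcal/mol).
    A minimal gap indicates a site I binder; a significant gap — the
    small site II pocket scoring markedly differently — indicates a
    site II binder.  ``delta`` is kept raw as the continuous decision
    statistic for ROC analysis.
    """

    ligand_id: str
    delta: Optional[float]
    predicted_site: str  # site_I | site_II | indeterminate


def site_preference(
    ensemble: EnsembleScore, threshold: float = DEFAULT_SITE_THRESHOLD
) -> SitePreference:
    """Classify site preference from an ensemble score's per-site minima."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if ensemble.best_site_I is None or ensemble.best_site_II is None:
        return SitePreference(ensemble.ligand_id, None, "indeterminate")
    delta = ensemble.best_site_II - ensemble.best_site_I
    predicted = "site_I" if abs(delta) <= threshold else "site_II"
    return SitePreference(ensemble.ligand_id, delta, predicted)
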