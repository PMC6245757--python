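"""Jackknife variable-contribution analysis on the envelope model.

The protocol mirrors the classic leave-one-variable-out jackknife: the
occurrence climates are split 75/25 into train and test; for each
variable a model is fitted on the train rows using only that variable
(*with-only*) and using every variable except it (*without*), alongside
the full model.  A model's score is its discrimination: the fraction of
test occurrences falling inside the fitted envelope (distance 0) minus
the fraction of background grid cells inside it.  Inclusion alone
cannot rank variables — dropping a variable can only relax a
rectangular envelope, so test inclusion never decreases — whereas a
constraining variable's removal admits much more background, lowering
the discrimination score.  A variable's contribution is
``max(0, score(all) - score(without v))`` normalized so contributions
sum to 100%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envelope import NormalizationParams, build_profile, point_distance

logger = logging.getLogger("nichebox")

__all__ = ["SplitSpec", "split", "jackknife"]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition parameters."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must be in (0, 1)")


def split(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive row split: round(n*f) train rows, rest test."""
    if n < 4:
        raise ValueError("need at least 4 rows to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(round(n * spec.train_fraction))
    n_train = min(max(n_train, 1), n - 1)  # keep both sides non-empty
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def _inclusion_rate(profile, values: np.ndarray) -> float:
    norm = profile.params.normalize(values)
    d = np.min(
        [
            point_distance(norm, lo, hi)
            for lo, hi in zip(profile.clusters.scopes_lo, profile.clusters.scopes_hi)
        ],
        axis=0,
    )
    return float(np.mean(d == 0))


def _score(profile, test: np.ndarray, background: np.ndarray) -> float:
    return _inclusion_rate(profile, test) - _inclusion_rate(profile, background)


def jackknife(climates: np.ndarray, soils, background: np.ndarray,
              params: NormalizationParams, spec: SplitSpec | None = None,
              k: int = 1, seed: int = 0, species: str = "species") -> pd.DataFrame:
    """Per-variable contribution table for one species.

    Parameters
    ----------
    climates : (n, n_var) native-unit occurrence climate matrix.
    soils : soil class per occurrence (passed through to profile fits).
    background : (m, n_var) native-unit climate matrix of grid cells the
        model could in principle predict (typically all valid cells or a
        subsample); defines the discrimination baseline.
    params : layer normalization statistics for the full variable set.
    """
    spec = spec or SplitSpec()
    climates = np.asarray(climates, dtype=float)
    background = np.asarray(background, dtype=float)
    variables = list(params.variables)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least two variables")
    train_idx, test_idx = split(climates.shape[0], spec)
    train, test = climates[train_idx], climates[test_idx]
    soils = np.asarray(soils)
    tr_soil = soils[train_idx]

    # a variable constant on the training rows yields a degenerate
    # zero-width envelope slab that would zero every model's background
    # inclusion; such variables are left out of the fitted models
    active = [v for v in variables if np.ptp(train[:, variables.index(v)]) > 0]
    for v in variables:
        if v not in active:
            warnings.warn(f"variable {v!r} is constant on the training rows")
    if len(active) < 2:
        raise ValueError("jackknife needs at least two non-degenerate variables")

    def fit_and_score(var_subset):
        cols = [variables.index(v) for v in var_subset]
        sub = params.subset(var_subset)
        prof = build_profile(train[:, cols], tr_soil, species, sub, k=k, seed=seed)
        return prof, _score(prof, test[:, cols], background[:, cols])

    _, full_score = fit_and_score(active)
    rows = []
    raw = []
    for v in variables:
        _, only_score = fit_and_score([v])
        if v in active:
            _, without_score = fit_and_score([u for u in active if u != v])
            contrib = max(0.0, full_score - without_score)
        else:
            without_score = full_score
            contrib = 0.0
        raw.append(contrib)
        rows.append({"variable": v, "with_only_score": only_score,
                     "without_score": without_score, "full_score": full_score})
    total = sum(raw)
    if total > 0:
        norm = [100.0 * c / total for c in raw]
    else:  # nothing discriminates: spread evenly
        norm = [100.0 / len(raw)] * len(raw)
    for row, c, pct in zip(rows, raw, norm):
        row["raw_drop"] = c
        row["contribution_pct"] = pct
    return pd.DataFrame(rows)
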