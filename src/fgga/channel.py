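"""Gaussian noise-channel model of classifier scores.

A real-valued per-term classifier score y is treated as the output of an
additive white Gaussian noise channel fed with the latent annotation
x in {+1, -1}:  y = x + z,  z ~ N(0, eta).  Under equal priors the channel
posterior is the logistic

    p(x | y) = 1 / (1 + exp(-2 y x / eta)),

which is the local evidence each observed score contributes to the factor
graph.  The per-term variance eta is estimated from positively annotated
validation samples as  eta_hat = sum_l (y_l - 1)^2 / (L+ - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InsufficientDataError

#: Lower clamp for channel variances.  A zero variance turns the posterior
#: into a hard 0/1 indicator and can annihilate message products; the floor
#: keeps the channel numerically safe while remaining effectively
#: deterministic.
ETA_FLOOR = 1e-6


def _check_eta(eta) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < ETA_FLOOR):
        raise ValueError(
            f"variance below floor {ETA_FLOOR}; clamp explicitly before calling"
        )
    return eta


def channel_posterior(y, x, eta):
    """p(x | y) of the Gaussian channel; x must be +1 or -1.

    Vectorised over y and eta.  Satisfies
    ``channel_posterior(y, +1, eta) + channel_posterior(y, -1, eta) == 1``.
    """
    if x not in (+1, -1):
        raise ValueError(f"x must be +1 or -1, got {x!r}")
    eta = _check_eta(eta)
    return expit(2.0 * np.asarray(y, dtype=float) * x / eta)


def leaf_message(y, eta):
    """Normalised message (p_+, p_-) the channel factor sends to its term."""
    eta = _check_eta(eta)
    p_plus = expit(2.0 * np.asarray(y, dtype=float) / eta)
    return p_plus, 1.0 - p_plus


def estimate_variance(
    pos_scores: Sequence[float],
    eta_floor: float = ETA_FLOOR,
    term: str | None = None,
) -> float:
    """Unbiased channel-variance estimate from positive validation scores.

    Uses the latent value x=1 for every positive sample:
    eta_hat = sum (y - 1)^2 / (L+ - 1), clamped below at *eta_floor*.
    """
    scores = np.asarray(list(pos_scores), dtype=float)
    if scores.size < 2:
        where = f" for term {term!r}" if term else ""
        raise InsufficientDataError(
            f"variance estimation needs >= 2 positive samples{where}, "
            f"got {scores.size}"
        )
    raw = float(np.sum((scores - 1.0) ** 2) / (scores.size - 1))
    return max(raw, eta_floor)


def estimate_variances(
    scores: pd.DataFrame, labels: pd.DataFrame, eta_floor: float = ETA_FLOOR
) -> pd.Series:
    """Per-term variance estimates from the positive rows of each column."""
    out = {}
    for term in scores.columns:
        pos = scores.loc[labels[term] == 1, term]
        out[term] = estimate_variance(pos, eta_floor=eta_floor, term=term)
    return pd.Series(out)


@dataclass
class ScoreMatrix:
    """Samples x terms real-valued scores plus per-term channel variances."""

    scores: pd.DataFrame
    variances: pd.Series | None = None

    def __post_init__(self):
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite")
        if self.variances is not None:
            self.variances = self.variances.reindex(self.scores.columns)
            if self.variances.isna().any():
                missing = self.variances.index[self.variances.isna()]
                raise ValueError(f"missing variance for terms {list(missing)[:5]}")
            _check_eta(self.variances.to_numpy())

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def terms(self) -> list[str]:
        return list(self.scores.columns)

    def write_tsv(self, scores_path, variances_path=None) -> None:
        self.scores.to_csv(scores_path, sep="\t", index_label="gene")
        if variances_path is not None:
            if self.variances is None:
                raise ValueError("no variances to write")
            self.variances.rename("variance").to_csv(
                variances_path, sep="\t", index_label="term"
            )

    @classmethod
    def read_tsv(cls, scores_path, variances_path=None) -> "ScoreMatrix":
        scores = pd.read_csv(scores_path, sep="\t", index_col="gene").rename_axis(None)
        variances = None
        if variances_path is not None:
            variances = pd.read_csv(variances_path, sep="\t", index_col="term")[
                "variance"
            ].rename_axis(None)
        return cls(scores=scores, variances=variances)
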