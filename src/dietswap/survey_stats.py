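"""Complex-survey inference: balanced repeated replication with Fay's
adjustment, replicate-based standard errors, unequal-variance t-tests and
effect-size classification.

The design assumed throughout is stratified with exactly two primary
sampling units (PSUs) per stratum.  Each BRR replicate selects one PSU per
stratum via a row of a Hadamard matrix; with Fay coefficient ``f`` the
selected PSU's weight is multiplied by ``2 - f`` and the complement's by
``f``, and the replicate variance is rescaled by ``1 / (R (1 - f)^2)``.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
import pandas as pd
from scipy.linalg import hadamard
from scipy.stats import norm, t as t_dist


@dataclasses.dataclass
class ReplicateWeights:
    """Base weight plus R replicate weight columns per participant."""

    participant_id: np.ndarray
    base: np.ndarray
    replicates: np.ndarray  # shape (n, R)
    fay: float

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]

    def as_frame(self) -> pd.DataFrame:
        """Replicate weights as columns, for export alongside participants."""
        df = pd.DataFrame({"participant_id": self.participant_id, "weight": self.base})
        for r in range(self.n_replicates):
            df[f"brr_{r + 1}"] = self.replicates[:, r]
        return df


@dataclasses.dataclass
class EffectClassification:
    pct_change: float
    p_value: float
    label: str  # no_change | marginal | modest | strong


def make_brr_weights(
    participants: pd.DataFrame,
    fay: float = 0.7,
    n_replicates: int = 32,
    weight_col: str = "weight_day1",
) -> ReplicateWeights:
    """Construct Fay-adjusted BRR replicate weights from the survey design.

    Requires exactly 2 PSUs per stratum and ``n_strata <= R - 1``.  Strata
    are assigned to Hadamard columns in sorted-key order, so the replicate
    pattern is deterministic for a given design.
    """
    # fay = 1 is a degenerate construction (replicates equal base weights);
    # it is allowed here but rejected by brr_se, whose variance rescaling
    # divides by (1 - fay)^2.
    if not 0.0 <= fay <= 1.0:
        raise ValueError(f"fay must be in [0, 1], got {fay}")
    R = n_replicates
    if R < 2 or (R & (R - 1)) != 0:
        raise ValueError(f"no Sylvester Hadamard matrix of order {R}")
    psus = participants.groupby("stratum_id")["psu_id"].unique().sort_index()
    for stratum, vals in psus.items():
        if len(vals) != 2:
            raise ValueError(
                f"stratum {stratum!r} has {len(vals)} PSU(s); BRR needs exactly 2"
            )
    strata = list(psus.index)
    if len(strata) > R - 1:
        raise ValueError(f"{len(strata)} strata exceed R - 1 = {R - 1}")
    H = hadamard(R)

    base = participants[weight_col].to_numpy(dtype=float)
    # first PSU (sorted) of stratum h follows Hadamard column h + 1
    first_psu = {s: sorted(v)[0] for s, v in psus.items()}
    col_of = {s: h + 1 for h, s in enumerate(strata)}
    sign = np.array([
        H[:, col_of[s]] * (1 if p == first_psu[s] else -1)
        for s, p in zip(participants["stratum_id"], participants["psu_id"])
    ])  # shape (n, R); +1 = selected (up-weighted)
    factors = np.where(sign > 0, 2.0 - fay, fay)
    return ReplicateWeights(
        participant_id=participants["participant_id"].to_numpy(),
        base=base,
        replicates=base[:, None] * factors,
        fay=fay,
    )


def brr_se(
    estimator: Callable[[pd.DataFrame, np.ndarray], float],
    data: pd.DataFrame,
    repweights: ReplicateWeights,
) -> tuple[float, float]:
    """Point estimate (base weights) and Fay-BRR standard error.

    ``estimator(data, weights)`` must be deterministic.  The variance is
    ``sum_r (theta_r - theta_0)^2 / (R (1 - fay)^2)``.
    """
    if repweights.fay >= 1.0:
        raise ValueError("fay must be < 1 for variance estimation")
    theta0 = float(estimator(data, repweights.base))
    R = repweights.n_replicates
    devs = np.empty(R)
    for r in range(R):
        try:
            devs[r] = float(estimator(data, repweights.replicates[:, r])) - theta0
        except Exception as exc:
            raise RuntimeError(f"estimator failed on replicate {r + 1}") from exc
    var = (devs ** 2).sum() / (R * (1.0 - repweights.fay) ** 2)
    return theta0, float(np.sqrt(var))


def weighted_mean(values: np.ndarray | pd.Series, weights: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float((v * w).sum() / w.sum())


def ttest_unequal(
    est1: float, se1: float, est2: float, se2: float,
    df_policy: int | str = "strata",
    n_strata: int | None = None,
) -> tuple[float, float]:
    """Unequal-variance t-test on two estimates with their standard errors.

    ``df_policy``: an integer degrees of freedom, ``"strata"`` (use
    ``n_strata``, the design df of a two-PSU stratified sample), or
    ``"normal"`` for the normal approximation.
    """
    if se1 < 0 or se2 < 0 or (se1 == 0 and se2 == 0):
        raise ValueError("needs nonnegative SEs, not both zero")
    t = (est1 - est2) / float(np.hypot(se1, se2))
    if df_policy == "normal":
        p = 2.0 * norm.sf(abs(t))
    else:
        if df_policy == "strata":
            if n_strata is None:
                raise ValueError("df_policy='strata' requires n_strata")
            df = n_strata
        else:
            df = int(df_policy)
        p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(p)


def classify_effect(pct_change: float, p_value: float) -> EffectClassification:
    """Label a relative change by size and significance.

    Non-significant (p >= 0.05) differences are ``no_change``; significant
    changes below 5% in magnitude are ``marginal``, between 5% and 10%
    inclusive ``modest``, and above 10% ``strong``.
    """
    if not (np.isfinite(pct_change) and np.isfinite(p_value)):
        raise ValueError("pct_change and p_value must be finite")
    if p_value >= 0.05:
        label = "no_change"
    elif abs(pct_change) < 5.0:
        label = "marginal"
    elif abs(pct_change) <= 10.0:
        label = "modest"
    else:
        label = "strong"
    return EffectClassification(pct_change, p_value, label)
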