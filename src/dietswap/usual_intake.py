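"""Usual-intake distribution estimation from repeated 24-h recalls.

This is a deliberately simplified two-part measurement-error model in the
spirit of the National Cancer Institute usual-intake method:

* **Ubiquitous** constituents (consumed by most people on most days, e.g.
  fiber or refined grains): day intakes are modeled on a transformed scale
  (log by default, Box-Cox optional) as person mean + day deviation, with
  covariate adjustment for weekend and recall sequence.  Covariate effects
  come from survey-weighted least squares; the within-person variance is
  the weighted mean squared half-difference of the two recalls; the
  between-person variance is the total residual variance minus the
  within-person part, floored at zero (moment decomposition, not maximum
  likelihood).

* **Episodic** constituents (not consumed by most people on most days,
  e.g. whole grains): a consumption-probability part — per-person observed
  frequency shrunk toward the weighted population rate via a beta-binomial
  moment fit — multiplied by an independent amount part fit on consumption
  days only.  No correlation between probability and amount is modeled.

The usual-intake distribution is obtained by Monte Carlo: person effects
are drawn on the transformed scale, back-transformed with a within-person
variance adjustment (Gauss-Hermite integration over the day distribution),
and summarized into percentiles and threshold proportions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Gauss-Hermite node count for the back-transformation integral
_GH_NODES = 30


@dataclasses.dataclass
class EpisodicPart:
    """Beta-binomial consumption-probability submodel."""

    pop_rate: float          # weighted population consumption rate (mu)
    prior_strength: float    # beta prior strength M = a + b
    person_p: pd.Series      # shrunken per-person probabilities

    def shrunken_p(self, k: int, n: int) -> float:
        """Posterior-mean consumption probability for k-of-n observed days."""
        return (k + self.prior_strength * self.pop_rate) / (n + self.prior_strength)


@dataclasses.dataclass
class UsualIntakeModel:
    transformation: str            # "log" | "box_cox"
    lam: float                     # Box-Cox lambda (0 = log)
    offset: float                  # added before transform (half-minimum rule)
    mu: float                      # transformed-scale mean at covariate expectation
    coef_weekend: float
    coef_recall2: float
    var_between: float
    var_within: float
    episodic: EpisodicPart | None = None

    def __post_init__(self) -> None:
        if self.var_between < 0 or self.var_within < 0:
            raise ValueError("variance components must be nonnegative")


@dataclasses.dataclass
class UsualIntakeDistribution:
    mean: float
    se: float                       # Monte-Carlo SE of the mean
    percentiles: pd.Series          # index 1..99
    proportion_above: dict[float, float]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.percentiles.to_numpy()) < -1e-12):
            raise ValueError("percentiles must be nondecreasing")


def _transform(x: np.ndarray, transformation: str, lam: float) -> np.ndarray:
    if transformation == "log":
        return np.log(x)
    if transformation == "box_cox":
        if lam == 0:
            return np.log(x)
        return (x ** lam - 1.0) / lam
    raise ValueError(f"unknown transformation {transformation}")


def _back_transform(y: np.ndarray, transformation: str, lam: float,
                    offset: float) -> np.ndarray:
    if transformation == "log" or lam == 0:
        x = np.exp(y)
    else:
        x = np.maximum(lam * y + 1.0, 0.0) ** (1.0 / lam)
    return np.maximum(x - offset, 0.0)


def fit_ubiquitous(
    day_values: pd.DataFrame,
    weights: pd.Series | np.ndarray | None = None,
    transformation: str = "log",
    lam: float = 0.0,
) -> UsualIntakeModel:
    """Fit the measurement-error model for a ubiquitously consumed outcome.

    ``day_values`` needs columns ``participant_id``, ``value``, ``weekend``
    (0/1) and ``recall2`` (0/1, second recall); one row per person-day.
    ``weights`` are per-row survey weights (frequency-weight role).  Zero
    values are offset by half the minimum positive value before the
    transform.  At least one person must contribute two recalls, or the
    within-person variance is not identifiable.
    """
    df = day_values.copy()
    if weights is None:
        df["_w"] = 1.0
    else:
        df["_w"] = np.asarray(weights, dtype=float)

    vals = df["value"].to_numpy(dtype=float)
    offset = 0.0
    if (vals <= 0).any():
        positive = vals[vals > 0]
        if positive.size == 0:
            raise ValueError("all values are zero; nothing to fit")
        offset = float(positive.min()) / 2.0
    y = _transform(vals + offset, transformation, lam)

    X = sm.add_constant(df[["weekend", "recall2"]].to_numpy(dtype=float))
    fit = sm.WLS(y, X, weights=df["_w"].to_numpy()).fit()
    b0, bw, br = fit.params
    resid = y - X @ fit.params

    df = df.assign(_resid=resid)
    two = df.groupby("participant_id").filter(lambda g: len(g) >= 2)
    if two.empty:
        raise ValueError("no person with 2 recalls; within-person variance "
                         "not identifiable")
    # weighted mean squared half-difference across persons with two recalls
    per = two.groupby("participant_id").agg(
        d=("_resid", lambda r: (r.iloc[0] - r.iloc[1]) ** 2 / 2.0),
        w=("_w", "mean"),
    )
    var_within = float((per["d"] * per["w"]).sum() / per["w"].sum())
    w = df["_w"].to_numpy()
    var_total = float((w * resid ** 2).sum() / w.sum())
    var_between = max(0.0, var_total - var_within)

    # population mean on the transformed scale, averaged over the weekend
    # distribution (2 weekend days in 7) at first-recall reference
    mu = float(b0 + bw * (2.0 / 7.0))
    return UsualIntakeModel(
        transformation=transformation, lam=lam, offset=offset, mu=mu,
        coef_weekend=float(bw), coef_recall2=float(br),
        var_between=var_between, var_within=var_within,
    )


def fit_episodic(
    day_values: pd.DataFrame,
    weights: pd.Series | np.ndarray | None = None,
    transformation: str = "log",
    lam: float = 0.0,
) -> UsualIntakeModel:
    """Fit the two-part model for an episodically consumed outcome.

    The probability part shrinks each person's observed consumption
    frequency toward the weighted population rate with strength from a
    beta-binomial moment fit; the amount part is :func:`fit_ubiquitous`
    restricted to consumption days.  Usual intake is the product of the two
    parts, taken as independent.
    """
    df = day_values.copy()
    if weights is None:
        df["_w"] = 1.0
    else:
        df["_w"] = np.asarray(weights, dtype=float)
    consumed = df["value"] > 0
    if not consumed.any():
        raise ValueError("no consumption days observed")

    per = df.assign(_c=consumed.astype(float)).groupby("participant_id").agg(
        k=("_c", "sum"), n=("_c", "size"), w=("_w", "mean"),
    )
    phat = per["k"] / per["n"]
    mu = float((phat * per["w"]).sum() / per["w"].sum())
    # beta-binomial moment fit among 2-recall persons:
    # Var(k/n) = mu (1-mu) (1 + (n-1) rho) / n  with rho = 1 / (M + 1)
    two = per[per["n"] == 2]
    if len(two) and 0 < mu < 1:
        p2 = two["k"] / 2.0
        m2 = float((p2 * two["w"]).sum() / two["w"].sum())
        s2 = float((two["w"] * (p2 - m2) ** 2).sum() / two["w"].sum())
        rho = 2.0 * s2 / (mu * (1.0 - mu)) - 1.0
    else:
        rho = 0.0
    rho = float(np.clip(rho, 0.01, 0.99))
    M = 1.0 / rho - 1.0

    shrunk = (per["k"] + M * mu) / (per["n"] + M)
    episodic = EpisodicPart(pop_rate=mu, prior_strength=float(M), person_p=shrunk)

    amount = fit_ubiquitous(
        df[consumed], df.loc[consumed, "_w"], transformation, lam,
    )
    return dataclasses.replace(amount, episodic=episodic)


def _usual_amounts(model: UsualIntakeModel, u: np.ndarray) -> np.ndarray:
    """Usual (long-run mean) daily amount for person effects ``u``.

    Integrates the back-transform over the day-deviation distribution with
    Gauss-Hermite quadrature.
    """
    nodes, gh_w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    gh_w = gh_w / gh_w.sum()
    sd_w = np.sqrt(model.var_within)
    y = (model.mu + u)[:, None] + sd_w * nodes[None, :]
    x = _back_transform(y, model.transformation, model.lam, model.offset)
    return x @ gh_w


def usual_distribution(
    model: UsualIntakeModel,
    n_mc: int = 20000,
    seed: int = 0,
    thresholds: tuple[float, ...] = (),
) -> UsualIntakeDistribution:
    """Monte-Carlo usual-intake distribution for a fitted model.

    Simulates ``n_mc`` persons (person effect on the transformed scale,
    plus a beta-distributed consumption probability for episodic models)
    and summarizes usual intakes into mean, percentiles 1-99 and the
    proportion above each requested threshold.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000")
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, np.sqrt(model.var_between), size=n_mc)
    usual = _usual_amounts(model, u)
    if model.episodic is not None:
        e = model.episodic
        a = e.prior_strength * e.pop_rate
        b = e.prior_strength * (1.0 - e.pop_rate)
        p = rng.beta(max(a, 1e-9), max(b, 1e-9), size=n_mc)
        usual = usual * p
    pct = pd.Series(
        np.percentile(usual, np.arange(1, 100)), index=np.arange(1, 100)
    )
    return UsualIntakeDistribution(
        mean=float(usual.mean()),
        se=float(usual.std(ddof=1) / np.sqrt(n_mc)),
        percentiles=pct,
        proportion_above={
            float(t): float((usual > t).mean()) for t in thresholds
        },
    )
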