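"""Monte Carlo propagation of exposure-parameter and concentration
uncertainty through the risk equations, with rank-correlation sensitivity.

Each uncertain input gets a distribution (fixed, normal, lognormal,
triangular or uniform, optionally truncated); the risk function is
evaluated on n independent joint draws and summarized by its empirical
mean and 5th/50th/95th percentiles (linear-interpolation, "type 7"
quantiles). One global seed drives everything; per-parameter substreams
are spawned from it so draws are independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
from scipy import stats

from .datatypes import ValidationError

_MAX_TRUNC_RETRIES = 1000


@dataclass(frozen=True)
class Dist:
    """Distribution spec for one parameter.

    family: fixed | normal | uniform | triangular | lognormal.
    For lognormal, a/b are the log-scale mu and sigma unless
    ``moments=True``, in which case they are the arithmetic mean and sd and
    the log-scale parameters are moment-matched:
    sigma_log^2 = ln(1 + sd^2/mean^2), mu_log = ln(mean) - sigma_log^2/2.
    lower/upper optionally truncate by rejection.
    """

    family: str
    a: float
    b: float = 0.0
    c: float = 0.0
    lower: Optional[float] = None
    upper: Optional[float] = None
    moments: bool = False

    def __post_init__(self) -> None:
        families = ("fixed", "normal", "uniform", "triangular", "lognormal")
        if self.family not in families:
            raise ValidationError(f"unknown distribution family {self.family!r}")

    def _draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.a)
        if self.family == "normal":
            return rng.normal(self.a, self.b, n)
        if self.family == "uniform":
            return rng.uniform(self.a, self.b, n)
        if self.family == "triangular":
            return rng.triangular(self.a, self.b, self.c, n)
        # lognormal
        if self.moments:
            mean, sd = self.a, self.b
            if mean <= 0:
                raise ValidationError("lognormal moment-matching needs mean > 0")
            s2 = np.log1p((sd / mean) ** 2)
            mu, sigma = np.log(mean) - s2 / 2.0, np.sqrt(s2)
        else:
            mu, sigma = self.a, self.b
        return rng.lognormal(mu, sigma, n)

    def sample(self, rng: np.random.Generator, n: int, name: str = "?") -> np.ndarray:
        """n draws, rejection-resampled into [lower, upper] if truncated."""
        x = self._draw(rng, n)
        if self.lower is None and self.upper is None:
            return x
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        for _ in range(_MAX_TRUNC_RETRIES):
            bad = (x < lo) | (x > hi)
            if not bad.any():
                return x
            x[bad] = self._draw(rng, int(bad.sum()))
        raise ValidationError(
            f"parameter {name!r}: could not draw within [{lo}, {hi}] "
            f"after {_MAX_TRUNC_RETRIES} retries")


def fixed(v: float) -> Dist:
    return Dist("fixed", v)


@dataclass(frozen=True)
class McConfig:
    n_iterations: int = 10_000
    seed: int = 0
    distributions: Mapping[str, Dist] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")


@dataclass(frozen=True)
class McResult:
    name: str
    mean: float
    p05: float
    p50: float
    p95: float
    sensitivity: Mapping[str, Optional[float]]
    contribution: Mapping[str, Optional[float]]
    samples: np.ndarray
    draws: Mapping[str, np.ndarray]


def _spawn_streams(seed: int, names) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


def mc_propagate(risk_fn: Callable[..., np.ndarray], cfg: McConfig,
                 name: str = "output") -> McResult:
    """Propagate cfg.distributions through risk_fn.

    risk_fn is called once with keyword arrays (one per parameter, each of
    length n_iterations) and must return an array of outputs, so the risk
    equations vectorize naturally. Sensitivity (Spearman rank correlation
    of each non-fixed parameter against the output) and its normalized
    squared contribution are attached to the result.
    """
    names = sorted(cfg.distributions)
    if not names:
        raise ValidationError("no distributions configured")
    rngs = _spawn_streams(cfg.seed, names)
    draws = {p: cfg.distributions[p].sample(rngs[p], cfg.n_iterations, p)
             for p in names}
    out = np.asarray(risk_fn(**draws), dtype=float)
    if out.shape != (cfg.n_iterations,):
        raise ValidationError(
            f"risk_fn returned shape {out.shape}, expected ({cfg.n_iterations},)")
    varied = [p for p in names if cfg.distributions[p].family != "fixed"]
    sens, contrib = mc_sensitivity({p: draws[p] for p in varied}, out)
    p05, p50, p95 = np.percentile(out, [5, 50, 95])  # linear interpolation
    return McResult(name=name, mean=float(out.mean()), p05=float(p05),
                    p50=float(p50), p95=float(p95), sensitivity=sens,
                    contribution=contrib, samples=out, draws=draws)


def mc_sensitivity(samples: Mapping[str, np.ndarray], outputs: np.ndarray
                   ) -> tuple[dict, dict]:
    """Spearman rank correlation of each parameter against the output,
    plus squared-coefficient contribution shares.

    A constant output (or constant parameter column) yields null
    coefficients rather than a spurious zero.
    """
    outputs = np.asarray(outputs, dtype=float)
    sens: dict[str, Optional[float]] = {}
    for pname, x in samples.items():
        x = np.asarray(x, dtype=float)
        if len(x) != len(outputs):
            raise ValidationError(f"parameter {pname!r}: length mismatch")
        if len(x) < 10:
            raise ValidationError("sensitivity needs >= 10 samples")
        if np.ptp(outputs) == 0 or np.ptp(x) == 0:
            sens[pname] = None
            continue
        rho = stats.spearmanr(x, outputs).statistic
        sens[pname] = float(rho)
    sq = {p: (v ** 2 if v is not None else None) for p, v in sens.items()}
    total = sum(v for v in sq.values() if v is not None)
    contrib = {p: (v / total if (v is not None and total > 0) else None)
               for p, v in sq.items()}
    return sens, contrib
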