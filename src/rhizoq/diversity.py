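"""Alpha-diversity estimators and rarefaction curves.

Conventions (chosen to match the usual amplicon-survey reporting style):

* Shannon H = −Σ p ln p in natural log by default (``log_base`` switches);
* Simpson is reported as the *concentration* D = Σ p² (large D = low
  diversity); the complement 1−D is available as ``simpson_diversity``;
* Chao1 is bias-corrected by default, S + F1(F1−1)/(2(F2+1)); the classic
  form S + F1²/(2 F2) is available and raises on F2 = 0;
* ACE uses the standard abundance-based coverage estimator with the
  rare/abundant cutoff at 10;
* Good's coverage is 1 − F1/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DomainError
from .io import CountTable

__all__ = [
    "alpha_diversity",
    "alpha_diversity_table",
    "rarefaction_curve",
]


def _validate_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise DomainError("expected a 1-D count vector")
    if np.any(c < 0) or np.any(c != np.floor(c)):
        raise DomainError("counts must be non-negative integers")
    if c.sum() == 0:
        raise DomainError("all-zero count vector")
    return c.astype(np.int64)


def _chao1(c: np.ndarray, bias_corrected: bool) -> float:
    s = int(np.sum(c > 0))
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if bias_corrected:
        return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 and f2 == 0:
        raise DomainError(
            "classic Chao1 is undefined with singletons but no doubletons; "
            "use the bias-corrected form"
        )
    return s + (f1 * f1 / (2.0 * f2) if f2 else 0.0)


def _ace(c: np.ndarray, rare_cutoff: int = 10) -> float:
    pos = c[c > 0]
    rare = pos[pos <= rare_cutoff]
    abund = pos[pos > rare_cutoff]
    s_abund = len(abund)
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    if f1 == n_rare:
        # all rare taxa are singletons: coverage estimate degenerates;
        # fall back to bias-corrected Chao1 as is conventional
        return _chao1(c, bias_corrected=True)
    c_ace = 1.0 - f1 / n_rare
    fk = np.array([np.sum(rare == k) for k in range(1, rare_cutoff + 1)])
    ks = np.arange(1, rare_cutoff + 1)
    gamma2 = max(
        (s_rare / c_ace) * np.sum(ks * (ks - 1) * fk)
        / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


@dataclass
class AlphaDiversity:
    """Alpha-diversity summary for one sample."""

    observed: int
    shannon: float
    simpson: float          # concentration D = Σ p²
    simpson_diversity: float  # 1 − D
    chao1: float
    ace: float
    goods_coverage: float

    def as_dict(self) -> dict[str, float]:
        return {
            "observed": self.observed,
            "shannon": self.shannon,
            "simpson": self.simpson,
            "simpson_diversity": self.simpson_diversity,
            "chao1": self.chao1,
            "ace": self.ace,
            "goods_coverage": self.goods_coverage,
        }


def alpha_diversity(
    counts,
    log_base: float | None = None,
    chao1_bias_corrected: bool = True,
    ace_rare_cutoff: int = 10,
) -> AlphaDiversity:
    """Alpha-diversity indices of one sample's count vector.

    ``log_base`` of None means natural log for Shannon.
    """
    c = _validate_counts(counts)
    n = c.sum()
    p = c[c > 0] / n
    shannon = float(-np.sum(p * np.log(p)))
    if log_base is not None:
        shannon /= np.log(log_base)
    simpson = float(np.sum(p**2))
    f1 = int(np.sum(c == 1))
    return AlphaDiversity(
        observed=int(np.sum(c > 0)),
        shannon=shannon,
        simpson=simpson,
        simpson_diversity=1.0 - simpson,
        chao1=float(_chao1(c, chao1_bias_corrected)),
        ace=float(_ace(c, ace_rare_cutoff)),
        goods_coverage=float(1.0 - f1 / n),
    )


def alpha_diversity_table(table: CountTable, **kwargs) -> pd.DataFrame:
    """Per-sample alpha diversity of a count table, one row per sample."""
    rows = {
        sid: alpha_diversity(table.data.loc[sid].to_numpy(), **kwargs).as_dict()
        for sid in table.sample_ids
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def rarefaction_curve(
    counts,
    depths,
    n_iter: int = 100,
    seed: int | None = None,
    mode: str = "expectation",
) -> pd.Series:
    """Mean observed richness when subsampling to each depth.

    ``mode='expectation'`` uses the exact hypergeometric expectation
    E[S_d] = Σ_i (1 − C(N−n_i, d)/C(N, d)); ``mode='montecarlo'`` averages
    ``n_iter`` random subsamples without replacement (seeded).
    """
    c = _validate_counts(counts)
    n = int(c.sum())
    depths = [int(d) for d in depths]
    if any(d < 1 or d > n for d in depths):
        raise DomainError(f"depths must lie in [1, {n}]")
    if mode == "expectation":
        vals = []
        for d in depths:
            # P(taxon i absent from subsample) is hypergeometric at 0 draws
            absent = hypergeom.pmf(0, n, c[c > 0], d)
            vals.append(float(np.sum(1.0 - absent)))
        return pd.Series(vals, index=depths, name="richness")
    if mode == "montecarlo":
        if n_iter < 1:
            raise DomainError("n_iter must be >= 1")
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(c.size), c)
        vals = np.zeros(len(depths))
        for _ in range(n_iter):
            perm = rng.permutation(pool)
            for j, d in enumerate(depths):
                vals[j] += len(np.unique(perm[:d]))
        return pd.Series(vals / n_iter, index=depths, name="richness")
    raise DomainError(f"unknown rarefaction mode {mode!r}")
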