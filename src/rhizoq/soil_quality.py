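"""Fuzzy comprehensive soil-quality evaluation.

The soil quality index (SQI) condenses a panel of soil indicators (pH, EC,
organic matter, mineral nitrogen, enzyme activities) into one score per
treatment:

1. each indicator is rescaled to a [0, 1] desirability ("membership") score
   by a linear min-max membership function whose direction depends on
   whether more or less of the indicator is desirable;
2. per-indicator weights are the indicators' communality shares from a
   principal-component analysis of the standardized indicator table (Kaiser
   retention, varimax rotation — communalities are rotation-invariant, the
   rotated loadings are reported as diagnostics);
3. SQI(t) = Σ_i Q_i(t) · S_i, the weight-averaged membership, graded into
   five levels: I ≥ 0.85 (extremely high), II [0.7, 0.85) high,
   III [0.55, 0.7) medium, IV [0.4, 0.55) low, V < 0.4 very low.

Sampling adequacy for the factor-analysis step is reported via the
Kaiser-Meyer-Olkin measure and Bartlett's test of sphericity.

A published instance of the membership/weight table for a sewage-sludge
biochar pot experiment (two plant species × five doses) ships as a fixture,
see :func:`table4_fixture`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import AlignmentError, ConfigError, DegenerateDataError, DomainError
from .io import IndicatorTable

__all__ = [
    "ExtremeBounds",
    "SqiResult",
    "membership",
    "assign_directions",
    "factor_weights",
    "kmo_bartlett",
    "kmo_from_correlation",
    "compute_sqi",
    "classify_sqi",
    "table4_fixture",
    "radar_table",
    "evaluate_soil_quality",
]

#: indicators whose *decrease* improves soil quality in the default scheme
LESS_IS_BETTER = ("pH", "EC")

LEVEL_LABELS = {
    "I": "extremely high",
    "II": "high",
    "III": "medium",
    "IV": "low",
    "V": "very low",
}

# grading bounds: level -> lower bound on SQI (V is the open bottom class)
LEVEL_BOUNDS = (("I", 0.85), ("II", 0.70), ("III", 0.55), ("IV", 0.40))


@dataclass
class ExtremeBounds:
    """Per-indicator (minimum, maximum) used by the membership functions."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise DegenerateDataError(
                    f"degenerate range for indicator {name!r}: "
                    f"min {lo} >= max {hi}"
                )

    @classmethod
    def from_table(cls, table: IndicatorTable) -> "ExtremeBounds":
        vals = table.values()
        return cls({c: (vals[c].min(), vals[c].max()) for c in vals.columns})


@dataclass
class SqiResult:
    """SQI score and level per treatment."""

    scores: pd.Series          # treatment_id -> sqi
    levels: pd.Series          # treatment_id -> level string
    memberships: pd.DataFrame  # treatment × indicator
    weights: pd.Series         # indicator -> weight

    @property
    def labels(self) -> pd.Series:
        return self.levels.map(LEVEL_LABELS)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sqi": self.scores, "level": self.levels, "label": self.labels}
        )


# ---------------------------------------------------------------------------
# membership functions
# ---------------------------------------------------------------------------

def membership(
    values,
    direction: str,
    bounds: tuple[float, float],
    variant: str = "unit",
):
    """Linear min-max membership score of indicator ``values``.

    direction 'more_better': (Y − Mi) / (Ma − Mi);
    direction 'less_better': (Ma − Y) / (Ma − Mi).
    variant 'unit' leaves the score in [0, 1]; 'rescaled_01_to_1' applies
    0.9·s + 0.1 so scores live in [0.1, 1.0]. Values outside the bounds are
    clipped with a warning.
    """
    lo, hi = bounds
    if not hi > lo:
        raise DegenerateDataError(f"degenerate bounds: min {lo} >= max {hi}")
    y = np.asarray(values, dtype=float)
    if np.any(y < lo) or np.any(y > hi):
        warnings.warn(
            "indicator values outside bounds were clipped", stacklevel=2
        )
        y = np.clip(y, lo, hi)
    if direction == "more_better":
        s = (y - lo) / (hi - lo)
    elif direction == "less_better":
        s = (hi - y) / (hi - lo)
    else:
        raise ConfigError(f"unknown direction {direction!r}")
    if variant == "rescaled_01_to_1":
        s = 0.9 * s + 0.1
    elif variant != "unit":
        raise ConfigError(f"unknown membership variant {variant!r}")
    if np.isscalar(values):
        return float(s)
    return s


def assign_directions(
    indicator_names: Sequence[str],
    overrides: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Default membership direction per indicator.

    pH and EC score as 'less_better'; everything else as 'more_better'
    (unknown indicators fall back to 'more_better' with a warning).
    ``overrides`` wins over the defaults.
    """
    known_more = {"SOM", "SAN", "SNN", "SPEA", "SCEA", "SIEA"}
    out: dict[str, str] = {}
    for name in indicator_names:
        if name in LESS_IS_BETTER:
            out[name] = "less_better"
        elif name in known_more:
            out[name] = "more_better"
        else:
            warnings.warn(
                f"unknown indicator {name!r}; defaulting to more_better",
                stacklevel=2,
            )
            out[name] = "more_better"
    if overrides:
        for name, direction in overrides.items():
            if direction not in ("more_better", "less_better"):
                raise ConfigError(f"invalid direction {direction!r}")
            if name in out:
                out[name] = direction
    return out


# ---------------------------------------------------------------------------
# factor-analysis weights
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Varimax-rotate a loading matrix (SVD-based iteration)."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - (lam * (lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return loadings @ rot


def factor_weights(
    table: IndicatorTable | pd.DataFrame,
    retention: str = "kaiser",
    n_components: int | None = None,
    rotate: str = "varimax",
) -> tuple[pd.Series, dict]:
    """Indicator weights as communality shares of a PCA.

    Indicators are z-standardized (so the PCA operates on the correlation
    structure); components are retained by the Kaiser rule (eigenvalue > 1)
    or as a fixed count; retained loadings are varimax-rotated; the weight of
    indicator i is its communality h²_i = Σ_k loading²_ik divided by the sum
    of all communalities. Weights are non-negative and sum to 1.

    Returns ``(weights, diagnostics)`` where diagnostics carries the
    eigenvalues, (rotated) loadings and communalities.
    """
    vals = table.values() if isinstance(table, IndicatorTable) else table.astype(float)
    n, p = vals.shape
    if n < 3:
        raise DegenerateDataError(f"need >= 3 samples for factor weights, got {n}")
    if p < 2:
        raise DegenerateDataError("need >= 2 indicators for factor weights")
    sd = vals.std(axis=0, ddof=1)
    const = sd[sd == 0]
    if len(const):
        raise DegenerateDataError(
            f"constant indicator(s): {', '.join(const.index)}"
        )
    z = (vals - vals.mean(axis=0)) / sd

    pca = PCA(svd_solver="full")
    pca.fit(z.to_numpy())
    # eigenvalues of the correlation matrix (sample covariance of z, ddof=1)
    eigenvalues = pca.explained_variance_
    if retention == "kaiser":
        k = max(1, int(np.sum(eigenvalues > 1.0)))
    elif retention == "fixed_k":
        if not n_components or n_components < 1 or n_components > p:
            raise ConfigError("fixed_k retention requires 1 <= n_components <= p")
        k = n_components
    else:
        raise ConfigError(f"unknown retention rule {retention!r}")
    # loadings: eigenvector columns scaled by sqrt(eigenvalue)
    load = (pca.components_[:k].T * np.sqrt(eigenvalues[:k]))
    if rotate == "varimax":
        load = varimax(load)
    elif rotate != "none":
        raise ConfigError(f"unknown rotation {rotate!r}")
    communalities = (load**2).sum(axis=1)
    weights = pd.Series(
        communalities / communalities.sum(), index=vals.columns, name="weight"
    )
    diagnostics = {
        "eigenvalues": eigenvalues,
        "n_retained": k,
        "loadings": pd.DataFrame(
            load, index=vals.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        "communalities": pd.Series(communalities, index=vals.columns),
    }
    return weights, diagnostics


def kmo_from_correlation(corr: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy from a correlation matrix.

    KMO = Σ r²_ij / (Σ r²_ij + Σ q²_ij) over i≠j, where q are the anti-image
    (negated scaled inverse) partial correlations.
    """
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0 or logdet < -50 * p:
        off = np.abs(r - np.eye(p))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise DegenerateDataError(
            f"correlation matrix is singular; worst pair is indicators "
            f"{i} and {j} (|r| = {off[i, j]:.4f})"
        )
    rinv = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    partial = -rinv / d
    mask = ~np.eye(p, dtype=bool)
    r2 = np.sum(r[mask] ** 2)
    q2 = np.sum(partial[mask] ** 2)
    return float(r2 / (r2 + q2))


def kmo_bartlett(table: IndicatorTable | pd.DataFrame) -> tuple[float, float, float]:
    """KMO measure plus Bartlett's test of sphericity on an indicator table.

    Bartlett's statistic is −(n−1−(2p+5)/6)·ln|R| on p(p−1)/2 degrees of
    freedom, testing R = I. Returns ``(kmo, chi2, p_value)``.
    """
    vals = table.values() if isinstance(table, IndicatorTable) else table.astype(float)
    n, p = vals.shape
    corr = np.corrcoef(vals.to_numpy(), rowvar=False)
    kmo = kmo_from_correlation(corr)
    sign, logdet = np.linalg.slogdet(corr)
    chi2 = max(0.0, -(n - 1 - (2 * p + 5) / 6.0) * logdet)
    df = p * (p - 1) / 2.0
    p_value = float(stats.chi2.sf(chi2, df))
    return kmo, float(chi2), p_value


# ---------------------------------------------------------------------------
# SQI aggregation and grading
# ---------------------------------------------------------------------------

def classify_sqi(sqi: float) -> str:
    """Grade one SQI value into level I–V."""
    if not 0.0 <= sqi <= 1.0:
        raise DomainError(f"SQI must lie in [0, 1], got {sqi}")
    for level, lower in LEVEL_BOUNDS:
        if sqi >= lower:
            return level
    return "V"


def compute_sqi(
    memberships: pd.DataFrame,
    weights: pd.Series,
) -> SqiResult:
    """Weighted-sum SQI per treatment: SQI(t) = Σ_i Q_i(t)·S_i.

    ``memberships`` is treatment × indicator; ``weights`` must cover exactly
    the same indicators and sum to 1.
    """
    mset, wset = set(memberships.columns), set(weights.index)
    if mset != wset:
        diff = sorted(mset.symmetric_difference(wset))
        raise AlignmentError(
            f"indicator sets differ between memberships and weights: {diff}"
        )
    if not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise DomainError(f"weights must sum to 1, got {weights.sum():.6f}")
    w = weights.reindex(memberships.columns)
    scores = memberships.astype(float) @ w.astype(float)
    scores.name = "sqi"
    levels = scores.map(classify_sqi)
    levels.name = "level"
    return SqiResult(scores, levels, memberships.copy(), w.copy())


def radar_table(result: SqiResult) -> pd.DataFrame:
    """Tidy (treatment, axis, value) table for radar-chart plotting.

    Axes are the membership components plus the aggregate SQI.
    """
    long = (
        result.memberships.reset_index(names="treatment")
        .melt(id_vars="treatment", var_name="axis", value_name="value")
    )
    sqi = result.scores.to_frame("value").reset_index(names="treatment")
    sqi["axis"] = "SQI"
    sqi = sqi[["treatment", "axis", "value"]]
    return pd.concat([long, sqi], ignore_index=True)


# ---------------------------------------------------------------------------
# end-to-end evaluation of a replicate-level table
# ---------------------------------------------------------------------------

def evaluate_soil_quality(
    table: IndicatorTable,
    variant: str = "unit",
    bounds_scope: str = "replicates",
    weights: pd.Series | None = None,
    direction_overrides: Mapping[str, str] | None = None,
) -> SqiResult:
    """Full SQI evaluation of one species' replicate-level indicator table.

    Memberships are computed on treatment (dose) means; the min/max bounds
    come from replicate-level values (``bounds_scope='replicates'``, default)
    or from the treatment means (``'treatment_means'``). Weights default to
    factor-analysis communality shares of the replicate-level table.
    Treatments are labelled by their dose (``dose_<dose>``), or by the
    species-dose sample prefix when one exists.
    """
    vals = table.values()
    meta = table.data
    groups = vals.groupby(meta["dose_pct"])
    means = groups.mean()
    means.index = [f"dose_{d:g}" for d in means.index]

    if bounds_scope == "replicates":
        bounds = ExtremeBounds.from_table(table)
    elif bounds_scope == "treatment_means":
        bounds = ExtremeBounds(
            {c: (means[c].min(), means[c].max()) for c in means.columns}
        )
    else:
        raise ConfigError(f"unknown bounds_scope {bounds_scope!r}")

    directions = assign_directions(table.indicators, direction_overrides)
    memberships = pd.DataFrame(
        {
            ind: membership(
                means[ind].to_numpy(), directions[ind],
                bounds.bounds[ind], variant,
            )
            for ind in table.indicators
        },
        index=means.index,
    )
    if weights is None:
        weights, _ = factor_weights(table)
    return compute_sqi(memberships, weights)


# ---------------------------------------------------------------------------
# published fixture: membership/weight table of the SSB pot experiment
# ---------------------------------------------------------------------------

_T4_INDICATORS = ["pH", "EC", "SOM", "SAN", "SNN", "SPEA", "SCEA", "SIEA"]

_T4_RYEGRASS = {
    "P1S1": [0.787, 0.226, 0.153, 0.308, 0.190, 0.717, 0.532, 0.490],
    "P1S2": [0.483, 0.101, 0.210, 0.107, 0.566, 0.566, 0.544, 0.574],
    "P1S3": [0.468, 0.999, 0.553, 0.381, 0.910, 0.526, 0.556, 0.551],
    "P1S4": [0.313, 0.502, 0.755, 0.993, 0.663, 0.519, 0.568, 0.610],
    "P1S5": [0.476, 0.816, 0.947, 0.821, 0.313, 0.383, 0.550, 0.526],
}
_T4_RYEGRASS_WEIGHTS = [0.263, 0.149, 0.077, 0.136, 0.034, 0.125, 0.062, 0.154]

_T4_COSMOS = {
    "P2S1": [0.271, 0.101, 0.270, 0.101, 0.110, 0.632, 0.417, 0.650],
    "P2S2": [0.596, 0.714, 0.298, 0.603, 0.990, 0.647, 0.676, 0.462],
    "P2S3": [0.749, 0.787, 0.161, 0.999, 0.416, 0.613, 0.683, 0.458],
    "P2S4": [0.812, 0.990, 0.475, 0.446, 0.327, 0.453, 0.432, 0.450],
    "P2S5": [0.829, 0.999, 0.939, 0.711, 0.246, 0.616, 0.435, 0.460],
}
_T4_COSMOS_WEIGHTS = [0.254, 0.180, 0.199, 0.103, 0.121, 0.074, 0.042, 0.027]


def table4_fixture(species: str) -> tuple[pd.DataFrame, pd.Series]:
    """Published membership values and weights for one plant species.

    ``species`` is 'ryegrass' (treatments P1S1–P1S5) or 'cosmos'
    (P2S1–P2S5); values are the printed three-decimal memberships of eight
    soil indicators under five sewage-sludge-biochar doses, plus the
    communality-share weight row. (The published table's header labels the
    conductivity column "CEC"; it is treated as EC.)
    """
    if species == "ryegrass":
        rows, w = _T4_RYEGRASS, _T4_RYEGRASS_WEIGHTS
    elif species == "cosmos":
        rows, w = _T4_COSMOS, _T4_COSMOS_WEIGHTS
    else:
        raise ConfigError(f"unknown species {species!r}; use 'ryegrass' or 'cosmos'")
    memberships = pd.DataFrame.from_dict(
        rows, orient="index", columns=_T4_INDICATORS
    )
    weights = pd.Series(w, index=_T4_INDICATORS, name="weight")
    return memberships, weights
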