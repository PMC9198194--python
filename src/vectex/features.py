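"""Texture measures on normalized co-occurrence matrices.

Each VCM is normalized to a joint probability matrix p(i, j) over vector
states (0-based indices) and reduced to 28 scalar texture measures: the 14
classic Haralick statistics plus 14 widely used co-occurrence extensions.
Thirteen directions x 28 measures give the 364-entry per-lesion feature
vector.

Conventions: logarithms are base 2 (entropies in bits) with 0*log(0) = 0;
measures undefined on a degenerate matrix (e.g. correlation with zero
marginal variance) return a sentinel of 0. "sum of squares: variance" and
"joint variance" follow the same formula (the variance of the row marginal)
and are kept as two named entries of the fixed 28-measure contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .vcm import VCMStack

#: Fixed order of the 28 texture measures.
MEASURE_NAMES: tuple[str, ...] = (
    # 14 classic Haralick measures
    "energy",                # angular second moment
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",   # homogeneity
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",                  # information measure of correlation 1
    "imc2",                  # information measure of correlation 2
    "max_correlation_coeff",
    # 14 extensions
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "dissimilarity",
    "maximum_probability",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
    "joint_average",
    "joint_variance",
    "inverse_variance",
    "difference_average",
    "marginal_entropy_sum",
)

N_MEASURES = len(MEASURE_NAMES)
N_DIRECTIONS = 13
N_FEATURES = N_DIRECTIONS * N_MEASURES  # 364


class DegenerateMatrixError(ValueError):
    """The co-occurrence matrix has zero total count."""


@dataclass
class ProbMatrix:
    """Normalized co-occurrence matrix with its derived distributions."""

    p: np.ndarray          # joint probabilities, sum 1
    p_x: np.ndarray        # row marginal
    p_y: np.ndarray        # column marginal
    p_sum: np.ndarray      # distribution of i + j, support 0 .. 2(N-1)
    p_diff: np.ndarray     # distribution of |i - j|, support 0 .. N-1


def normalize_vcm(m) -> ProbMatrix:
    """Normalize a VCMatrix (or raw count matrix) to probabilities."""
    counts = np.asarray(getattr(m, "counts", m), dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise DegenerateMatrixError("co-occurrence matrix has zero total")
    p = counts / total
    n = p.shape[0]
    i, j = np.indices((n, n))
    p_sum = np.bincount((i + j).ravel(), weights=p.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(np.abs(i - j).ravel(), weights=p.ravel(), minlength=n)
    return ProbMatrix(p=p, p_x=p.sum(axis=1), p_y=p.sum(axis=0),
                      p_sum=p_sum, p_diff=p_diff)


def _xlog2(x: np.ndarray) -> np.ndarray:
    """x * log2(x) with the 0*log(0) = 0 convention."""
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def _entropy(x: np.ndarray) -> float:
    return float(-_xlog2(x).sum())


def _max_correlation_coeff(p: np.ndarray, p_x: np.ndarray, p_y: np.ndarray) -> float:
    support = p_x > 0
    ps = p[np.ix_(support, support)]
    px = p_x[support]
    py = p_y[support]
    if px.size < 2:
        return 0.0
    # Q[i,j] = sum_k p[i,k] p[j,k] / (p_x[i] p_y[k])
    q = (ps / px[:, None]) @ (ps / py[None, :]).T
    try:
        eig = np.linalg.eigvals(q)
    except np.linalg.LinAlgError:
        return 0.0
    eig = np.sort(np.real(eig))[::-1]
    second = eig[1] if eig.size > 1 else 0.0
    if not np.isfinite(second) or second < 0:
        return 0.0
    return float(np.sqrt(min(second, 1.0)))


def texture_measures(pm: ProbMatrix) -> list[tuple[str, float]]:
    """The 28 named texture measures, in the fixed documented order."""
    p = pm.p
    n = p.shape[0]
    i, j = np.indices((n, n), dtype=np.float64)
    k_sum = np.arange(pm.p_sum.size, dtype=np.float64)
    k_diff = np.arange(pm.p_diff.size, dtype=np.float64)

    mu_x = float((np.arange(n) * pm.p_x).sum())
    mu_y = float((np.arange(n) * pm.p_y).sum())
    var_x = float(((np.arange(n) - mu_x) ** 2 * pm.p_x).sum())
    var_y = float(((np.arange(n) - mu_y) ** 2 * pm.p_y).sum())

    diff = i - j
    absdiff = np.abs(diff)

    energy = float((p * p).sum())
    contrast = float((diff ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float((((i - mu_x) * (j - mu_y) * p).sum())
                            / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    sum_sq_var = var_x
    idm = float((p / (1.0 + diff ** 2)).sum())

    sum_average = float((k_sum * pm.p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * pm.p_sum).sum())
    sum_entropy = _entropy(pm.p_sum)
    entropy = _entropy(p.ravel())

    diff_average = float((k_diff * pm.p_diff).sum())
    diff_variance = float(((k_diff - diff_average) ** 2 * pm.p_diff).sum())
    diff_entropy = _entropy(pm.p_diff)

    hx = _entropy(pm.p_x)
    hy = _entropy(pm.p_y)
    outer = np.outer(pm.p_x, pm.p_y)
    hxy1 = float(-np.sum(np.where(outer > 0, p * np.log2(np.where(outer > 0, outer, 1.0)), 0.0)))
    hxy2 = _entropy(outer.ravel())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))
    mcc = _max_correlation_coeff(p, pm.p_x, pm.p_y)

    autocorrelation = float((i * j * p).sum())
    centered_sum = i + j - mu_x - mu_y
    cluster_prominence = float((centered_sum ** 4 * p).sum())
    cluster_shade = float((centered_sum ** 3 * p).sum())
    cluster_tendency = float((centered_sum ** 2 * p).sum())
    dissimilarity = float((absdiff * p).sum())
    maximum_probability = float(p.max())
    inv_difference = float((p / (1.0 + absdiff)).sum())
    idn = float((p / (1.0 + absdiff / n)).sum())
    idmn = float((p / (1.0 + diff ** 2 / (n * n))).sum())
    joint_average = mu_x
    joint_variance = var_x
    offdiag = absdiff > 0
    inverse_variance = float((p[offdiag] / diff[offdiag] ** 2).sum())
    marginal_entropy_sum = hx + hy

    values = (
        energy, contrast, correlation, sum_sq_var, idm,
        sum_average, sum_variance, sum_entropy, entropy,
        diff_variance, diff_entropy, imc1, imc2, mcc,
        autocorrelation, cluster_prominence, cluster_shade, cluster_tendency,
        dissimilarity, maximum_probability, inv_difference, idn, idmn,
        joint_average, joint_variance, inverse_variance, diff_average,
        marginal_entropy_sum,
    )
    return list(zip(MEASURE_NAMES, (float(v) for v in values)))


@dataclass
class FeatureVector:
    """The 364 named texture measures of one lesion."""

    values: np.ndarray
    names: list[str]
    lesion_id: str
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != N_FEATURES or len(self.names) != N_FEATURES:
            raise ValueError(f"feature vector must have {N_FEATURES} entries")
        if len(set(self.names)) != N_FEATURES:
            raise ValueError("feature names must be unique")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def feature_vector(stack: VCMStack, lesion_id: str,
                   label: int | None = None) -> FeatureVector:
    """Concatenate 13 x 28 texture measures in direction-major order.

    A direction whose VCM has zero total contributes 28 zero sentinels with
    a warning instead of failing the whole lesion.
    """
    names: list[str] = []
    values: list[float] = []
    for m in stack.matrices:
        prefix = m.direction.name
        try:
            measures = texture_measures(normalize_vcm(m))
        except DegenerateMatrixError:
            warnings.warn(
                f"degenerate VCM for direction {m.direction.offset}; "
                "emitting zero sentinels", RuntimeWarning, stacklevel=2)
            measures = [(name, 0.0) for name in MEASURE_NAMES]
        for name, value in measures:
            names.append(f"{prefix}__{name}")
            values.append(value)
    return FeatureVector(values=np.array(values), names=names,
                         lesion_id=lesion_id, label=label)
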