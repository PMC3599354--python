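"""Descriptor reduction: SNR, moment and rank-correlation filters.

Three filters, applied in order and on training data only:

1. signal-to-noise ratio — for each descriptor and each of the 15 class
   pairs, ``SNR = |mean_g1 - mean_g2| / max(sd_g1, sd_g2)``; a descriptor
   survives if its maximum pair SNR reaches ``snr_min`` (default 3.00);
2. moments — discard descriptors whose worst per-class bias-corrected
   excess kurtosis exceeds 16.0 or worst per-class |skewness| exceeds 13.4
   (heavy-tailed or wildly asymmetric descriptors destabilize covariance
   estimates);
3. Kendall tau_b — a greedy pass in decreasing-SNR order drops any
   descriptor whose |tau_b| with an already-kept descriptor exceeds 0.95,
   keeping the higher-SNR member of each correlated pair.

The report carries a complete audit trail: every input descriptor is either
kept or attributed to exactly one filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


class SelectionError(ValueError):
    """Base class for selection failures."""


class EmptySelectionError(SelectionError):
    """No descriptor survived the filters; relax the thresholds."""


class InsufficientDataError(SelectionError):
    """A class has fewer than 2 samples."""


@dataclass
class SelectionThresholds:
    snr_min: float = 3.00
    kurtosis_max: float = 16.0
    skewness_max: float = 13.4
    tau_max: float = 0.95

    def __post_init__(self) -> None:
        if not all(
            np.isfinite([self.snr_min, self.kurtosis_max, self.skewness_max, self.tau_max])
        ):
            raise ValueError("thresholds must be finite")
        if self.snr_min <= 0:
            raise ValueError("snr_min must be positive")
        if not (0 < self.tau_max <= 1):
            raise ValueError("tau_max must be in (0, 1]")


@dataclass
class SelectionReport:
    """Surviving descriptor indices plus a per-filter audit trail."""

    kept: np.ndarray  # indices into the input descriptor axis
    snr: np.ndarray  # per-descriptor max-pair SNR
    max_kurtosis: np.ndarray  # per-descriptor max-over-groups excess kurtosis
    max_abs_skewness: np.ndarray
    dropped_snr: np.ndarray
    dropped_moment: np.ndarray
    dropped_correlation: list[tuple[int, int, float]] = field(default_factory=list)
    # (dropped index, kept index it correlated with, tau_b)
    filter_order: tuple[str, ...] = ("snr", "moments", "correlation")

    def to_dict(self) -> dict:
        return {
            "kept": self.kept.tolist(),
            "dropped_snr": self.dropped_snr.tolist(),
            "dropped_moment": self.dropped_moment.tolist(),
            "dropped_correlation": [
                {"dropped": int(d), "kept": int(k), "tau_b": float(t)}
                for d, k, t in self.dropped_correlation
            ],
            "filter_order": list(self.filter_order),
        }


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    classes = np.unique(labels)
    groups = [np.flatnonzero(labels == c) for c in classes]
    for c, g in zip(classes, groups):
        if len(g) < 2:
            raise InsufficientDataError(f"class {c!r} has fewer than 2 samples")
    return groups


def pairwise_snr(matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Max-over-class-pairs SNR for every descriptor.

    ``SNR_pair = |mu_1 - mu_2| / max(sd_1, sd_2)`` with the sample standard
    deviation (ddof=1).  When both sds are 0 the pair SNR is 0 for equal
    means and +inf for different means.  With 6 classes there are 15 pairs.
    """
    matrix = np.asarray(matrix, dtype=float)
    groups = _group_indices(np.asarray(labels))
    means = np.stack([matrix[g].mean(axis=0) for g in groups])
    sds = np.stack([matrix[g].std(axis=0, ddof=1) for g in groups])
    k = len(groups)
    best = np.zeros(matrix.shape[1])
    for i in range(k):
        for j in range(i + 1, k):
            num = np.abs(means[i] - means[j])
            den = np.maximum(sds[i], sds[j])
            with np.errstate(divide="ignore", invalid="ignore"):
                snr = num / den
            snr = np.where(den == 0, np.where(num == 0, 0.0, np.inf), snr)
            best = np.maximum(best, snr)
    return best


def group_moments(matrix: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Worst-case per-class moments of every descriptor.

    Returns ``(max excess kurtosis, max |skewness|)`` over the classes,
    both bias-corrected.  Zero-variance groups contribute 0 (logged).
    """
    matrix = np.asarray(matrix, dtype=float)
    groups = _group_indices(np.asarray(labels))
    kurt = np.full((len(groups), matrix.shape[1]), -np.inf)
    skew = np.zeros((len(groups), matrix.shape[1]))
    n_const = 0
    for gi, g in enumerate(groups):
        sub = matrix[g]
        var = sub.var(axis=0)
        ok = var > 0
        n_const += int((~ok).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            kurt[gi, ok] = stats.kurtosis(sub[:, ok], fisher=True, bias=False)
            skew[gi, ok] = stats.skew(sub[:, ok], bias=False)
        kurt[gi, ~ok] = 0.0
    if n_const:
        log.debug("moment filter: %d constant group columns treated as moments 0", n_const)
    return kurt.max(axis=0), np.abs(skew).max(axis=0)


def moment_filter(
    matrix: np.ndarray, labels: np.ndarray, thresholds: SelectionThresholds
) -> np.ndarray:
    """Indices (into the matrix columns) failing the kurtosis/skewness caps."""
    max_kurt, max_skew = group_moments(matrix, labels)
    bad = (max_kurt > thresholds.kurtosis_max) | (max_skew > thresholds.skewness_max)
    return np.flatnonzero(bad)


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    tau = stats.kendalltau(x, y).statistic
    return 0.0 if np.isnan(tau) else float(tau)


def _pair_signs(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """sign(x_i - x_j) over all sample pairs i < j, per column.

    Kendall's tau_b between two columns is then a normalized dot product of
    their sign vectors: tau_b = sum(s_x * s_y) / sqrt((n0 - t_x)(n0 - t_y))
    with n0 = n(n-1)/2 and t the number of tied pairs in each column.  This
    turns the greedy filter's inner loop into vectorized arithmetic; the
    scalar :func:`kendall_tau_b` remains the reference definition.
    """
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    signs = np.sign(matrix[iu] - matrix[ju]).astype(np.int8)  # (n0, cols)
    ties = (signs == 0).sum(axis=0)
    return signs, ties


def correlation_filter(
    matrix: np.ndarray, snr: np.ndarray, tau_max: float
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Greedy de-correlation in decreasing-SNR order.

    ``matrix`` holds only the candidate columns; ``snr`` their SNR values.
    Returns kept column positions (sorted) plus the (dropped, kept, tau_b)
    audit list.  Ties in SNR are broken toward the lower column index, so
    the pass is deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    # stable sort on negated SNR gives decreasing SNR, lower index first on ties
    order = np.argsort(-np.asarray(snr), kind="stable")
    signs, ties = _pair_signs(matrix)
    n0 = signs.shape[0]
    denom = np.sqrt(np.maximum((n0 - ties).astype(float), 0.0))
    kept: list[int] = []
    dropped: list[tuple[int, int, float]] = []
    for cand in order:
        if denom[cand] == 0.0:  # constant column: tau_b undefined, treat as 0
            kept.append(int(cand))
            continue
        hit = None
        if kept:
            concordance = signs[:, kept].T.astype(np.float64) @ signs[:, cand]
            with np.errstate(invalid="ignore"):
                taus = concordance / (denom[kept] * denom[cand])
            taus = np.nan_to_num(taus)
            over = np.flatnonzero(np.abs(taus) > tau_max)
            if len(over):
                k = kept[over[0]]
                hit = (int(cand), int(k), float(taus[over[0]]))
        if hit is None:
            kept.append(int(cand))
        else:
            dropped.append(hit)
    return np.array(sorted(kept), dtype=int), dropped


def select_descriptors(
    matrix: np.ndarray,
    labels: np.ndarray,
    thresholds: SelectionThresholds | None = None,
) -> SelectionReport:
    """Apply SNR -> moment -> correlation filters; training data only."""
    thresholds = thresholds or SelectionThresholds()
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    n_desc = matrix.shape[1]

    snr = pairwise_snr(matrix, labels)
    survive_snr = np.flatnonzero(snr >= thresholds.snr_min)
    dropped_snr = np.flatnonzero(snr < thresholds.snr_min)

    max_kurt, max_skew = group_moments(matrix, labels)
    bad_moment = (max_kurt > thresholds.kurtosis_max) | (
        max_skew > thresholds.skewness_max
    )
    dropped_moment = survive_snr[bad_moment[survive_snr]]
    survive_moment = survive_snr[~bad_moment[survive_snr]]

    if len(survive_moment) == 0:
        raise EmptySelectionError(
            "no descriptor survived the SNR/moment filters; relax the thresholds"
        )
    kept_pos, dropped_corr_pos = correlation_filter(
        matrix[:, survive_moment], snr[survive_moment], thresholds.tau_max
    )
    kept = survive_moment[kept_pos]
    dropped_corr = [
        (int(survive_moment[d]), int(survive_moment[k]), t)
        for d, k, t in dropped_corr_pos
    ]
    if len(kept) == 0:
        raise EmptySelectionError("no descriptor survived; relax the thresholds")
    assert len(kept) + len(dropped_snr) + len(dropped_moment) + len(dropped_corr) == n_desc
    return SelectionReport(
        kept=kept,
        snr=snr,
        max_kurtosis=max_kurt,
        max_abs_skewness=max_skew,
        dropped_snr=dropped_snr,
        dropped_moment=dropped_moment,
        dropped_correlation=dropped_corr,
    )
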