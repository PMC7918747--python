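"""One-sample cluster-mass permutation test of binned gaze proportions.

Given per-subject time courses of lower-half proportions (subjects x bins,
NaN for missing), each bin gets an uncorrected two-sided one-sample t test
against chance (0.50). Maximal runs of consecutive, individually significant
bins whose t statistics share a sign form *clusters*; a cluster's mass is the
sum of its t statistics, and single-bin clusters are allowed.

Family-wise error across the bins is controlled with a max-statistic
permutation null: on each of 1000 iterations, every subject's whole
deviation-from-chance time course is independently sign-flipped
(x -> chance + s * (x - chance), s in {-1, +1}) — the standard exchangeable
null for a one-sample test against chance, which preserves each subject's
within-trial autocorrelation and missingness pattern — the bin tests and
clusters are recomputed, and the largest absolute cluster mass (0 when no
cluster forms) is stored. An observed cluster is significant when its
absolute mass exceeds the empirical 95th percentile of that null; its
p-value is the fraction of null masses at least as large, which may be
reported as 0.000 when none reaches it.

Bins with fewer than two contributing subjects or zero variance are
untestable: they are excluded from clusters and break runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import PermConfig
from .errors import DataError

_VAR_EPS = 1e-18


@dataclass(frozen=True)
class ClusterResult:
    """A run of consecutive significant bins and its summed-t mass."""

    cluster_index: int  # 1-based
    start_bin: int
    end_bin: int  # inclusive
    mass: float  # signed sum of member t statistics
    onset_ms: float
    offset_ms: float
    p_value: Optional[float] = None
    significant: Optional[bool] = None

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass(frozen=True)
class NullDistribution:
    """Max-|cluster mass| permutation null."""

    max_abs_masses: np.ndarray
    threshold: float  # empirical (1 - alpha_cluster) quantile
    alpha_cluster: float

    @property
    def n_permutations(self) -> int:
        return len(self.max_abs_masses)


def _prepare(matrix: np.ndarray, chance: float):
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise DataError("subject time courses must be a 2-D (subjects x bins) array")
    finite = np.isfinite(m)
    dev = np.where(finite, m - chance, 0.0)
    n = finite.sum(axis=0)
    sumsq = (dev**2).sum(axis=0)
    return dev, n, sumsq


def _t_from_signed_sums(sums, n, sumsq, min_n):
    """t statistics per bin from sums of (optionally sign-flipped) deviations.

    Sign flips leave each squared deviation unchanged, so the per-bin sum of
    squares is permutation-invariant and the whole permutation reduces to a
    sign-matrix product; works on a single sum vector or a (perms x bins)
    stack. Returns (t, testable).
    """
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n
        var = (sumsq - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        t = mean / np.sqrt(var / n)
    testable = (n >= min_n) & (var > _VAR_EPS)
    t = np.where(testable, t, np.nan)
    return t, testable


def bin_ttests(matrix: np.ndarray, cfg: PermConfig | None = None) -> pd.DataFrame:
    """Uncorrected per-bin one-sample t tests against chance.

    One row per bin: bin_index, n, t, p (two-sided), significant, testable.
    Only subjects with a non-missing value in a bin contribute to it; df is
    n - 1. Bins with n < min_subjects_per_bin or zero variance are untestable
    (t and p are NaN, significant is False).
    """
    cfg = cfg or PermConfig()
    cfg.validate()
    dev, n, sumsq = _prepare(matrix, cfg.chance)
    t, testable = _t_from_signed_sums(dev.sum(axis=0), n, sumsq, cfg.min_subjects_per_bin)
    p = np.full(len(n), np.nan)
    with np.errstate(invalid="ignore"):
        p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), n[testable] - 1)
    return pd.DataFrame(
        {
            "bin_index": np.arange(len(n)),
            "n": n,
            "t": t,
            "p": p,
            "significant": testable & (p < cfg.alpha_bin),
            "testable": testable,
        }
    )


def _cluster_spans(t: np.ndarray, significant: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive significant bins with a common t sign.

    Returns (start_bin, end_bin_inclusive, mass) triples in bin order."""
    spans = []
    start = None
    sign = 0
    for b in range(len(significant) + 1):
        here_sig = b < len(significant) and bool(significant[b])
        here_sign = int(np.sign(t[b])) if here_sig else 0
        if start is not None and (not here_sig or here_sign != sign):
            spans.append((start, b - 1, float(t[start:b].sum())))
            start = None
        if here_sig and start is None:
            start = b
            sign = here_sign
    return spans


def find_clusters(
    bin_tests: pd.DataFrame, bin_width_ms: float = 250.0
) -> List[ClusterResult]:
    """Clusters (masses only, no p-values yet) from a bin-test table.

    Onset is the start of the first member bin, offset the end of the last;
    a single significant bin at index 0 spans 0-250 ms.
    """
    t = bin_tests["t"].to_numpy(dtype=float)
    sig = bin_tests["significant"].to_numpy(dtype=bool)
    bins = bin_tests["bin_index"].to_numpy()
    return [
        ClusterResult(
            cluster_index=i + 1,
            start_bin=int(bins[s]),
            end_bin=int(bins[e]),
            mass=mass,
            onset_ms=float(bins[s] * bin_width_ms),
            offset_ms=float((bins[e] + 1) * bin_width_ms),
        )
        for i, (s, e, mass) in enumerate(_cluster_spans(t, sig))
    ]


def _max_abs_mass(t: np.ndarray, significant: np.ndarray) -> float:
    spans = _cluster_spans(t, significant)
    return max((abs(m) for *_, m in spans), default=0.0)


def permutation_null(matrix: np.ndarray, cfg: PermConfig | None = None) -> NullDistribution:
    """Build the max-cluster-mass null by per-subject sign flipping.

    Deterministic under ``cfg.seed``. Iterations in which no cluster forms
    contribute a mass of 0, keeping the null length at ``n_permutations``.
    """
    cfg = cfg or PermConfig()
    cfg.validate()
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] < 2:
        raise DataError("permutation test needs at least 2 subjects")
    dev, n, sumsq = _prepare(m, cfg.chance)

    rng = np.random.default_rng(cfg.seed)
    signs = rng.integers(0, 2, size=(cfg.n_permutations, m.shape[0])) * 2 - 1
    sums = signs.astype(float) @ dev  # (perms x bins) signed deviation sums
    t, testable = _t_from_signed_sums(sums, n[None, :], sumsq[None, :], cfg.min_subjects_per_bin)
    p = np.full(t.shape, np.nan)
    with np.errstate(invalid="ignore"):
        df = np.broadcast_to(n - 1.0, t.shape)
        p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), df[testable])
    sig = testable & (p < cfg.alpha_bin)

    masses = np.array(
        [_max_abs_mass(t[k], sig[k]) for k in range(cfg.n_permutations)]
    )
    threshold = float(
        np.quantile(masses, 1.0 - cfg.alpha_cluster, method="inverted_cdf")
    )
    return NullDistribution(masses, threshold, cfg.alpha_cluster)


def evaluate_clusters(
    clusters: List[ClusterResult], null: NullDistribution, cfg: PermConfig | None = None
) -> List[ClusterResult]:
    """Attach permutation p-values and significance to observed clusters.

    p is the proportion of null max masses at least as large as |mass| (the
    (+1)-corrected variant is available via the config); a cluster is
    significant when |mass| exceeds the null's 95th-percentile threshold.
    """
    cfg = cfg or PermConfig()
    out = []
    masses = null.max_abs_masses
    for c in clusters:
        b = int(np.sum(masses >= abs(c.mass)))
        if cfg.add_one_correction:
            p = (b + 1) / (null.n_permutations + 1)
        else:
            p = b / null.n_permutations
        out.append(replace(c, p_value=float(p), significant=bool(abs(c.mass) > null.threshold)))
    return out


@dataclass
class ClusterTestResult:
    """Full outcome of one cluster permutation analysis."""

    bin_tests: pd.DataFrame
    clusters: List[ClusterResult]
    null: NullDistribution

    def to_frame(self, condition: str = "all") -> pd.DataFrame:
        """Report table: condition, cluster_index, sum_t, onset_ms, offset_ms,
        p_value, significant (one row per observed cluster)."""
        return pd.DataFrame(
            [
                {
                    "condition": condition,
                    "cluster_index": c.cluster_index,
                    "sum_t": c.mass,
                    "onset_ms": c.onset_ms,
                    "offset_ms": c.offset_ms,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.clusters
            ],
            columns=[
                "condition",
                "cluster_index",
                "sum_t",
                "onset_ms",
                "offset_ms",
                "p_value",
                "significant",
            ],
        )


def cluster_permutation_test(
    matrix: np.ndarray,
    cfg: PermConfig | None = None,
    bin_width_ms: float = 250.0,
) -> ClusterTestResult:
    """Observed bin tests + clusters + permutation null in one call."""
    cfg = cfg or PermConfig()
    tests = bin_ttests(matrix, cfg)
    clusters = find_clusters(tests, bin_width_ms)
    null = permutation_null(matrix, cfg)
    return ClusterTestResult(tests, evaluate_clusters(clusters, null, cfg), null)


def format_p(p: float) -> str:
    """Three-decimal p-value formatting; an empirical zero prints as 0.000."""
    return f"{p:.3f}"
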