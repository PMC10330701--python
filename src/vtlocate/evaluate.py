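"""Accuracy-assessment protocol: split, bootstrap, error summaries.

Localization accuracy is judged by the distance between the projected and
the true element centroid on the generic surface — geodesic (spherical
arc-length approximation) for the pacing-site protocol, Euclidean for the
VT-exit protocol.  Two protocols are provided:

* a single 80/20 train/test split with per-sample errors and an
  :class:`ErrorSummary` (gmean / gsd / gmedian / 5th / 95th percentile);
* an out-of-bag bootstrap: each of ``n_trials`` (default 1,000) trials
  draws n samples with replacement as the training set, refits the
  population coefficients, and evaluates on the samples never drawn
  (expected count n(1-1/n)^n ~ n/e), then aggregates the per-trial
  g-variables across trials with mean, SD, median and 5th/95th
  percentiles.

Paired method comparison uses the two-sided Wilcoxon signed-rank test
(localization errors are right-skewed), with the paired t-test and a
bootstrap CI of the mean difference reported alongside.  Percentiles use
linear interpolation between order statistics throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ecg import IntegralVector
from .mesh import TriMesh, euclidean_distance, geodesic_distance
from .model import QRSSiteModel, QRSSiteResults, TrainingSample
from .projection import project_batch, project_knn, project_sa

__all__ = [
    "LabeledSample",
    "ErrorSummary",
    "BootstrapResult",
    "ComparisonResult",
    "split_train_test",
    "evaluate",
    "bootstrap_evaluate",
    "bootstrap_compare",
    "compare_projectors",
    "iqr_outliers",
]

logger = logging.getLogger(__name__)

_PROJECTORS: dict[str, Callable] = {"sa": project_sa, "knn": project_knn}
_METRICS = {"geodesic": geodesic_distance, "euclidean": euclidean_distance}
_G_VARS = ("gmean", "gsd", "gmedian")


@dataclass(frozen=True)
class LabeledSample:
    """A sample whose true site is a registered mesh element.

    ``target`` carries the coordinates used as the regression response —
    the registered centroid, possibly displaced by interobserver jitter;
    when omitted it defaults to the true element's centroid at evaluation
    time.
    """

    integrals: IntegralVector
    true_element: int
    target: np.ndarray | None = None

    def training_sample(self, mesh: TriMesh) -> TrainingSample:
        tgt = self.target if self.target is not None else mesh.centroid_of(
            self.true_element
        )
        return TrainingSample(self.integrals, tgt, self.true_element)


@dataclass(frozen=True)
class ErrorSummary:
    """Summary of per-sample localization errors (mm)."""

    gmean: float
    gsd: float
    gmedian: float
    pctl5: float
    pctl95: float
    n: int
    metric: str

    @classmethod
    def from_errors(cls, errors: np.ndarray, metric: str) -> "ErrorSummary":
        e = np.asarray(errors, dtype=float)
        return cls(
            gmean=float(e.mean()),
            gsd=float(e.std(ddof=1)) if len(e) > 1 else 0.0,
            gmedian=float(np.percentile(e, 50)),
            pctl5=float(np.percentile(e, 5)),
            pctl95=float(np.percentile(e, 95)),
            n=len(e),
            metric=metric,
        )


@dataclass
class BootstrapResult:
    """Per-trial g-variables and their across-trial aggregation.

    ``trials`` has one row per bootstrap trial (columns: gmean, gsd,
    gmedian, n_oob); ``table`` aggregates each g-variable across trials
    (columns: mean, sd, median, pctl5, pctl95), mirroring the standard
    bootstrap report layout.
    """

    trials: pd.DataFrame
    table: pd.DataFrame
    seed: int
    metric: str
    projector: str
    redraws: int = 0

    @property
    def mean_oob_size(self) -> float:
        return float(self.trials["n_oob"].mean())


@dataclass(frozen=True)
class ComparisonResult:
    """Paired comparison of two per-sample error vectors."""

    wilcoxon_stat: float
    p_value: float
    t_p_value: float
    mean_diff: float
    mean_diff_ci: tuple[float, float]
    degenerate: bool = False


def split_train_test(
    n: int, train_fraction: float = 0.8, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive train/test index partition.

    The training size is ``train_fraction * n`` rounded half-up, so 1,012
    samples at 0.8 give the 810/202 split of the standard protocol.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2 to split")
    n_train = int(np.floor(train_fraction * n + 0.5))  # round half up
    n_train = min(max(n_train, 1), n - 1)  # both parts non-empty
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _check_samples(samples: Sequence[LabeledSample], mesh: TriMesh) -> None:
    for s in samples:
        mesh.centroid_of(s.true_element)  # validates the id


def _element_distances(
    mesh: TriMesh, els_a: np.ndarray, els_b: np.ndarray, metric: str
) -> np.ndarray:
    """Vectorized centroid-to-centroid distances between element id arrays."""
    ca = mesh.centroids[np.asarray(els_a) - 1]
    cb = mesh.centroids[np.asarray(els_b) - 1]
    if metric == "euclidean":
        return np.linalg.norm(ca - cb, axis=1)
    va, vb = ca - mesh.cavity_center, cb - mesh.cavity_center
    ra, rb = np.linalg.norm(va, axis=1), np.linalg.norm(vb, axis=1)
    cos = np.clip((va * vb).sum(axis=1) / (ra * rb), -1.0, 1.0)
    arc = (ra + rb) / 2 * np.arccos(cos)
    arc[np.asarray(els_a) == np.asarray(els_b)] = 0.0  # exact, not ulp-level
    return arc


def _errors_for(
    results: QRSSiteResults,
    test: Sequence[LabeledSample],
    mesh: TriMesh,
    projector: str,
    metric: str,
) -> np.ndarray:
    preds = results.predict(np.array([s.integrals.values for s in test]))
    est = project_batch(mesh, preds, projector)
    true = np.array([s.true_element for s in test])
    return _element_distances(mesh, est, true, metric)


def evaluate(
    train: Sequence[LabeledSample],
    test: Sequence[LabeledSample],
    mesh: TriMesh,
    projector: str = "knn",
    metric: str = "geodesic",
) -> tuple[np.ndarray, ErrorSummary]:
    """Fit on ``train``, localize every ``test`` sample, summarize errors.

    Returns the per-sample errors (mm, in test order) and their
    :class:`ErrorSummary`.
    """
    if projector not in _PROJECTORS:
        raise ValueError(f"unknown projector '{projector}' (sa|knn)")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric '{metric}' (geodesic|euclidean)")
    _check_samples(train, mesh)
    _check_samples(test, mesh)
    if set(id(s) for s in train) & set(id(s) for s in test):
        warnings.warn("train and test sets overlap", UserWarning, stacklevel=2)
    results = QRSSiteModel.from_samples(
        [s.training_sample(mesh) for s in train]
    ).fit()
    errors = _errors_for(results, test, mesh, projector, metric)
    return errors, ErrorSummary.from_errors(errors, metric)


def bootstrap_evaluate(
    data: Sequence[LabeledSample],
    mesh: TriMesh,
    projector: str = "knn",
    metric: str = "geodesic",
    n_trials: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Out-of-bag bootstrap of the full fit-predict-project pipeline.

    Each trial resamples n training indices with replacement, refits the
    population coefficients, and evaluates on the unique left-out
    (out-of-bag) samples.  A trial whose out-of-bag set is empty is
    redrawn (logged).  Fully reproducible given ``seed``.
    """
    data = list(data)
    n = len(data)
    if n < 10:
        raise ValueError("bootstrap needs at least 10 samples")
    _check_samples(data, mesh)
    rng = np.random.default_rng(seed)
    rows, redraws = [], 0
    integrals = np.array([s.integrals.values for s in data])
    targets = np.array(
        [
            s.target if s.target is not None else mesh.centroid_of(s.true_element)
            for s in data
        ]
    )
    for _ in range(n_trials):
        while True:
            draw = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), draw)
            if len(oob):
                break
            redraws += 1
            logger.warning("bootstrap trial had an empty out-of-bag set; redrawn")
        results = QRSSiteModel(targets[draw], integrals[draw]).fit()
        test = [data[i] for i in oob]
        errors = _errors_for(results, test, mesh, projector, metric)
        summ = ErrorSummary.from_errors(errors, metric)
        rows.append(
            {
                "gmean": summ.gmean,
                "gsd": summ.gsd,
                "gmedian": summ.gmedian,
                "n_oob": len(oob),
            }
        )
    trials = pd.DataFrame(rows)
    table = pd.DataFrame(
        {
            "mean": trials[list(_G_VARS)].mean(),
            "sd": trials[list(_G_VARS)].std(ddof=1),
            "median": trials[list(_G_VARS)].median(),
            "pctl5": trials[list(_G_VARS)].quantile(0.05),
            "pctl95": trials[list(_G_VARS)].quantile(0.95),
        }
    )
    return BootstrapResult(
        trials=trials,
        table=table,
        seed=seed,
        metric=metric,
        projector=projector,
        redraws=redraws,
    )


def bootstrap_compare(
    data: Sequence[LabeledSample],
    mesh: TriMesh,
    projectors: tuple[str, str] = ("knn", "sa"),
    metric: str = "geodesic",
    n_trials: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, BootstrapResult], ComparisonResult]:
    """Paired bootstrap comparison of two projection rules.

    Runs :func:`bootstrap_evaluate` for both projectors with the *same*
    seed, so every trial uses identical resamples and identical fitted
    coefficients, and the per-trial mean errors are exactly paired.  The
    Wilcoxon signed-rank test over the paired per-trial gmeans is the
    bootstrap significance assessment of the mean-accuracy difference.
    """
    results = {
        p: bootstrap_evaluate(data, mesh, p, metric, n_trials, seed)
        for p in projectors
    }
    a, b = (results[p].trials["gmean"].to_numpy() for p in projectors)
    return results, compare_projectors(a, b, seed=seed)


def compare_projectors(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> ComparisonResult:
    """Paired two-sided comparison of per-sample errors from two methods.

    Wilcoxon signed-rank is the primary test; the paired t-test p-value
    and a percentile-bootstrap 95% CI of the mean difference (a - b) are
    reported alongside.  If every paired difference is zero the comparison
    is degenerate and p = 1 is reported.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired error vectors must be 1-D and equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    rng = np.random.default_rng(seed)
    boot_means = rng.choice(diff, size=(n_boot, len(diff)), replace=True).mean(axis=1)
    ci = (float(np.percentile(boot_means, 2.5)), float(np.percentile(boot_means, 97.5)))
    if np.all(diff == 0):
        return ComparisonResult(
            wilcoxon_stat=0.0,
            p_value=1.0,
            t_p_value=1.0,
            mean_diff=0.0,
            mean_diff_ci=(0.0, 0.0),
            degenerate=True,
        )
    w = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    t = stats.ttest_rel(a, b)
    return ComparisonResult(
        wilcoxon_stat=float(w.statistic),
        p_value=float(w.pvalue),
        t_p_value=float(t.pvalue),
        mean_diff=mean_diff,
        mean_diff_ci=ci,
    )


def iqr_outliers(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Tukey fences: flag values beyond 1.5 IQR outside the quartiles.

    Quartiles use linear interpolation between order statistics.  Returns
    a boolean flag array and the (lower, upper) fences.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("need at least 4 values for IQR outlier detection")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (v < lo) | (v > hi), (float(lo), float(hi))
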