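"""Population regression linking QRS integrals to LV site coordinates.

The localization hypothesis is linear: each Cartesian coordinate of an
early-activation site is an affine function of the eight QRS integrals,

    x = a0 + sum_i a_i V_i,   y = b0 + sum_i b_i V_i,   z = g0 + sum_i g_i V_i,

with three independent nine-term ("population") coefficient sets fitted by
ordinary least squares on a training set of (pacing site, integrals)
pairs.  Prediction is a plain affine evaluation of the fitted equations.

The API follows the Model/Results convention: build a
:class:`QRSSiteModel` from data, call :meth:`~QRSSiteModel.fit`, and use
the returned :class:`QRSSiteResults` for prediction, diagnostics and the
coefficient table.  The module-level functions
:func:`fit_population_coefficients` / :func:`predict_site` are thin
wrappers over the same path.

Rank-deficient designs (noiseless synthetic data occupies a 3-D affine
subspace of the 8-D feature space) are solved by the minimum-norm
least-squares solution, with a warning.  No predictor standardization and
no regularization: the method fits raw integrals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ecg import LEAD_ORDER, IntegralVector

__all__ = [
    "TrainingSample",
    "PopulationCoefficients",
    "PredictedSite",
    "QRSSiteModel",
    "QRSSiteResults",
    "fit_population_coefficients",
    "predict_site",
    "save_coefficients",
    "load_coefficients",
    "CoefficientsIOError",
    "LeadOrderError",
    "RankDeficientWarning",
]

_COEFF_FORMAT_VERSION = 1
_COORDS = ("x", "y", "z")


class CoefficientsIOError(ValueError):
    """Coefficient file fails schema or version validation."""


class LeadOrderError(ValueError):
    """Lead order of features does not match the coefficients' metadata."""


class RankDeficientWarning(UserWarning):
    """The regression design was rank deficient; minimum-norm solution used."""


@dataclass(frozen=True)
class TrainingSample:
    """One labelled pacing beat: 8 integrals and the site coordinates (mm)."""

    integrals: IntegralVector
    target: np.ndarray
    true_element: int | None = None

    def __post_init__(self) -> None:
        tgt = np.asarray(self.target, dtype=float).reshape(3)
        if not np.all(np.isfinite(tgt)):
            raise ValueError("target coordinates must be finite")
        object.__setattr__(self, "target", tgt)


@dataclass(frozen=True)
class PredictedSite:
    """Predicted 3-D site (mm) in the generic-mesh frame."""

    point: np.ndarray

    def __post_init__(self) -> None:
        pt = np.asarray(self.point, dtype=float).reshape(3)
        if not np.all(np.isfinite(pt)):
            raise ValueError("predicted coordinates must be finite")
        object.__setattr__(self, "point", pt)


@dataclass(frozen=True)
class PopulationCoefficients:
    """Three 9-term coefficient sets (intercept first).

    Units: intercepts mm, slopes mm/(uV*s).  ``lead_order`` records the
    feature order the slopes refer to; prediction refuses a mismatch
    rather than silently reordering.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    lead_order: tuple[str, ...] = LEAD_ORDER
    n: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            if arr.shape != (9,):
                raise CoefficientsIOError(
                    f"{name} must have 9 entries (intercept + 8 slopes), "
                    f"got {arr.size}"
                )
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "lead_order", tuple(self.lead_order))
        if len(self.lead_order) != 8:
            raise CoefficientsIOError("lead_order must name 8 leads")

    def as_matrix(self) -> np.ndarray:
        """(9, 3) stacked coefficients, rows = intercept + 8 slopes."""
        return np.column_stack([self.alpha, self.beta, self.gamma])


class QRSSiteModel:
    """The eight-integral / three-coordinate linear localization model.

    Parameters
    ----------
    targets : (n, 3) array
        Site coordinates in mm (the regression response).
    integrals : (n, 8) array
        QRS integrals in uV*s, columns in ``lead_order``.
    lead_order : tuple of str
        Feature order of the integral columns.
    """

    def __init__(
        self,
        targets: np.ndarray,
        integrals: np.ndarray,
        lead_order: Sequence[str] = LEAD_ORDER,
    ) -> None:
        self.targets = np.asarray(targets, dtype=float)
        self.integrals = np.asarray(integrals, dtype=float)
        self.lead_order = tuple(lead_order)
        if self.targets.ndim != 2 or self.targets.shape[1] != 3:
            raise ValueError("targets must be (n, 3)")
        if self.integrals.shape != (len(self.targets), 8):
            raise ValueError("integrals must be (n, 8), aligned with targets")
        if len(self.targets) == 0:
            raise ValueError("empty training set")
        if not (
            np.all(np.isfinite(self.targets))
            and np.all(np.isfinite(self.integrals))
        ):
            raise ValueError("non-finite values in training data")

    @classmethod
    def from_samples(cls, samples: Iterable[TrainingSample]) -> "QRSSiteModel":
        samples = list(samples)
        if not samples:
            raise ValueError("empty training set")
        order = samples[0].integrals.lead_order
        if any(s.integrals.lead_order != order for s in samples):
            raise LeadOrderError("training samples disagree on lead order")
        return cls(
            np.array([s.target for s in samples]),
            np.array([s.integrals.values for s in samples]),
            order,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target_cols: Sequence[str] = _COORDS,
        lead_cols: Sequence[str] = LEAD_ORDER,
    ) -> "QRSSiteModel":
        return cls(
            df[list(target_cols)].to_numpy(),
            df[list(lead_cols)].to_numpy(),
            tuple(lead_cols),
        )

    def fit(self) -> "QRSSiteResults":
        """OLS fit of all three coordinate equations.

        Uses the minimum-norm least-squares solution, which coincides with
        ordinary OLS on full-rank designs and remains well defined (and
        consistent with the observed data) when the design is rank
        deficient.
        """
        X = np.column_stack([np.ones(len(self.integrals)), self.integrals])
        W, _, rank, sv = np.linalg.lstsq(X, self.targets, rcond=None)
        if rank < X.shape[1]:
            warnings.warn(
                f"design rank {rank} < {X.shape[1]}; "
                "minimum-norm least-squares solution used",
                RankDeficientWarning,
                stacklevel=2,
            )
        resid = self.targets - X @ W
        rss = (resid**2).sum(axis=0)
        coeffs = PopulationCoefficients(
            W[:, 0], W[:, 1], W[:, 2], self.lead_order, n=len(self.targets)
        )
        return QRSSiteResults(self, coeffs, rss=rss, rank=rank, singular_values=sv)


class QRSSiteResults:
    """Fitted population coefficients plus diagnostics."""

    def __init__(
        self,
        model: QRSSiteModel,
        coefficients: PopulationCoefficients,
        rss: np.ndarray,
        rank: int,
        singular_values: np.ndarray,
    ) -> None:
        self.model = model
        self.coefficients = coefficients
        self.rss = np.asarray(rss, dtype=float)
        self.rank = int(rank)
        self.singular_values = np.asarray(singular_values, dtype=float)

    @property
    def nobs(self) -> int:
        return len(self.model.targets)

    def predict(self, integrals: np.ndarray | IntegralVector) -> np.ndarray:
        """Affine evaluation; accepts one IntegralVector or an (m, 8) array."""
        if isinstance(integrals, IntegralVector):
            return predict_site(self.coefficients, integrals).point
        arr = np.asarray(integrals, dtype=float)
        squeeze = arr.ndim == 1
        arr = np.atleast_2d(arr)
        if arr.shape[1] != 8:
            raise ValueError("integrals must have 8 columns")
        W = self.coefficients.as_matrix()
        out = W[0] + arr @ W[1:]
        return out[0] if squeeze else out

    def summary(self) -> str:
        """Plain-text coefficient table in the three-equation layout."""
        rows = ["intercept"] + [f"slope[{l}]" for l in self.coefficients.lead_order]
        W = self.coefficients.as_matrix()
        lines = [
            "QRS-integral site localization (OLS, 3 coordinate equations)",
            f"n = {self.nobs}   design rank = {self.rank}/9",
            f"RSS (mm^2): x={self.rss[0]:.4g}  y={self.rss[1]:.4g}  "
            f"z={self.rss[2]:.4g}",
            "",
            f"{'term':<12}{'x (alpha)':>14}{'y (beta)':>14}{'z (gamma)':>14}",
        ]
        for i, name in enumerate(rows):
            lines.append(
                f"{name:<12}{W[i, 0]:>14.6g}{W[i, 1]:>14.6g}{W[i, 2]:>14.6g}"
            )
        return "\n".join(lines)


def fit_population_coefficients(
    training: Iterable[TrainingSample],
) -> PopulationCoefficients:
    """Fit the three population coefficient sets from labelled samples."""
    return QRSSiteModel.from_samples(training).fit().coefficients


def predict_site(
    coeffs: PopulationCoefficients, integrals: IntegralVector
) -> PredictedSite:
    """Evaluate the three fitted equations at one integral vector."""
    if tuple(integrals.lead_order) != tuple(coeffs.lead_order):
        raise LeadOrderError(
            f"integral lead order {integrals.lead_order} does not match "
            f"coefficients' {coeffs.lead_order}; refusing to reorder silently"
        )
    W = coeffs.as_matrix()
    return PredictedSite(W[0] + integrals.values @ W[1:])


def save_coefficients(coeffs: PopulationCoefficients, path: str | Path) -> None:
    """Serialize to versioned JSON at full precision."""
    Path(path).write_text(
        json.dumps(
            {
                "format_version": _COEFF_FORMAT_VERSION,
                "units": {"intercept": "mm", "slope": "mm/(uV*s)"},
                "n": coeffs.n,
                "lead_order": list(coeffs.lead_order),
                "alpha": coeffs.alpha.tolist(),
                "beta": coeffs.beta.tolist(),
                "gamma": coeffs.gamma.tolist(),
            },
            indent=1,
        )
    )


def load_coefficients(path: str | Path) -> PopulationCoefficients:
    """Load and validate a coefficient file (version, shape, lead order)."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CoefficientsIOError(f"cannot read coefficient file {path}: {exc}")
    if doc.get("format_version") != _COEFF_FORMAT_VERSION:
        raise CoefficientsIOError(
            f"unsupported coefficient format version {doc.get('format_version')}"
        )
    lead_order = tuple(doc.get("lead_order", ()))
    if lead_order != LEAD_ORDER:
        raise CoefficientsIOError(
            f"lead order {lead_order} does not match the required {LEAD_ORDER}"
        )
    missing = [k for k in ("alpha", "beta", "gamma") if k not in doc]
    if missing:
        raise CoefficientsIOError(f"coefficient file missing {missing}")
    return PopulationCoefficients(
        np.array(doc["alpha"]),
        np.array(doc["beta"]),
        np.array(doc["gamma"]),
        lead_order,
        n=int(doc.get("n", 0)),
    )
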