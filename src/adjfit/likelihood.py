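"""Measurement data container and the negative log-likelihood objective.

For independent Gaussian noise with known standard deviations sigma_ij the
negative log-likelihood (up to an additive constant) is the weighted least
squares

    J(theta) = 1/2 * sum_ij [ (ybar_ij - y_i(t_j, theta)) / sigma_ij ]^2

summed over observed entries only; missing values are carried as an
explicit mask so the sum stays well-defined without sentinel arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Trajectory

__all__ = ["ExperimentData", "ObjectiveValue", "DataError", "AlignmentError", "negloglik"]


class DataError(ValueError):
    """Inconsistent measurement data (e.g. non-positive sigma, unsorted times)."""


class AlignmentError(ValueError):
    """Trajectory and data disagree on the measurement time grid."""


@dataclass
class ExperimentData:
    """Discrete-time noisy measurements on a time x observable grid.

    ``values`` and ``sigmas`` have shape (n_y, N); ``mask`` is True where a
    value was observed.  ``sigmas`` may be given as a scalar or one value
    per observable and is broadcast.
    """

    times: np.ndarray
    values: np.ndarray
    sigmas: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n_y, n_t = self.values.shape
        if self.times.ndim != 1 or self.times.size != n_t:
            raise DataError(
                f"times has length {self.times.size}, values has {n_t} columns"
            )
        if np.any(np.diff(self.times) <= 0):
            raise DataError("measurement times must be strictly increasing")
        self.sigmas = np.broadcast_to(
            np.asarray(self.sigmas, dtype=float).reshape(-1, 1)
            if np.ndim(self.sigmas) == 1
            else np.asarray(self.sigmas, dtype=float),
            self.values.shape,
        ).copy()
        if self.mask is None:
            self.mask = ~np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise DataError("mask shape must match values shape")
        # NaN cells are always treated as missing
        self.mask &= ~np.isnan(self.values)
        if np.any(self.sigmas[self.mask] <= 0) or np.any(
            ~np.isfinite(self.sigmas[self.mask])
        ):
            raise DataError("sigma must be strictly positive on observed entries")

    @property
    def n_y(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


@dataclass
class ObjectiveValue:
    """Objective J and the weighted residuals it is built from.

    ``residuals`` has shape (n_y, N) with zeros at masked entries; ``J``
    equals half the sum of squared residuals over observed entries.
    """

    J: float
    residuals: np.ndarray
    mask: np.ndarray

    @property
    def residual_vector(self) -> np.ndarray:
        """Flat vector of observed residuals (row-major over observables)."""
        return self.residuals[self.mask]


def _check_alignment(traj: Trajectory, data: ExperimentData) -> None:
    if traj.times.size != data.times.size or not np.allclose(
        traj.times, data.times, rtol=1e-12, atol=1e-12
    ):
        raise AlignmentError("trajectory and data measurement times differ")
    if traj.outputs.shape[1] != data.n_y:
        raise AlignmentError(
            f"trajectory has {traj.outputs.shape[1]} observables, data has {data.n_y}"
        )


def negloglik(traj: Trajectory, data: ExperimentData) -> ObjectiveValue:
    """Evaluate J(theta) = 1/2 sum of squared weighted residuals.

    Masked (missing) entries contribute nothing.  Raises
    :class:`AlignmentError` if the trajectory was not simulated on the
    data's time grid.
    """
    _check_alignment(traj, data)
    res = np.zeros_like(data.values)
    y = traj.outputs.T  # (n_y, N)
    res[data.mask] = (data.values[data.mask] - y[data.mask]) / data.sigmas[data.mask]
    J = 0.5 * float(np.sum(res[data.mask] ** 2))
    return ObjectiveValue(J=J, residuals=res, mask=data.mask.copy())


def residual_weights(traj: Trajectory, data: ExperimentData) -> np.ndarray:
    """(ybar - y)/sigma^2 on observed entries, zero elsewhere; shape (n_y, N).

    This is the weight vector that drives both the forward-sensitivity
    gradient sum and the adjoint-state reinitialisation jumps.
    """
    _check_alignment(traj, data)
    w = np.zeros_like(data.values)
    y = traj.outputs.T
    w[data.mask] = (data.values[data.mask] - y[data.mask]) / data.sigmas[data.mask] ** 2
    return w
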