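"""Multivariate temporal response function (mTRF) estimation by boosting.

The response at time ``t`` is modelled as a sum of convolutions::

    yhat_t = sum_i sum_tau h[i, tau] * x[i, t - tau]

with kernels ``h`` spanning delays from -100 to +990 ms (at 100 Hz), built
from a basis of 50 ms wide Hamming windows centred every 10 ms.  Kernels are
estimated by greedy coordinate descent ("boosting"): at each iteration every
basis coefficient is probed with a small +/- step and the proposal that most
reduces the training l1 error is applied; a proposal that would increase the
validation error instead freezes its whole predictor channel.  The returned
weights are the snapshot with minimal validation error.

The user-facing surface follows the fit/results idiom:
:class:`TemporalResponseModel` is built from a response and a
:class:`~cohorttrf.predictors.PredictorSet`; :meth:`TemporalResponseModel.fit`
runs nested cross-validation and returns :class:`TRFResults` carrying
kernels, held-out predictive power, per-fold diagnostics, and a
``summary()`` table.  The lower-level :func:`boost`, :func:`cross_validate`,
:func:`predict` and :func:`explained_variability` functions are the building
blocks and remain public.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .predictors import PredictorSet, standardize

__all__ = [
    "TRFBasis",
    "TRFModel",
    "FitResult",
    "TemporalResponseModel",
    "TRFResults",
    "predict",
    "boost",
    "cross_validate",
    "explained_variability",
    "unique_power",
]


class TRFBasis:
    """Hamming-window basis over a sampled delay axis.

    Parameters
    ----------
    tmin, tmax
        Delay window in seconds (default -0.1 to 1.0; the right edge is
        exclusive).
    rate
        Sampling rate (Hz); basis centers are placed at every delay sample.
    width
        Width of each Hamming element in seconds (default 0.05).
    """

    def __init__(
        self,
        tmin: float = -0.1,
        tmax: float = 1.0,
        rate: float = 100.0,
        width: float = 0.05,
    ):
        if tmax <= tmin:
            raise ValueError("tmax must exceed tmin")
        self.tmin, self.tmax, self.rate, self.width = tmin, tmax, rate, width
        self.delays = np.arange(int(round(tmin * rate)), int(round(tmax * rate)))
        n = len(self.delays)
        w_samp = int(round(width * rate))
        if w_samp < 1:
            raise ValueError("basis width below one sample")
        window = np.hamming(w_samp)
        half = (w_samp - 1) // 2
        B = np.zeros((n, n))
        for j in range(n):
            for k in range(w_samp):
                idx = j + k - half
                if 0 <= idx < n:
                    B[idx, j] = window[k]
        self.matrix = B  # (n_delays, n_basis)

    @property
    def n_delays(self) -> int:
        return len(self.delays)

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[1]

    @property
    def delay_times(self) -> np.ndarray:
        return self.delays / self.rate

    def expand(self, weights: np.ndarray) -> np.ndarray:
        """Kernel over sampled delays for basis ``weights`` (last axis)."""
        weights = np.asarray(weights, float)
        return weights @ self.matrix.T

    def project(self, kernel: np.ndarray) -> np.ndarray:
        """Least-squares basis weights reproducing ``kernel`` (exact in span)."""
        kernel = np.asarray(kernel, float)
        w, *_ = np.linalg.lstsq(self.matrix, kernel.T, rcond=None)
        return w.T

    def design(self, features: np.ndarray) -> np.ndarray:
        """Basis-expanded design matrix for ``(n_features, n_time)`` input.

        Returns ``(n_features * n_basis, n_time)``: row ``i*n_basis + j`` is
        feature ``i`` convolved with basis element ``j`` over the delay axis
        (out-of-range history treated as zero).
        """
        features = np.atleast_2d(np.asarray(features, float))
        n_feat, n_time = features.shape
        shifted = np.zeros((self.n_delays, n_time))
        out = np.empty((n_feat * self.n_basis, n_time))
        for i in range(n_feat):
            x = features[i]
            for ti, d in enumerate(self.delays):
                if d == 0:
                    shifted[ti] = x
                elif d > 0:
                    shifted[ti, :d] = 0.0
                    shifted[ti, d:] = x[:-d]
                else:
                    shifted[ti, d:] = 0.0
                    shifted[ti, :d] = x[-d:]
            out[i * self.n_basis : (i + 1) * self.n_basis] = self.matrix.T @ shifted
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TRFBasis)
            and (self.tmin, self.tmax, self.rate, self.width)
            == (other.tmin, other.tmax, other.rate, other.width)
        )

    def __repr__(self) -> str:
        return (
            f"<TRFBasis: [{self.tmin*1e3:.0f}, {self.tmax*1e3:.0f}) ms, "
            f"{self.n_basis} x {self.width*1e3:.0f} ms Hamming @ {self.rate:.0f} Hz>"
        )


@dataclass
class TRFModel:
    """Estimated kernels for a set of named predictor features."""

    basis: TRFBasis
    feature_names: list[str]
    weights: np.ndarray  # (n_features, n_basis)
    n_iterations: int = 0
    train_error: float = np.nan
    val_error: float = np.nan

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if self.weights.shape != (len(self.feature_names), self.basis.n_basis):
            raise ValueError("weight shape does not match features x basis")

    @property
    def kernels(self) -> np.ndarray:
        """Expanded kernels ``(n_features, n_delays)``; exactly basis @ weights."""
        return self.basis.expand(self.weights)


def predict(model: TRFModel, predictors: PredictorSet | np.ndarray) -> np.ndarray:
    """Predicted response ``yhat_t = sum_i sum_tau h[i,tau] x[i,t-tau]``."""
    if isinstance(predictors, PredictorSet):
        if predictors.feature_names != model.feature_names:
            raise ValueError(
                "predictor features do not match the model: "
                f"{predictors.feature_names} vs {model.feature_names}"
            )
        if predictors.rate != model.basis.rate:
            raise ValueError("sampling rate mismatch")
        features = predictors.to_array()
    else:
        features = np.atleast_2d(np.asarray(predictors, float))
        if features.shape[0] != len(model.feature_names):
            raise ValueError("feature count does not match the model")
    kernels = model.kernels
    n_time = features.shape[1]
    yhat = np.zeros(n_time)
    for i in range(features.shape[0]):
        x = features[i]
        for h, d in zip(kernels[i], model.basis.delays):
            if h == 0.0:
                continue
            if d == 0:
                yhat += h * x
            elif d > 0:
                yhat[d:] += h * x[:-d]
            else:
                yhat[:d] += h * x[-d:]
    return yhat


@njit(cache=True)
def _boost_loop(Ztr, Zval, ytr, yval, coef_channel, n_channels, step, max_iter):
    """Greedy l1 coordinate descent with per-channel validation freezing.

    Returns (best_weights, n_iter, final_train_err, best_val_err,
    train_err_path) where the path records the training error after each
    applied proposal.
    """
    n_coef, n_tr = Ztr.shape
    n_val = Zval.shape[1]
    w = np.zeros(n_coef)
    best_w = np.zeros(n_coef)
    r_tr = ytr.copy()
    r_val = yval.copy()
    frozen = np.zeros(n_channels, np.bool_)
    train_err = 0.0
    for t in range(n_tr):
        train_err += abs(r_tr[t])
    val_err = 0.0
    for t in range(n_val):
        val_err += abs(r_val[t])
    best_val = val_err
    path = np.empty(max_iter)
    n_applied = 0
    it = 0
    while it < max_iter:
        it += 1
        best_delta = -1e-12
        best_j = -1
        best_sign = 0.0
        for j in range(n_coef):
            if frozen[coef_channel[j]]:
                continue
            d_plus = 0.0
            d_minus = 0.0
            for t in range(n_tr):
                x = Ztr[j, t]
                if x != 0.0:
                    r = r_tr[t]
                    a = abs(r)
                    sx = step * x
                    d_plus += abs(r - sx) - a
                    d_minus += abs(r + sx) - a
            if d_plus < best_delta:
                best_delta = d_plus
                best_j = j
                best_sign = 1.0
            if d_minus < best_delta:
                best_delta = d_minus
                best_j = j
                best_sign = -1.0
        if best_j < 0:
            break  # no proposal reduces the training error
        # validation effect of the selected proposal
        d_val = 0.0
        for t in range(n_val):
            x = Zval[best_j, t]
            if x != 0.0:
                r = r_val[t]
                d_val += abs(r - best_sign * step * x) - abs(r)
        if d_val > 0.0:
            frozen[coef_channel[best_j]] = True
            all_frozen = True
            for c in range(n_channels):
                if not frozen[c]:
                    all_frozen = False
                    break
            if all_frozen:
                break
            continue
        # apply
        w[best_j] += best_sign * step
        for t in range(n_tr):
            x = Ztr[best_j, t]
            if x != 0.0:
                r_tr[t] -= best_sign * step * x
        for t in range(n_val):
            x = Zval[best_j, t]
            if x != 0.0:
                r_val[t] -= best_sign * step * x
        train_err += best_delta
        val_err += d_val
        path[n_applied] = train_err
        n_applied += 1
        if val_err < best_val:
            best_val = val_err
            best_w[:] = w
    return best_w, n_applied, train_err, best_val, path[:n_applied]


def boost(
    predictors: PredictorSet | np.ndarray,
    response: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    step: float = 0.005,
    max_iter: int = 2000,
    basis: TRFBasis | None = None,
    design: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
    channel_index: np.ndarray | None = None,
) -> TRFModel:
    """Estimate a TRF on ``train_idx`` with early stopping on ``val_idx``.

    ``train_idx`` and ``val_idx`` are disjoint contiguous sample-index
    arrays.  A precomputed ``design`` matrix (from :meth:`TRFBasis.design`)
    may be passed to avoid recomputation across folds.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    response = np.asarray(response, float)
    if not np.isfinite(response).all():
        raise ValueError("non-finite values in response")
    train_idx = np.asarray(train_idx, np.int64)
    val_idx = np.asarray(val_idx, np.int64)
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and validation indices overlap")

    if isinstance(predictors, PredictorSet):
        if basis is None:
            basis = TRFBasis(rate=predictors.rate)
        feature_names = predictors.feature_names
        channel_index = predictors.feature_channel_index()
        if design is None:
            design = basis.design(predictors.to_array())
    else:
        if basis is None:
            basis = TRFBasis()
        features = np.atleast_2d(np.asarray(predictors, float))
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(features.shape[0])]
        if channel_index is None:
            channel_index = np.arange(features.shape[0], dtype=np.int64)
        if design is None:
            design = basis.design(features)

    coef_channel = np.repeat(np.asarray(channel_index, np.int64), basis.n_basis)
    n_channels = int(coef_channel.max()) + 1
    Ztr = np.ascontiguousarray(design[:, train_idx])
    Zval = np.ascontiguousarray(design[:, val_idx])
    w, n_iter, train_err, val_err, _ = _boost_loop(
        Ztr,
        Zval,
        response[train_idx],
        response[val_idx],
        coef_channel,
        n_channels,
        float(step),
        int(max_iter),
    )
    weights = w.reshape(len(feature_names), basis.n_basis)
    return TRFModel(
        basis=basis,
        feature_names=list(feature_names),
        weights=weights,
        n_iterations=n_iter,
        train_error=train_err,
        val_error=val_err,
    )


def explained_variability(
    y: np.ndarray, yhat: np.ndarray, metric: str = "l1"
) -> float:
    """Proportion of response variability explained by the prediction.

    ``l1`` form: ``1 - sum|y - yhat| / sum|y - mean(y)|`` (the analogue of
    R^2 under the l1 loss used for fitting); ``l2`` gives the squared-error
    variant.  May be negative for predictions worse than the mean.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    centered = y - y.mean()
    if metric == "l1":
        denom = np.abs(centered).sum()
        if denom == 0:
            raise ValueError("constant response; explained variability undefined")
        return 1.0 - np.abs(y - yhat).sum() / denom
    elif metric == "l2":
        denom = (centered**2).sum()
        if denom == 0:
            raise ValueError("constant response; explained variability undefined")
        return 1.0 - ((y - yhat) ** 2).sum() / denom
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class FitResult:
    """Cross-validated TRF estimate for one or more response sources."""

    basis: TRFBasis
    feature_names: list[str]
    weights: np.ndarray  # (n_sources, n_features, n_basis), fold-averaged
    power: np.ndarray  # (n_sources,) held-out l1 proportion explained
    power_l2: np.ndarray  # (n_sources,) squared-error variant
    r: np.ndarray  # (n_sources,) held-out Pearson correlation
    k: int
    n_boost_calls: int
    fold_diagnostics: list = field(default_factory=list)

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]

    @property
    def kernels(self) -> np.ndarray:
        """(n_sources, n_features, n_delays)"""
        return self.basis.expand(self.weights)


def _partitions(n: int, k: int) -> list[np.ndarray]:
    return [np.asarray(p, np.int64) for p in np.array_split(np.arange(n), k)]


def cross_validate(
    predictors: PredictorSet | np.ndarray,
    response: np.ndarray,
    k: int = 5,
    step: float = 0.005,
    max_iter: int = 2000,
    basis: TRFBasis | None = None,
    feature_names: Sequence[str] | None = None,
) -> FitResult:
    """Nested k-fold cross-validated TRF estimation.

    The session is split into ``k`` contiguous near-equal partitions.  Each
    partition serves as test data once; within the remaining ``k - 1``
    partitions, each serves as validation data once, yielding ``k - 1``
    boosted models whose average predicts the test partition.  Held-out
    predictive power is computed on the concatenated test predictions only.
    The returned TRF is the mean over all ``k*(k-1)`` estimates.

    ``response`` may be ``(n_time,)`` or ``(n_sources, n_time)``; sources are
    fit independently and results do not depend on source order.
    """
    if k < 3:
        raise ValueError("k-fold TRF estimation needs k >= 3 (train/val/test)")
    response = np.asarray(response, float)
    one_d = response.ndim == 1
    Y = response[None, :] if one_d else response
    n_sources, n_time = Y.shape

    if isinstance(predictors, PredictorSet):
        if basis is None:
            basis = TRFBasis(rate=predictors.rate)
        feature_names = predictors.feature_names
        channel_index = predictors.feature_channel_index()
        design = basis.design(predictors.to_array())
        if predictors.n_samples != n_time:
            raise ValueError("response length does not match predictors")
    else:
        features = np.atleast_2d(np.asarray(predictors, float))
        if basis is None:
            basis = TRFBasis()
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(features.shape[0])]
        channel_index = np.arange(features.shape[0], dtype=np.int64)
        design = basis.design(features)
        if features.shape[1] != n_time:
            raise ValueError("response length does not match predictors")

    parts = _partitions(n_time, k)
    n_feat = len(feature_names)
    all_weights = np.zeros((n_sources, n_feat, basis.n_basis))
    power = np.empty(n_sources)
    power_l2 = np.empty(n_sources)
    r = np.empty(n_sources)
    n_calls = 0
    diagnostics = []

    for s in range(n_sources):
        y = Y[s]
        yhat = np.empty(n_time)
        source_weights = []
        for i_test in range(k):
            test_idx = parts[i_test]
            fold_weights = []
            for i_val in range(k):
                if i_val == i_test:
                    continue
                val_idx = parts[i_val]
                train_idx = np.concatenate(
                    [parts[j] for j in range(k) if j not in (i_test, i_val)]
                )
                model = boost(
                    predictors if isinstance(predictors, PredictorSet) else design,
                    y,
                    train_idx,
                    val_idx,
                    step=step,
                    max_iter=max_iter,
                    basis=basis,
                    design=design,
                    feature_names=feature_names,
                    channel_index=channel_index,
                )
                n_calls += 1
                fold_weights.append(model.weights)
                diagnostics.append(
                    {
                        "source": s,
                        "test": i_test,
                        "val": i_val,
                        "n_iterations": model.n_iterations,
                        "val_error": model.val_error,
                    }
                )
            avg = np.mean(fold_weights, axis=0)
            source_weights.append(avg)
            yhat[test_idx] = _predict_from_design(design, avg, test_idx)
        all_weights[s] = np.mean(source_weights, axis=0)
        power[s] = explained_variability(y, yhat, "l1")
        power_l2[s] = explained_variability(y, yhat, "l2")
        sd = y.std()
        r[s] = np.corrcoef(y, yhat)[0, 1] if sd > 0 and yhat.std() > 0 else 0.0

    return FitResult(
        basis=basis,
        feature_names=list(feature_names),
        weights=all_weights,
        power=power[0:1] if one_d else power,
        power_l2=power_l2[0:1] if one_d else power_l2,
        r=r[0:1] if one_d else r,
        k=k,
        n_boost_calls=n_calls,
        fold_diagnostics=diagnostics,
    )


def _predict_from_design(design: np.ndarray, weights: np.ndarray, idx: np.ndarray):
    """Prediction at samples ``idx`` from the precomputed design matrix."""
    return design[:, idx].T @ weights.ravel()


def unique_power(full: FitResult, reduced: FitResult, metric: str = "l1") -> np.ndarray:
    """Per-source unique predictive power: full minus reduced model.

    Both fits must share the fold structure (same ``k``) and sources.
    """
    if full.k != reduced.k:
        raise ValueError("fold structure mismatch between fits")
    a = full.power if metric == "l1" else full.power_l2
    b = reduced.power if metric == "l1" else reduced.power_l2
    if a.shape != b.shape:
        raise ValueError("source count mismatch between fits")
    return a - b


# ---------------------------------------------------------------------------
# model / results objects


class TemporalResponseModel:
    """Encoding model mapping a predictor set to one or more response sources.

    Parameters
    ----------
    response
        ``(n_time,)`` or ``(n_sources, n_time)`` response array on the same
        clock as the predictors.
    predictors
        The stimulus :class:`~cohorttrf.predictors.PredictorSet`.
    basis
        Delay basis; defaults to 50 ms Hamming windows on [-100, 1000) ms.
    standardize_data
        Standardize predictors and response (center, scale by mean absolute
        value) before fitting, as is conventional for boosting.
    """

    def __init__(
        self,
        response: np.ndarray,
        predictors: PredictorSet,
        basis: TRFBasis | None = None,
        standardize_data: bool = True,
    ):
        response = np.asarray(response, float)
        n_time = response.shape[-1]
        if predictors.n_samples != n_time:
            raise ValueError("response and predictors differ in length")
        self.predictors_raw = predictors
        self.response_raw = response
        self.basis = basis or TRFBasis(rate=predictors.rate)
        self.standardized = standardize_data
        if standardize_data:
            self.predictors = standardize(predictors)
            self.response = standardize(response)
        else:
            self.predictors = predictors
            self.response = response

    def fit(self, k: int = 5, step: float = 0.005, max_iter: int = 2000) -> "TRFResults":
        result = cross_validate(
            self.predictors,
            self.response,
            k=k,
            step=step,
            max_iter=max_iter,
            basis=self.basis,
        )
        return TRFResults(self, result)


class TRFResults:
    """Results of a cross-validated TRF fit.

    Exposes the fold-averaged kernels, held-out predictive power (l1
    proportion of variability explained), its squared-error variant and the
    held-out Pearson ``r``, plus :meth:`summary` and :meth:`plot_kernels`.
    """

    def __init__(self, model: TemporalResponseModel, result: FitResult):
        self.model = model
        self.result = result

    # delegated views -------------------------------------------------
    @property
    def basis(self) -> TRFBasis:
        return self.result.basis

    @property
    def feature_names(self) -> list[str]:
        return self.result.feature_names

    @property
    def kernels(self) -> np.ndarray:
        return self.result.kernels

    @property
    def power(self) -> np.ndarray:
        return self.result.power

    @property
    def power_l2(self) -> np.ndarray:
        return self.result.power_l2

    @property
    def r(self) -> np.ndarray:
        return self.result.r

    def predict(self, predictors: PredictorSet | None = None) -> np.ndarray:
        """Predicted (standardized-scale) response for each source."""
        ps = predictors or self.model.predictors
        out = []
        for s in range(self.result.n_sources):
            m = TRFModel(self.basis, self.feature_names, self.result.weights[s])
            out.append(predict(m, ps))
        arr = np.asarray(out)
        return arr[0] if self.model.response_raw.ndim == 1 else arr

    def summary(self) -> str:
        lines = [
            "Temporal response function fit (l1 boosting)",
            f"  delay basis:        {self.basis!r}",
            f"  predictors:         {', '.join(self.feature_names)}",
            f"  folds (k):          {self.result.k} "
            f"({self.result.n_boost_calls} boosting runs)",
            f"  sources:            {self.result.n_sources}",
            "",
            "  held-out performance (per source):",
            f"    l1 explained:     {_fmt(self.power)}",
            f"    l2 explained:     {_fmt(self.power_l2)}",
            f"    Pearson r:        {_fmt(self.r)}",
        ]
        return "\n".join(lines)

    def plot_kernels(self, source: int = 0, ax=None):
        """Plot each predictor's kernel over delay for one source."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.basis.delay_times * 1e3
        for name, kern in zip(self.feature_names, self.kernels[source]):
            ax.plot(t, kern, label=name)
        ax.set_xlabel("delay (ms)")
        ax.set_ylabel("kernel weight (standardized units)")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.legend(fontsize="small")
        return ax


def _fmt(arr: np.ndarray) -> str:
    arr = np.atleast_1d(arr)
    if arr.size <= 4:
        return ", ".join(f"{v:.4f}" for v in arr)
    return (
        f"median {np.median(arr):.4f}, max {arr.max():.4f} over {arr.size} sources"
    )
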