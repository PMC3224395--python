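"""Per-window sEMG features: waveform length, RMS and AR(4) coefficients.

Each 256-sample window yields six features per channel — waveform length
(sum of absolute successive differences, a complexity measure), root mean
square amplitude, and the four coefficients of an autoregressive model
fitted to the window (spectral-shape features) — for a 24-dimensional
feature vector over the four channels ED, PL, FCU, ECR.

AR coefficients follow the prediction-form sign convention

    t_n = q_1 t_{n-1} + ... + q_p t_{n-p} + w_n

so a positively lag-1-correlated signal has positive q_1.  Burg estimation
is the default (stable on short windows); Yule-Walker is available for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.regression.linear_model import burg as _sm_burg
from statsmodels.regression.linear_model import yule_walker as _sm_yule_walker

from .segmentation import Segment
from .synthetic import MUSCLES

AR_METHODS = ("burg", "yule_walker")


@dataclass(frozen=True)
class ARModelSpec:
    order: int = 4
    method: str = "burg"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("AR order must be >= 1")
        if self.method not in AR_METHODS:
            raise ValueError(f"method must be one of {AR_METHODS}")


def feature_names(channels: Sequence[str] = MUSCLES, ar_order: int = 4) -> List[str]:
    """Column order of the feature vector: per channel wl, rms, ar1..arp."""
    names = []
    for ch in channels:
        names.append(f"{ch}_wl")
        names.append(f"{ch}_rms")
        names.extend(f"{ch}_ar{i}" for i in range(1, ar_order + 1))
    return names


FEATURE_NAMES = feature_names()


def waveform_length(samples: Sequence[float]) -> float:
    """Sum of absolute successive sample differences over the window."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("waveform length needs a 1-d window of >= 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def rms(samples: Sequence[float]) -> float:
    """Root mean square amplitude of the window."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("rms needs a non-empty 1-d window")
    return float(np.sqrt(np.mean(x ** 2)))


def ar_coefficients(samples: Sequence[float],
                    spec: ARModelSpec = ARModelSpec()) -> np.ndarray:
    """Estimate AR coefficients q_1..q_p of the window (prediction form)."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) <= spec.order:
        raise ValueError(f"need more than {spec.order} samples for AR({spec.order})")
    if np.ptp(x) == 0:
        raise ValueError("AR estimation undefined for constant input")
    try:
        if spec.method == "burg":
            coeffs, _sigma2 = _sm_burg(x, order=spec.order, demean=True)
        else:
            coeffs, _sigma = _sm_yule_walker(x, order=spec.order, method="mle")
    except np.linalg.LinAlgError as exc:  # singular autocovariance
        raise ValueError(f"AR estimation failed: {exc}") from exc
    coeffs = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("AR estimation produced non-finite coefficients")
    return coeffs


@dataclass
class FeatureVector:
    """24 features (6 per channel x 4 channels) plus window identity."""

    values: np.ndarray
    label: Optional[int]
    subject_id: str
    window_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def extract_features(segment: Segment,
                     spec: ARModelSpec = ARModelSpec()) -> FeatureVector:
    """Apply the three extractors to each channel in fixed channel order."""
    rows = []
    for c, ch in enumerate(MUSCLES):
        x = segment.samples[c]
        try:
            rows.extend([waveform_length(x), rms(x)])
            rows.extend(ar_coefficients(x, spec))
        except ValueError as exc:
            raise ValueError(f"channel {ch}: {exc}") from exc
    return FeatureVector(values=np.array(rows), label=segment.label,
                         subject_id=segment.subject_id,
                         window_index=segment.window_index)


def features_dataframe(segments: Sequence[Segment],
                       spec: ARModelSpec = ARModelSpec()) -> pd.DataFrame:
    """Feature table for a list of labelled segments."""
    names = feature_names(ar_order=spec.order)
    records = []
    for seg in segments:
        fv = extract_features(seg, spec)
        rec = {"subject_id": fv.subject_id, "window_index": fv.window_index,
               "label": fv.label}
        rec.update(dict(zip(names, fv.values)))
        records.append(rec)
    return pd.DataFrame(records, columns=["subject_id", "window_index", "label",
                                          *names])


class EMGFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping windows (n_windows, n_channels, n_samples) to the
    per-channel waveform-length / RMS / AR coefficient feature matrix.

    Stateless; ``fit`` only records the input layout.  Composes with sklearn
    pipelines ahead of a classifier.
    """

    def __init__(self, ar_order: int = 4, ar_method: str = "burg"):
        self.ar_order = ar_order
        self.ar_method = ar_method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, n_samples)")
        ARModelSpec(self.ar_order, self.ar_method)  # validate params
        self.n_channels_ = X.shape[1]
        self.n_features_out_ = X.shape[1] * (2 + self.ar_order)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_channels_"):
            raise ValueError("EMGFeatureExtractor is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.n_channels_:
            raise ValueError(f"expected (n, {self.n_channels_}, window) input")
        spec = ARModelSpec(self.ar_order, self.ar_method)
        out = np.empty((X.shape[0], self.n_features_out_))
        for i in range(X.shape[0]):
            row = []
            for c in range(self.n_channels_):
                x = X[i, c]
                row.extend([waveform_length(x), rms(x)])
                row.extend(ar_coefficients(x, spec))
            out[i] = row
        return out

    def get_feature_names_out(self, input_features=None):
        chans = (MUSCLES if getattr(self, "n_channels_", 4) == len(MUSCLES)
                 else [f"ch{c}" for c in range(self.n_channels_)])
        return np.asarray(feature_names(chans, self.ar_order), dtype=object)
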