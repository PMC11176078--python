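"""Raphe calcium-trace analysis: ΔF/F, trial averaging, period-selective
classification and 2-component NMF population dynamics.

Traces are sampled at 1 Hz during an alternating spontaneous/OMR task.
ΔF/F is the raw trace divided by a rolling-percentile baseline (bottom 30th
percentile over a centered 2-min window); note the convention here is the
plain ratio F/F0 without subtracting 1 (a flag restores the conventional
form).  Neurons significantly more active in one task period (independent
t-test across trials, p < 0.05) are classified as spontaneous-active
(class 1) or OMR-active (class 2).  Pooled trial-averaged activity S (one
row per neuron) is factorized with rank-2 NMF; per-neuron weights W give
population state trajectories V[i, t] = sum_n W[n, i] S[n, t], each
component normalized by its vector norm |V| for comparison across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import NMF

__all__ = [
    "TrialStructure",
    "NMFStateModel",
    "StateTrajectory",
    "compute_dff",
    "trial_average",
    "classify_neurons",
    "fit_state_model",
    "compute_trajectory",
]


@dataclass
class TrialStructure:
    """Alternating task epochs at 1 Hz: spontaneous first, then OMR."""

    epoch_spont_s: float = 10.0
    epoch_omr_s: float = 10.0
    n_trials: int = 20

    @property
    def period(self) -> int:
        return int(round(self.epoch_spont_s + self.epoch_omr_s))

    @property
    def n_samples(self) -> int:
        return self.n_trials * self.period

    def spont_mask(self) -> np.ndarray:
        """Boolean mask over one trial period (True = spontaneous)."""
        return np.arange(self.period) < self.epoch_spont_s


def compute_dff(trace: np.ndarray, window_s: float = 120.0,
                percentile: float = 30.0, fs_hz: float = 1.0,
                subtract_one: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
    """ΔF/F with a rolling-percentile baseline.

    The baseline at t is the ``percentile``-th percentile of the raw values
    in the centered ``window_s`` window (truncated at the trace edges), and
    ΔF/F is the raw trace divided by it.  Works on 1-D traces or
    (neurons, time) matrices.  Raises on nonpositive baselines.

    Returns ``(dff, baseline)``.
    """
    raw = np.asarray(trace, dtype=float)
    one_d = raw.ndim == 1
    mat = raw[None, :] if one_d else raw
    win = int(round(window_s * fs_hz))
    if mat.shape[1] <= win:
        raise ValueError("trace must be longer than the baseline window")
    baseline = (pd.DataFrame(mat.T)
                .rolling(win, center=True, min_periods=1)
                .quantile(percentile / 100.0)
                .to_numpy().T)
    if (baseline <= 0).any():
        raise ValueError("nonpositive baseline")
    dff = mat / baseline
    if subtract_one:
        dff = dff - 1.0
    if one_d:
        return dff[0], baseline[0]
    return dff, baseline


def trial_average(dff: np.ndarray, trials: TrialStructure) -> np.ndarray:
    """Time-locked mean over complete trials (length = one trial period)."""
    dff = np.asarray(dff, dtype=float)
    one_d = dff.ndim == 1
    mat = dff[None, :] if one_d else dff
    period = trials.period
    n_complete = mat.shape[1] // period
    if n_complete < 2:
        raise ValueError("need at least 2 complete trials")
    trimmed = mat[:, :n_complete * period]
    avg = trimmed.reshape(mat.shape[0], n_complete, period).mean(axis=1)
    return avg[0] if one_d else avg


def classify_neurons(dff: np.ndarray, trials: TrialStructure,
                     alpha: float = 0.05, equal_var: bool = True
                     ) -> tuple[np.ndarray, dict]:
    """Classify neurons by task-period selectivity.

    For each neuron, per-trial mean ΔF/F is computed for the spontaneous and
    OMR periods and compared with a two-sided independent t-test across
    trials (equal-variance by default; ``equal_var=False`` for Welch).
    p < alpha assigns 'class1_spont' or 'class2_omr' by the larger period
    mean; otherwise (including zero-variance traces) 'ns'.

    Returns ``(labels, fractions)`` where fractions holds the per-class
    share of all neurons.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    period = trials.period
    n_complete = dff.shape[1] // period
    if n_complete < 2:
        raise ValueError("need at least 2 complete trials")
    cube = dff[:, :n_complete * period].reshape(dff.shape[0], n_complete,
                                                period)
    mask = trials.spont_mask()
    spont = cube[:, :, mask].mean(axis=2)    # (neurons, trials)
    omr = cube[:, :, ~mask].mean(axis=2)

    labels = np.full(dff.shape[0], "ns", dtype=object)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, p = stats.ttest_ind(spont, omr, axis=1, equal_var=equal_var)
    sig = np.isfinite(p) & (p < alpha)
    labels[sig & (spont.mean(axis=1) > omr.mean(axis=1))] = "class1_spont"
    labels[sig & (spont.mean(axis=1) <= omr.mean(axis=1))] = "class2_omr"
    n = dff.shape[0]
    fractions = {c: float((labels == c).sum()) / n
                 for c in ("class1_spont", "class2_omr", "ns")}
    return labels.astype(str), fractions


@dataclass
class NMFStateModel:
    """Rank-2 NMF of pooled trial-averaged activity S ≈ W @ H."""

    W: np.ndarray          # (neurons, 2), nonnegative weights
    H: np.ndarray          # (2, T), nonnegative temporal profiles
    reconstruction_err: float


def fit_state_model(S: np.ndarray, seed: int = 0,
                    trials: TrialStructure | None = None,
                    max_iter: int = 1000) -> NMFStateModel:
    """Rank-2 nonnegative factorization of the neuron-by-time matrix.

    Uses coordinate descent with deterministic nonnegative-double-SVD
    initialization, so results are reproducible under a fixed seed.  When
    ``trials`` is given, components are ordered so that component 1 carries
    the larger temporal variance during OMR epochs (the swim axis).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ValueError("S must be (neurons >= 2, time)")
    if (S < 0).any():
        raise ValueError("S must be nonnegative (clip ΔF/F-1 at zero first)")
    if not S.any():
        raise ValueError("S is all zero")
    nmf = NMF(n_components=2, init="nndsvda", solver="cd",
              random_state=seed, max_iter=max_iter)
    W = nmf.fit_transform(S)
    H = nmf.components_
    if trials is not None:
        t = np.arange(S.shape[1])
        spont = (t % trials.period) < trials.epoch_spont_s
        # component 1 = the OMR-preferring temporal profile (swim axis)
        contrast = H[:, ~spont].mean(axis=1) - H[:, spont].mean(axis=1)
        if contrast[1] > contrast[0]:
            W, H = W[:, ::-1], H[::-1]
    return NMFStateModel(W=W, H=H,
                         reconstruction_err=float(nmf.reconstruction_err_))


@dataclass
class StateTrajectory:
    """Component amplitudes V (2, T) and their unit-norm versions."""

    V: np.ndarray
    V_normalized: np.ndarray


def compute_trajectory(W: np.ndarray, S: np.ndarray) -> StateTrajectory:
    """Population state trajectory V[i, t] = sum_n W[n, i] S[n, t].

    ``W`` rows must align with ``S`` rows (a subset of the pooled neurons,
    e.g. one fish).  Each component's time series is divided by its
    Euclidean norm, making the normalized trajectory invariant to a common
    rescaling of S and to neuron ordering.
    """
    W = np.asarray(W, dtype=float)
    S = np.asarray(S, dtype=float)
    if W.shape[0] != S.shape[0]:
        raise ValueError("W and S describe different neuron sets")
    if W.shape[0] == 0:
        raise ValueError("no overlapping neurons")
    V = W.T @ S
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return StateTrajectory(V=V, V_normalized=V / norms)
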