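"""Latent behavioral-state embedding and drug-effect scoring.

Five per-bout kinematic features — tail-beat frequency, mean peak tail angle
raised to the 0.4 power (the power that best predicts swim distance), number
of tail half-cycles, L/R balance and preceding inter-bout interval — are
z-scored against a reference dataset and embedded with 2-component FastICA.
The two axes are canonically oriented so that IC1 increases with tail
frequency (rapid scooting) and IC2 with L/R balance (turning/escape), then
frozen and applied to new sessions without refitting.

Distributional shifts along single IC axes are tested with a kernel-density
two-sample permutation test (integrated squared difference of Gaussian KDEs
with per-sample Silverman bandwidths), and four normalized scores quantify a
treatment's stimulatory effect (shift toward OMR-like swimming) and
anxiolytic effect (reversal of the stress-induced shift); by construction a
full reversal scores -1 and no effect scores 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA

__all__ = [
    "FEATURE_NAMES",
    "ANGLE_POWER",
    "NormalizationModel",
    "ICAModel",
    "KdeTestResult",
    "DrugEffectSummary",
    "build_features",
    "fit_embedding",
    "project",
    "save_model",
    "load_model",
    "kde_two_sample_test",
    "score_distance_effects",
    "score_ic_effects",
]

FEATURE_NAMES = ("tail_freq_hz", "peak_angle_pow", "n_motions",
                 "lr_balance", "interval_s")
ANGLE_POWER = 0.4
_FREQ_COL, _BALANCE_COL = 0, 3


def build_features(bouts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Five-feature matrix from a bout-parameter table.

    Applies the angle^0.4 transform (degrees) and drops rows with a missing
    interval (first bout of a session/epoch) or any other missing parameter.

    Returns
    -------
    X : (n, 5) array ordered as :data:`FEATURE_NAMES`
    index : (n,) integer positions of the retained bouts in ``bouts``
    """
    ang = bouts["mean_peak_angle_deg"].to_numpy(dtype=float)
    if np.nanmin(ang) < 0:
        raise ValueError("negative mean peak angle")
    X = np.column_stack([
        bouts["tail_freq_hz"].to_numpy(dtype=float),
        ang ** ANGLE_POWER,
        bouts["n_motions"].to_numpy(dtype=float),
        bouts["lr_balance"].to_numpy(dtype=float),
        bouts["interval_s"].to_numpy(dtype=float),
    ])
    keep = np.all(np.isfinite(X), axis=1)
    return X[keep], np.flatnonzero(keep)


@dataclass
class NormalizationModel:
    """Per-feature mean/SD learned on the reference dataset."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


@dataclass
class ICAModel:
    """Frozen 2x5 unmixing applied to z-scored features.

    ``components`` includes the whitening, so sources are
    ``(Z - center) @ components.T``; rows are IC1/IC2 in canonical
    orientation (IC1 correlates positively with tail frequency, IC2 with
    L/R balance).  ``orientation`` records the permutation/sign applied.
    """

    components: np.ndarray
    center: np.ndarray
    orientation: dict = field(default_factory=dict)


def fit_embedding(X_ref: np.ndarray, seed: int = 0, max_iter: int = 2000
                  ) -> tuple[NormalizationModel, ICAModel]:
    """Fit normalization + 2-component ICA on the reference feature matrix."""
    X_ref = np.asarray(X_ref, dtype=float)
    if X_ref.shape[0] < 2 or X_ref.shape[1] != len(FEATURE_NAMES):
        raise ValueError("reference must be (n >= 2, 5)")
    mean = X_ref.mean(axis=0)
    sd = X_ref.std(axis=0)
    if (sd <= 0).any():
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"zero-variance feature(s): {bad}")
    norm = NormalizationModel(mean=mean, sd=sd)
    Z = norm.transform(X_ref)

    ica = FastICA(n_components=2, random_state=seed, max_iter=max_iter,
                  whiten="unit-variance")
    S = ica.fit_transform(Z)
    U = np.asarray(ica.components_)         # includes whitening
    center = np.asarray(ica.mean_)

    # canonical orientation from source/feature loading correlations
    corr = np.array([[np.corrcoef(S[:, k], Z[:, j])[0, 1]
                      for j in range(Z.shape[1])] for k in range(2)])
    k1 = int(np.argmax(np.abs(corr[:, _FREQ_COL])))
    k2 = 1 - k1
    order = [k1, k2]
    signs = np.array([np.sign(corr[k1, _FREQ_COL]) or 1.0,
                      np.sign(corr[k2, _BALANCE_COL]) or 1.0])
    U = U[order] * signs[:, None]
    model = ICAModel(components=U, center=center,
                     orientation={"order": order,
                                  "signs": signs.tolist()})
    return norm, model


def project(X: np.ndarray, norm: NormalizationModel, model: ICAModel
            ) -> np.ndarray:
    """Embed new bouts with frozen reference statistics (no refit)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.components.shape[1]:
        raise ValueError("feature dimension mismatch")
    Z = norm.transform(X)
    return (Z - model.center) @ model.components.T


def save_model(path, norm: NormalizationModel, model: ICAModel) -> None:
    payload = {
        "feature_names": list(FEATURE_NAMES),
        "angle_power": ANGLE_POWER,
        "normalization": {"mean": norm.mean.tolist(), "sd": norm.sd.tolist()},
        "ica": {"components": model.components.tolist(),
                "center": model.center.tolist(),
                "orientation": model.orientation},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> tuple[NormalizationModel, ICAModel]:
    with open(path) as fh:
        payload = json.load(fh)
    norm = NormalizationModel(
        mean=np.array(payload["normalization"]["mean"]),
        sd=np.array(payload["normalization"]["sd"]))
    model = ICAModel(components=np.array(payload["ica"]["components"]),
                     center=np.array(payload["ica"]["center"]),
                     orientation=payload["ica"]["orientation"])
    return norm, model


# ---------------------------------------------------------------------------
# kernel-density two-sample permutation test
# ---------------------------------------------------------------------------

@dataclass
class KdeTestResult:
    statistic: float
    p_value: float
    n_perm: int


def _silverman(x):
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def _ise(d2_aa, d2_bb, d2_ab, ha, hb):
    """Integrated squared KDE difference from pairwise squared distances.

    Uses the Gaussian convolution identity
    ``int N(x; xi, h1) N(x; xj, h2) dx = N(xi - xj; 0, h1^2 + h2^2)``,
    so the statistic is exact (no quadrature grid).
    """
    def term(d2, v):
        return np.mean(np.exp(-d2 / (2.0 * v))) / np.sqrt(2.0 * np.pi * v)

    return term(d2_aa, 2 * ha * ha) + term(d2_bb, 2 * hb * hb) \
        - 2.0 * term(d2_ab, ha * ha + hb * hb)


def kde_two_sample_test(sample_a, sample_b, n_perm: int = 1000,
                        seed: int = 0) -> KdeTestResult:
    """Permutation test on the integrated squared KDE difference.

    The statistic is the exact integral of (f_A - f_B)^2 where f_A, f_B are
    Gaussian KDEs with per-sample Silverman plug-in bandwidths; the p-value
    is the add-one-corrected fraction of label permutations whose statistic
    meets or exceeds the observed one.  The p-value is invariant under a
    common affine transform of both samples and under swapping A and B.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 20 or b.size < 20:
        raise ValueError("both samples must have at least 20 values")
    pool = np.concatenate([a, b])
    if np.ptp(pool) == 0:
        raise ValueError("pooled sample has zero variance")

    d2 = (pool[:, None] - pool[None, :]) ** 2
    na = a.size

    def stat(idx):
        ia, ib = idx[:na], idx[na:]
        xa, xb = pool[ia], pool[ib]
        ha, hb = _silverman(xa), _silverman(xb)
        floor = 1e-3 * pool.std()
        ha, hb = max(ha, floor), max(hb, floor)
        return _ise(d2[np.ix_(ia, ia)], d2[np.ix_(ib, ib)],
                    d2[np.ix_(ia, ib)], ha, hb)

    identity = np.arange(pool.size)
    observed = stat(identity)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if stat(rng.permutation(pool.size)) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return KdeTestResult(statistic=float(observed), p_value=float(p),
                         n_perm=n_perm)


# ---------------------------------------------------------------------------
# drug-effect scores
# ---------------------------------------------------------------------------

@dataclass
class ScoreSet:
    per_fish: np.ndarray
    mean: float
    sem: float


def _score_set(values: np.ndarray) -> ScoreSet:
    values = np.asarray(values, dtype=float)
    sem = values.std(ddof=1) / np.sqrt(values.size) if values.size > 1 \
        else np.nan
    return ScoreSet(per_fish=values, mean=float(values.mean()),
                    sem=float(sem))


@dataclass
class DrugEffectSummary:
    """The four printed stimulatory/anxiolytic scores (dimensionless).

    The anxiolytic scores keep the printed sign convention: a drug that
    fully reverses the stress-induced change scores -1.
    ``anxiolytic_magnitude_*`` (= -score) is provided for plotting only.
    """

    stimulatory_distance: ScoreSet | None = None
    anxiolytic_distance: ScoreSet | None = None
    stimulatory_ic1: ScoreSet | None = None
    anxiolytic_ic2: ScoreSet | None = None

    @property
    def anxiolytic_magnitude_distance(self):
        s = self.anxiolytic_distance
        return None if s is None else -s.mean

    @property
    def anxiolytic_magnitude_ic2(self):
        s = self.anxiolytic_ic2
        return None if s is None else -s.mean


def _check_groups(*groups):
    for g in groups:
        if np.asarray(g).size < 2:
            raise ValueError("each group needs at least 2 fish")


def score_distance_effects(control, drug, stress, drug_stress
                           ) -> DrugEffectSummary:
    """Distance-based stimulatory and anxiolytic scores.

    Inputs are per-fish spontaneous swim distances.  Per drug fish i:
    ``stimulatory_i = (drug_i - mean(control)) / mean(control)``; per
    drug+stress fish j: ``anxiolytic_j = (drug_stress_j - mean(stress)) /
    (mean(stress) - mean(control))``.  Both are scale-free: multiplying every
    fish's distance by a positive constant leaves them unchanged.
    """
    control, drug = np.asarray(control, float), np.asarray(drug, float)
    stress = np.asarray(stress, float)
    drug_stress = np.asarray(drug_stress, float)
    _check_groups(control, drug, stress, drug_stress)
    mc, ms = control.mean(), stress.mean()
    if mc == 0:
        raise ValueError("control mean distance is zero")
    if ms == mc:
        raise ValueError("stress and control means coincide; "
                         "anxiolytic denominator is zero")
    return DrugEffectSummary(
        stimulatory_distance=_score_set((drug - mc) / mc),
        anxiolytic_distance=_score_set((drug_stress - ms) / (ms - mc)),
    )


def score_ic_effects(control_spont_ic1, control_omr_ic1, drug_spont_ic1,
                     control_spont_ic2, stress_spont_ic2,
                     drug_stress_spont_ic2) -> DrugEffectSummary:
    """IC-axis stimulatory and anxiolytic scores.

    Inputs are per-fish mean IC coordinates.  The stimulatory score measures
    the drug's shift of spontaneous IC1 relative to the control group's
    spont->OMR IC1 contrast (1 = spontaneous swimming moved all the way to
    the control OMR level); the anxiolytic score measures the drug's
    position on the stress-induced IC2 shift (0 = no reversal, -1 = fully
    back to the control level).
    """
    c1s = np.asarray(control_spont_ic1, float)
    c1o = np.asarray(control_omr_ic1, float)
    d1 = np.asarray(drug_spont_ic1, float)
    c2 = np.asarray(control_spont_ic2, float)
    s2 = np.asarray(stress_spont_ic2, float)
    ds2 = np.asarray(drug_stress_spont_ic2, float)
    _check_groups(c1s, c1o, d1, c2, s2, ds2)
    denom1 = c1o.mean() - c1s.mean()
    if denom1 == 0:
        raise ValueError("control OMR-vs-spont IC1 contrast is zero")
    denom2 = s2.mean() - c2.mean()
    if denom2 == 0:
        raise ValueError("stress-vs-control IC2 shift is zero")
    return DrugEffectSummary(
        stimulatory_ic1=_score_set((d1 - c1s.mean()) / denom1),
        anxiolytic_ic2=_score_set((ds2 - s2.mean()) / denom2),
    )
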