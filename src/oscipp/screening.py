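"""Systolic-hypertension screening: MLP training, ROC analysis,
measurement-noise robustness, and paired-measurement agreement statistics.

The classifier is a single-hidden-layer (10 ReLU units) perceptron with a
softmax output, trained with L-BFGS on the cross-entropy loss after
per-feature standardization.  Three feature sets are supported: pulse
pressure alone; demographics plus smoking; and everything (PP, HR,
demographics, smoking).  Because the problem is binary, training uses a
single logistic output and the equivalent two-logit softmax weights are
stored, so the serialized model has the stated 10x2 output layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .errors import ScreeningError
from .signal_sim.population import AGE_CUTOFF_YEARS

__all__ = [
    "FEATURE_SETS",
    "MLPModel",
    "ROCResult",
    "AgreementStats",
    "filter_population",
    "split_data",
    "train_mlp",
    "evaluate_roc",
    "noise_experiment",
    "agreement_stats",
]

FEATURE_SETS = {
    "pp_only": ["pp"],
    "demographics": ["age", "sex", "race", "bmi", "smoking"],
    "all_features": ["pp", "hr", "age", "sex", "race", "bmi", "smoking"],
}

_CATEGORICAL = ("sex", "race", "smoking")
_REQUIRED = ["age", "sex", "race", "bmi", "smoking", "sbp", "dbp", "hr"]


# ---------------------------------------------------------------------------
# table preparation


def filter_population(raw: pd.DataFrame) -> pd.DataFrame:
    """Apply the study's inclusion rules to a raw feature table.

    Replicate BP columns (``sbp_1, sbp_2, ...`` / ``dbp_*``) are averaged
    over the available (non-missing) replicates first; then any row with a
    missing field, age >= 65, or non-positive pulse pressure is dropped.
    Adds derived ``pp`` and the ``systolic_htn`` / ``general_htn`` labels.
    """
    df = raw.copy()
    for base in ("sbp", "dbp"):
        reps = [c for c in df.columns
                if c.startswith(base + "_") and c[len(base) + 1:].isdigit()]
        if reps and base not in df.columns:
            df[base] = df[reps].mean(axis=1, skipna=True)
            df = df.drop(columns=reps)
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise ScreeningError(f"table missing required columns: {missing_cols}")
    df = df.dropna(subset=_REQUIRED)
    df = df[df["age"] < AGE_CUTOFF_YEARS]
    df = df[(df["sbp"] - df["dbp"]) > 0]
    if len(df) == 0:
        raise ScreeningError("no rows survive filtering")
    df = df.copy()
    df["pp"] = df["sbp"] - df["dbp"]
    df["systolic_htn"] = (df["sbp"] >= 130.0).astype(int)
    df["general_htn"] = ((df["sbp"] >= 130.0) | (df["dbp"] >= 80.0)).astype(int)
    return df


def split_data(table: pd.DataFrame, train_frac: float = 0.7, seed: int = 0):
    """Seeded random disjoint train/test partition."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    n_train = int(round(train_frac * len(table)))
    return table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]


def _encode(table: pd.DataFrame, feature_set: str,
            columns: Optional[Sequence[str]] = None):
    feats = FEATURE_SETS[feature_set]
    cats = [f for f in feats if f in _CATEGORICAL]
    x = pd.get_dummies(table[feats], columns=cats, dtype=float)
    if columns is not None:
        x = x.reindex(columns=columns, fill_value=0.0)
    return x


# ---------------------------------------------------------------------------
# model


@dataclass
class MLPModel:
    """Trained screening network with its input standardization.

    Weights are stored explicitly (hidden ``n_features x 10`` + biases,
    output ``10 x 2`` + biases feeding a softmax) so prediction is a plain
    forward pass and the model serializes to JSON.
    """

    feature_set: str
    columns: list
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    w_hidden: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    label_col: str = "systolic_htn"
    train_loss: float = float("nan")
    meta: dict = field(default_factory=dict)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Softmax class probabilities, column 1 = hypertension."""
        x = _encode(table, self.feature_set, self.columns).to_numpy(dtype=float)
        xs = (x - self.scale_mean) / self.scale_sd
        h = np.maximum(xs @ self.w_hidden + self.b_hidden, 0.0)
        logits = h @ self.w_out + self.b_out
        return softmax(logits, axis=1)

    def to_json_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "columns": list(self.columns),
            "label_col": self.label_col,
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "train_loss": self.train_loss,
            "meta": self.meta,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MLPModel":
        return cls(
            feature_set=d["feature_set"],
            columns=list(d["columns"]),
            label_col=d.get("label_col", "systolic_htn"),
            scale_mean=np.asarray(d["scale_mean"], dtype=float),
            scale_sd=np.asarray(d["scale_sd"], dtype=float),
            w_hidden=np.asarray(d["w_hidden"], dtype=float),
            b_hidden=np.asarray(d["b_hidden"], dtype=float),
            w_out=np.asarray(d["w_out"], dtype=float),
            b_out=np.asarray(d["b_out"], dtype=float),
            train_loss=d.get("train_loss", float("nan")),
            meta=d.get("meta", {}),
        )


def train_mlp(
    train: pd.DataFrame,
    feature_set: str = "all_features",
    seed: int = 0,
    *,
    label_col: str = "systolic_htn",
    hidden_units: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MLPModel:
    """Train the screening perceptron with L-BFGS on cross-entropy.

    Features are standardized; categoricals are one-hot encoded.  The
    optimizer stops on its step-size tolerance ``tol``.
    """
    if feature_set not in FEATURE_SETS:
        raise ScreeningError(
            f"unknown feature set {feature_set!r}; choose from {sorted(FEATURE_SETS)}"
        )
    y = train[label_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ScreeningError("training data contain a single class")
    x_df = _encode(train, feature_set)
    scaler = StandardScaler().fit(x_df.to_numpy(dtype=float))
    sd = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
    xs = (x_df.to_numpy(dtype=float) - scaler.mean_) / sd

    net = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="relu",
        solver="lbfgs",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    net.fit(xs, y)

    w1, w2 = net.coefs_
    b1, b2 = net.intercepts_
    # binary sklearn net has one logistic output; express it as the
    # equivalent two-logit softmax layer (logit 0 pinned at zero)
    w_out = np.column_stack([np.zeros_like(w2[:, 0]), w2[:, 0]])
    b_out = np.array([0.0, b2[0]])
    return MLPModel(
        feature_set=feature_set,
        columns=list(x_df.columns),
        scale_mean=np.asarray(scaler.mean_, dtype=float),
        scale_sd=np.asarray(sd, dtype=float),
        w_hidden=np.asarray(w1, dtype=float),
        b_hidden=np.asarray(b1, dtype=float),
        w_out=w_out,
        b_out=b_out,
        label_col=label_col,
        train_loss=float(net.loss_),
        meta={"seed": seed, "n_train": int(len(train)),
              "n_iter": int(net.n_iter_)},
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def evaluate_roc(model: MLPModel, test: pd.DataFrame) -> ROCResult:
    """ROC curve and trapezoid AUC from the hypertension-class probability."""
    y = test[model.label_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ScreeningError("test data contain a single class")
    scores = model.predict_proba(test)[:, 1]
    fpr, tpr, thr = _roc_curve(y, scores)
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr,
                     auc=float(_trapezoid_auc(fpr, tpr)))


def noise_experiment(
    model: MLPModel,
    test: pd.DataFrame,
    noise_mean: float = -1.0,
    noise_sd: float = 7.2,
    n_realizations: int = 100,
    seed: int = 0,
):
    """Robustness of the trained model to PP measurement error.

    Gaussian noise with the given bias and SD (defaults: the app's
    field-measured bias/precision of -1.0 / 7.2 mmHg) is added to the
    test-set PP over ``n_realizations`` independent realizations; the
    already-trained model is re-evaluated each time.  Returns
    ``(mean_auc, sd_auc)``.
    """
    if "pp" not in FEATURE_SETS[model.feature_set]:
        raise ScreeningError("model does not use PP as a feature")
    if n_realizations < 2:
        raise ScreeningError("need at least 2 realizations for an SD")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_realizations)
    for i in range(n_realizations):
        noisy = test.copy()
        noisy["pp"] = noisy["pp"] + rng.normal(noise_mean, noise_sd, size=len(test))
        aucs[i] = evaluate_roc(model, noisy).auc
    if np.all(aucs == aucs[0]):  # e.g. zero noise: reproduce clean AUC exactly
        return float(aucs[0]), 0.0
    return float(aucs.mean()), float(aucs.std(ddof=1))


# ---------------------------------------------------------------------------
# agreement statistics


@dataclass
class AgreementStats:
    """Bland-Altman style agreement between estimates and references.

    ``mu`` is the bias (mean error), ``sigma`` the precision (sample SD of
    errors), ``r`` the Pearson correlation (NaN + flag when either vector
    has zero variance), and ``loa`` the 95% limits of agreement
    ``mu ± 1.96 sigma``.
    """

    r: float
    mu: float
    sigma: float
    loa: tuple
    r_defined: bool = True


def agreement_stats(estimates, references) -> AgreementStats:
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and references must be equal-length 1-D")
    if est.size < 2:
        raise ValueError("need at least 2 paired measurements")
    err = est - ref
    mu = float(err.mean())
    sigma = float(err.std(ddof=1))
    if est.std() == 0 or ref.std() == 0:
        r, defined = float("nan"), False
    else:
        r = float(np.corrcoef(est, ref)[0, 1])
        defined = True
    return AgreementStats(
        r=r, mu=mu, sigma=sigma,
        loa=(mu - 1.96 * sigma, mu + 1.96 * sigma),
        r_defined=defined,
    )
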