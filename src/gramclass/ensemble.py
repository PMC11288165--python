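"""Six-member heterogeneous ensemble with mode voting.

Members: Gaussian naive Bayes, elastic-net logistic regression, random
forest, RBF support-vector machine, a numpy 1-D CNN and a multilayer
perceptron. Several member hyperparameters are derived from the training
matrix rather than fixed: tree count and hidden width scale with
classes x features-per-class, SVM regularization with total feature
variance, naive-Bayes priors with per-class variance mass. The final label
is the mode of the member votes, with probability-sum tie-breaking.

Features are standardized (train statistics) for the scale-sensitive
members (LR, SVM, MLP, CNN); naive Bayes and the forest see raw values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._cnn import CNNConfig, Conv1DClassifier, variance_gate  # noqa: F401
from .ngram_features import FeatureMatrix
from .selection import GAConfig

MEMBER_NAMES = ("naive_bayes", "logistic", "random_forest", "svm", "cnn", "mlp")
SCALED_MEMBERS = frozenset({"logistic", "svm", "mlp", "cnn"})

RF_TREE_CAP = 200
MLP_HIDDEN_CAP = 256
SVM_C_FLOOR = 1e-3
TOLERANCE = 1e-4  # "0.01%" error tolerance


@dataclass
class MemberParams:
    """Hyperparameters derived from the training matrix."""

    n_classes: int
    n_features: int
    features_per_class: int
    largest_feature_variance: float
    total_feature_variance: float
    rf_trees: int
    rf_depth: int
    rf_max_features: int
    mlp_hidden: int
    mlp_max_iter: int
    svm_c: float
    nb_priors: list[float]
    nb_priors_fallback: bool
    learning_rate: float
    tolerance: float = TOLERANCE
    caps_applied: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def derive_member_params(
    fm_train: FeatureMatrix,
    ga: GAConfig,
    rf_tree_cap: int = RF_TREE_CAP,
    mlp_hidden_cap: int = MLP_HIDDEN_CAP,
) -> MemberParams:
    """Derive per-member hyperparameters from the (feature-reduced) train set.

    features_per_class F_c = ceil(N_f / N_c); rf_trees = min(N_c*F_c, cap);
    forest depth = N_c; hidden width = min(N_c*F_c, cap); SVM C = total
    feature variance (floored); naive-Bayes priors are proportional to each
    class's mean within-class variance, falling back to empirical class
    frequencies when any class variance is zero.
    """
    if fm_train.n_records == 0:
        raise ValueError("empty training matrix")
    n_classes = fm_train.n_classes
    present = np.unique(fm_train.y)
    if present.size < 2:
        raise ValueError("need at least 2 classes to derive member parameters")
    X, y = fm_train.X, fm_train.y
    n_features = fm_train.n_features
    variances = X.var(axis=0)
    lvf = float(variances.max())
    total_var = float(variances.sum())

    f_c = max(1, int(np.ceil(n_features / n_classes)))
    caps: list[str] = []
    rf_trees = n_classes * f_c
    if rf_trees > rf_tree_cap:
        rf_trees = rf_tree_cap
        caps.append(f"rf_trees capped at {rf_tree_cap}")
    mlp_hidden = n_classes * f_c
    if mlp_hidden > mlp_hidden_cap:
        mlp_hidden = mlp_hidden_cap
        caps.append(f"mlp_hidden capped at {mlp_hidden_cap}")
    svm_c = total_var
    if svm_c < SVM_C_FLOOR:
        svm_c = SVM_C_FLOOR
        caps.append(f"svm_c floored at {SVM_C_FLOOR}")

    class_var = np.array(
        [X[y == c].var(axis=0).mean() if np.any(y == c) else 0.0 for c in range(n_classes)]
    )
    if np.any(class_var <= 0):
        counts = np.bincount(y, minlength=n_classes).astype(float)
        priors = counts / counts.sum()
        fallback = True
    else:
        priors = class_var / class_var.sum()
        fallback = False

    return MemberParams(
        n_classes=n_classes,
        n_features=n_features,
        features_per_class=f_c,
        largest_feature_variance=lvf,
        total_feature_variance=total_var,
        rf_trees=max(1, rf_trees),
        rf_depth=max(1, n_classes),
        rf_max_features=max(1, int(np.floor(np.log2(max(n_features, 2))))),
        mlp_hidden=max(1, mlp_hidden),
        mlp_max_iter=max(1, ga.n_iterations * ga.n_solutions),
        svm_c=svm_c,
        nb_priors=[float(p) for p in priors],
        nb_priors_fallback=fallback,
        learning_rate=ga.learning_rate,
        caps_applied=caps,
    )


def tune_hyperparameter(
    hp_value: float,
    acc_old: float,
    acc_new: float,
    learning_rate: float,
    bounds: tuple[float, float] | None = None,
) -> float:
    """Accuracy-driven multiplicative update hp' = hp * (1 + L_r * dAcc),
    clamped to the hyperparameter's legal range."""
    if not (0 <= acc_old <= 1 and 0 <= acc_new <= 1):
        raise ValueError("accuracies must be in [0, 1]")
    if not 0 < learning_rate <= 1:
        raise ValueError("learning_rate must be in (0, 1]")
    out = hp_value * (1.0 + learning_rate * (acc_new - acc_old))
    if bounds is not None:
        out = min(max(out, bounds[0]), bounds[1])
    return out


def fit_cnn(
    X_train: np.ndarray, y_train: np.ndarray, config: CNNConfig
) -> Conv1DClassifier:
    """Train the 1-D CNN member on (already scaled) features."""
    return Conv1DClassifier(config).fit(X_train, y_train)


def mode_vote(
    member_labels: np.ndarray, member_probs: np.ndarray
) -> np.ndarray:
    """Final label per record: the modal class among member votes.

    Ties are broken by the largest summed probability over members among the
    tied classes; remaining ties go to the lowest class index.
    """
    labels = np.asarray(member_labels)
    probs = np.asarray(member_probs, dtype=float)
    if labels.ndim != 2:
        raise ValueError("member_labels must be (n_members, n_records)")
    if probs.shape[:2] != labels.shape:
        raise ValueError("member_probs shape does not match member_labels")
    n_members, n_records = labels.shape
    n_classes = probs.shape[2]
    out = np.empty(n_records, dtype=int)
    for i in range(n_records):
        counts = np.bincount(labels[:, i], minlength=n_classes)
        top = counts.max()
        tied = np.nonzero(counts == top)[0]
        if tied.size == 1:
            out[i] = tied[0]
        else:
            sums = probs[:, i, tied].sum(axis=0)
            out[i] = tied[int(np.argmax(sums))]  # argmax keeps lowest index on ties
    return out


class EnsembleModel:
    """Six fitted members plus the mode-vote combiner."""

    def __init__(
        self,
        class_names: list[str],
        params: MemberParams,
        cnn_config: CNNConfig,
        seed: int = 0,
    ):
        self.class_names = list(class_names)
        self.params = params
        self.cnn_config = cnn_config
        self.seed = seed
        self.members: dict[str, object] = {}
        self.scaler: StandardScaler | None = None
        self.fitted = False

    # -- construction -------------------------------------------------------------
    def _build_members(self) -> dict[str, object]:
        p = self.params
        return {
            "naive_bayes": GaussianNB(
                priors=np.asarray(p.nb_priors),
                var_smoothing=1e-9 * max(p.largest_feature_variance, 1.0),
            ),
            "logistic": LogisticRegression(
                l1_ratio=0.5,  # elastic-net mixing
                solver="saga",
                tol=p.tolerance,
                class_weight="balanced",
                max_iter=2000,
                random_state=self.seed,
            ),
            "random_forest": RandomForestClassifier(
                n_estimators=p.rf_trees,
                criterion="entropy",
                max_depth=p.rf_depth,
                max_features=p.rf_max_features,
                random_state=self.seed + 1,
            ),
            "svm": SVC(
                C=p.svm_c,
                kernel="rbf",
                probability=True,
                class_weight="balanced",
                tol=p.tolerance,
                random_state=self.seed + 2,
            ),
            "cnn": Conv1DClassifier(self.cnn_config),
            "mlp": MLPClassifier(
                hidden_layer_sizes=(p.mlp_hidden,),
                activation="relu",
                solver="adam",
                learning_rate_init=p.learning_rate,
                max_iter=p.mlp_max_iter,
                tol=p.tolerance,
                random_state=self.seed + 3,
            ),
        }

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EnsembleModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes to fit the ensemble")
        self.scaler = StandardScaler().fit(X)
        Xs = self.scaler.transform(X)
        members = self._build_members()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            for name, member in members.items():
                xin = Xs if name in SCALED_MEMBERS else X
                try:
                    member.fit(xin, y)
                except Exception as exc:
                    raise RuntimeError(f"member {name!r} failed to fit") from exc
        self.members = members
        self.fitted = True
        return self

    # -- prediction ---------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("ensemble is not fitted")

    def _member_input(self, name: str, X: np.ndarray) -> np.ndarray:
        return self.scaler.transform(X) if name in SCALED_MEMBERS else X

    def predict_members(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-member label votes (n_members, n) and probability rows
        (n_members, n, n_classes), in a fixed class order."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        n_classes = len(self.class_names)
        all_labels = np.empty((len(MEMBER_NAMES), X.shape[0]), dtype=int)
        all_probs = np.zeros((len(MEMBER_NAMES), X.shape[0], n_classes))
        for m, name in enumerate(MEMBER_NAMES):
            member = self.members[name]
            xin = self._member_input(name, X)
            probs = member.predict_proba(xin)
            # align member class order (sklearn uses sorted classes_ seen in fit)
            classes = np.asarray(member.classes_, dtype=int)
            aligned = np.zeros((X.shape[0], n_classes))
            aligned[:, classes] = probs
            all_probs[m] = aligned
            all_labels[m] = aligned.argmax(axis=1)
        return all_labels, all_probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        labels, probs = self.predict_members(X)
        return mode_vote(labels, probs)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Ensemble-averaged member probabilities."""
        _, probs = self.predict_members(X)
        return probs.mean(axis=0)


def fit_ensemble(
    fm_train: FeatureMatrix,
    ga: GAConfig,
    cnn_config: CNNConfig | None = None,
    seed: int = 0,
    rf_tree_cap: int = RF_TREE_CAP,
    mlp_hidden_cap: int = MLP_HIDDEN_CAP,
) -> EnsembleModel:
    """Derive member hyperparameters from the train matrix and fit all six
    members on identical rows."""
    params = derive_member_params(fm_train, ga, rf_tree_cap, mlp_hidden_cap)
    cnn_config = cnn_config or CNNConfig(seed=seed)
    model = EnsembleModel(
        class_names=fm_train.class_names,
        params=params,
        cnn_config=cnn_config,
        seed=seed,
    )
    return model.fit(fm_train.X, fm_train.y)


class EnsembleEvaluator:
    """Thin sklearn-style adapter so the partition GA can (expensively) use
    the full ensemble as its in-loop evaluator."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._model: EnsembleModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EnsembleEvaluator":
        fm = FeatureMatrix(
            X=X,
            y=y,
            feature_names=[f"f{i}" for i in range(X.shape[1])],
            class_names=[str(c) for c in range(int(np.max(y)) + 1)],
        )
        cnn = CNNConfig(epochs=5, seed=self.seed)
        self._model = fit_ensemble(fm, GAConfig(seed=self.seed), cnn, seed=self.seed)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict(X)
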