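"""The genomic-selection cross-validation protocol and learner suite.

Protocol: 10% of samples are drawn once per master seed as an untouched
test holdout. The remaining 90% are re-split 4:1 (train:validate) in every
iteration with an iteration-derived seed; each (learner, marker count)
combination is fitted on the train part and scored on the validation fifth
— accuracy for the binary trait, Pearson r for the continuous trait — and
the report averages over iterations. Only after model comparison is the
winning combination refitted on the full 90% and scored once on the
holdout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet, Lasso, LogisticRegression, Ridge
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

class _RidgeBlup(Ridge):
    """Ridge whose penalty scales with the marker count.

    With column-standardised dosages and marker effects sharing the variance
    equally, the BLUP-equivalent ridge penalty is proportional to the number
    of markers; a fixed alpha would under-shrink badly once markers outnumber
    samples.
    """

    def fit(self, X, y, **kw):
        self.alpha = float(max(1, X.shape[1]))
        return super().fit(X, y, **kw)


_CLASSIFIERS = {"logistic", "svc", "rfc", "naive_bayes"}
_REGRESSORS = {"lasso", "ridge", "elasticnet", "svr", "rfr", "gblup"}
_KERNEL_MODELS = {"svc", "svr"}
_TREE_MODELS = {"rfc", "rfr"}


@dataclass
class LearnerSpec:
    """One learner in the comparison suite.

    ``kernel`` applies only to the support-vector models; ``strength`` is
    the main regularisation knob (C for logistic/SVM, alpha for penalised
    linear models) and defaults to the library's standard value.
    """

    name: str
    kernel: str | None = None
    strength: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in _CLASSIFIERS | _REGRESSORS:
            raise ValueError(f"unknown learner {self.name!r}")
        if self.kernel is not None and self.name not in _KERNEL_MODELS:
            raise ValueError("kernel applies only to svc/svr")
        if self.kernel is not None and self.kernel not in ("linear", "poly", "rbf"):
            raise ValueError("kernel must be linear, poly, or rbf")

    @property
    def is_classifier(self) -> bool:
        return self.name in _CLASSIFIERS

    @property
    def label(self) -> str:
        return f"{self.name}[{self.kernel}]" if self.kernel else self.name


def make_learner(spec: LearnerSpec):
    """Instantiate the sklearn estimator; dosages are column-standardised for
    everything except the tree models, which take raw dosages."""
    s = spec.strength
    if spec.name == "logistic":
        est = LogisticRegression(C=s or 1.0, max_iter=2000)
    elif spec.name == "svc":
        est = SVC(kernel=spec.kernel or "rbf", C=s or 1.0, random_state=spec.seed)
    elif spec.name == "rfc":
        est = RandomForestClassifier(n_estimators=100, random_state=spec.seed, n_jobs=1)
    elif spec.name == "naive_bayes":
        est = GaussianNB()
    elif spec.name == "lasso":
        est = Lasso(alpha=s or 0.01, max_iter=5000)
    elif spec.name == "ridge":
        est = Ridge(alpha=s) if s is not None else _RidgeBlup()
    elif spec.name == "elasticnet":
        est = ElasticNet(alpha=s or 0.01, l1_ratio=0.5, max_iter=5000)
    elif spec.name == "svr":
        est = SVR(kernel=spec.kernel or "rbf", C=s or 1.0)
    elif spec.name == "rfr":
        est = RandomForestRegressor(n_estimators=100, random_state=spec.seed, n_jobs=1)
    elif spec.name == "gblup":
        # closed-form ridge on the marker kernel: the GBLUP baseline
        est = KernelRidge(alpha=s or 1.0, kernel="linear")
    else:  # pragma: no cover
        raise AssertionError
    if spec.name in _TREE_MODELS:
        return est
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def default_learners(trait_type: str, seed: int = 0) -> list[LearnerSpec]:
    """The compared suites: four classifiers, five regressors (kernels are
    chosen separately for the support-vector models)."""
    if trait_type == "binary":
        names = ["logistic", "svc", "rfc", "naive_bayes"]
    else:
        names = ["lasso", "ridge", "elasticnet", "svr", "rfr"]
    return [LearnerSpec(name=n, seed=seed) for n in names]


@dataclass
class GsReport:
    """Cross-validation summary over (learner, marker count) combinations."""

    trait_type: str
    summary: pd.DataFrame  # learner, n_markers, mean_metric, sd_metric
    per_iteration: pd.DataFrame  # learner, n_markers, iteration, metric
    best_learner: str
    best_count: int
    n_iter: int
    seed: int
    holdout_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    final_test_metric: float | None = None

    @property
    def best_mean_metric(self) -> float:
        m = self.summary
        row = m[(m["learner"] == self.best_learner) & (m["n_markers"] == self.best_count)]
        return float(row["mean_metric"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "trait_type": self.trait_type,
            "best_learner": self.best_learner,
            "best_count": int(self.best_count),
            "best_mean_metric": round(self.best_mean_metric, 8),
            "n_iter": int(self.n_iter),
            "seed": int(self.seed),
            "final_test_metric": (
                None if self.final_test_metric is None else round(self.final_test_metric, 8)
            ),
            "summary": [
                {
                    "learner": r.learner,
                    "n_markers": int(r.n_markers),
                    "mean_metric": round(float(r.mean_metric), 8),
                    "sd_metric": round(float(r.sd_metric), 8),
                }
                for r in self.summary.itertuples()
            ],
        }


def _metric(trait_type: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if trait_type == "binary":
        return float(np.mean(y_true == y_pred))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return 0.0  # degenerate predictor carries no signal
    return float(stats.pearsonr(y_true, y_pred).statistic)


def _predict(model, X: np.ndarray, is_classifier: bool) -> np.ndarray:
    if is_classifier and hasattr(model, "predict_proba"):
        return (model.predict_proba(X)[:, -1] >= 0.5).astype(int)
    return model.predict(X)


def split_holdout(n: int, holdout: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Drawn once per master seed; the holdout is untouched by CV."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    n_hold = max(1, int(round(holdout * n)))
    perm = rng.permutation(n)
    return np.sort(perm[n_hold:]), np.sort(perm[:n_hold])


def gs_crossvalidate(
    markers: np.ndarray,
    y: np.ndarray,
    learners: list[LearnerSpec],
    counts: list[int],
    trait_type: str,
    n_iter: int = 100,
    holdout: float = 0.10,
    seed: int = 0,
) -> GsReport:
    """Compare (learner, marker-count) combinations under the CV protocol.

    ``markers`` columns must already be ranked (best first), so the top-k
    subset for count k is the first k columns. The best combination is the
    argmax of the mean validation metric; ties go to the smaller count,
    then the learner listed first.
    """
    markers = np.asarray(markers, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 samples")
    if markers.shape[0] != n:
        raise ValueError("marker matrix and phenotype disagree on n")
    if not counts or max(counts) > markers.shape[1]:
        raise ValueError("counts must be non-empty and within the marker matrix")
    for spec in learners:
        if spec.is_classifier != (trait_type == "binary"):
            raise ValueError(f"learner {spec.label} does not fit trait {trait_type}")

    model_idx, hold_idx = split_holdout(n, holdout, seed)
    Xm, ym = markers[model_idx], y[model_idx]

    records = []
    for it in range(n_iter):
        rng_it = np.random.default_rng(np.random.SeedSequence([int(seed), 29, it]))
        perm = rng_it.permutation(len(ym))
        n_val = max(1, len(ym) // 5)  # the 4:1 validation fifth
        val, tr = perm[:n_val], perm[n_val:]
        if len(tr) == 0:
            raise ValueError("training fold empty")
        for spec in learners:
            for k in counts:
                model = make_learner(spec)
                model.fit(Xm[np.ix_(tr, np.arange(k))], ym[tr])
                pred = _predict(model, Xm[np.ix_(val, np.arange(k))], spec.is_classifier)
                records.append(
                    {
                        "learner": spec.label,
                        "n_markers": k,
                        "iteration": it,
                        "metric": _metric(trait_type, ym[val], pred),
                    }
                )
    per_it = pd.DataFrame(records)
    summary = (
        per_it.groupby(["learner", "n_markers"], sort=False)["metric"]
        .agg(mean_metric="mean", sd_metric="std")
        .reset_index()
    )
    best_row = summary.sort_values(
        ["mean_metric", "n_markers"], ascending=[False, True], kind="mergesort"
    ).iloc[0]
    return GsReport(
        trait_type=trait_type,
        summary=summary,
        per_iteration=per_it,
        best_learner=str(best_row["learner"]),
        best_count=int(best_row["n_markers"]),
        n_iter=n_iter,
        seed=int(seed),
        holdout_idx=hold_idx,
    )


def svm_kernel_select(
    markers: np.ndarray,
    y: np.ndarray,
    trait_type: str,
    kernels: tuple[str, ...] = ("linear", "poly", "rbf"),
    n_iter: int = 10,
    seed: int = 0,
) -> str:
    """Pick the support-vector kernel with the best mean CV metric.

    Ties (within 1e-12) resolve to the linear kernel when it is offered.
    """
    if not kernels:
        raise ValueError("need at least one kernel")
    if len(kernels) == 1:
        return kernels[0]
    name = "svc" if trait_type == "binary" else "svr"
    specs = [LearnerSpec(name=name, kernel=k_, seed=seed) for k_ in kernels]
    rep = gs_crossvalidate(
        markers,
        y,
        specs,
        counts=[markers.shape[1]],
        trait_type=trait_type,
        n_iter=n_iter,
        holdout=0.10,
        seed=seed,
    )
    s = rep.summary.set_index("learner")["mean_metric"]
    best = float(s.max())
    for k_ in ("linear",) + tuple(kernels):
        label = f"{name}[{k_}]"
        if label in s.index and s[label] >= best - 1e-12:
            return k_
    return kernels[0]  # pragma: no cover


def final_evaluate(
    spec: LearnerSpec,
    markers: np.ndarray,
    y: np.ndarray,
    k: int,
    model_idx: np.ndarray,
    hold_idx: np.ndarray,
    trait_type: str,
    allow_overlap: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Refit the chosen combination on the full 90% and score the holdout.

    Binary traits report accuracy (the point-biserial correlation of
    predictions and labels rides along in the prediction table); continuous
    traits report Pearson r. ``allow_overlap`` is a degenerate override for
    testing resubstitution behaviour; real evaluations keep it off.
    """
    model_idx = np.asarray(model_idx)
    hold_idx = np.asarray(hold_idx)
    if len(hold_idx) == 0:
        raise ValueError("empty test set")
    if np.intersect1d(model_idx, hold_idx).size and not allow_overlap:
        raise ValueError("train and test sets overlap")
    markers = np.asarray(markers, dtype=float)
    y = np.asarray(y)
    model = make_learner(spec)
    model.fit(markers[np.ix_(model_idx, np.arange(k))], y[model_idx])
    pred = _predict(model, markers[np.ix_(hold_idx, np.arange(k))], spec.is_classifier)
    metric = _metric(trait_type, y[hold_idx], pred)
    table = pd.DataFrame(
        {"sample_index": hold_idx, "y_true": y[hold_idx], "y_pred": pred}
    )
    if trait_type == "binary" and np.std(pred) > 0 and np.std(y[hold_idx]) > 0:
        table.attrs["point_biserial_r"] = float(
            stats.pearsonr(y[hold_idx].astype(float), pred.astype(float)).statistic
        )
    return metric, table
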