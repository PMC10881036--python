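"""Classifier-based sleep staging on channel x frequency spectral features.

Three procedures operate on the flattened 15 x 145 = 2175-feature table:

* a linear-kernel SVM with calibrated class probabilities, trained only on
  awake vs midsleep, then *probed* on epochs from stages it never saw
  (presleep, earlysleep, latesleep and the flanking probe minutes) -- the
  awake-class probability traces how brain state evolves around a bout;
* the same recipe trained on short (<14 min) vs long midsleep episodes;
* a multiclass random forest over all five stages with SMOTE class
  balancing, per-class metrics, and permutation feature importance.

Each recipe repeats over five seeded train/test splits (stratified 80/20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .spectra import N_FREQ_BINS, SpectralMatrix

META_COLUMNS = ("label", "fly_id", "minute", "bout_id", "midsleep_min", "clock")


# ------------------------------------------------------------- feature table

def feature_columns(channel_ids: tuple[int, ...]) -> list[str]:
    return [f"ch{c:02d}_f{j:03d}" for c in channel_ids
            for j in range(N_FREQ_BINS)]


def build_feature_table(spectra: list[SpectralMatrix],
                        midsleep_durations: dict[int, dict[int, float]] | None
                        = None) -> pd.DataFrame:
    """One row per epoch: 2175 dB features (channel-major) plus metadata."""
    if not spectra:
        raise ValueError("no spectra supplied")
    ch = spectra[0].channel_ids
    grid = spectra[0].freq_grid
    frames = []
    for sm in spectra:
        if sm.channel_ids != ch or not np.allclose(sm.freq_grid, grid):
            raise ValueError("inconsistent channel/frequency grid across flies")
        X = sm.power_db.reshape(sm.power_db.shape[0], -1)
        df = pd.DataFrame(X, columns=feature_columns(ch))
        df["label"] = sm.labels
        df["fly_id"] = sm.fly_id
        df["minute"] = sm.minute_labels
        df["bout_id"] = sm.bout_ids
        md = (midsleep_durations or {}).get(sm.fly_id, {})
        df["midsleep_min"] = [md.get(int(b), np.nan) / 60.0
                              if int(b) in md else np.nan
                              for b in sm.bout_ids]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if out[feature_columns(ch)].isna().any().any():
        raise ValueError("missing feature values")
    return out


def write_feature_table(table: pd.DataFrame, h5_path=None, csv_path=None) -> None:
    """Persist the feature table: HDF5 (features + metadata) and/or CSV."""
    if h5_path is not None:
        import h5py
        feats = [c for c in table.columns if c not in META_COLUMNS]
        with h5py.File(h5_path, "w") as f:
            f.create_dataset("features", data=table[feats].to_numpy(float))
            f.create_dataset("columns",
                             data=np.array(feats, dtype=h5py.string_dtype()))
            for m in META_COLUMNS:
                if m in table.columns:
                    col = table[m].to_numpy()
                    if col.dtype == object:
                        col = col.astype(str)
                        f.create_dataset(
                            m, data=col.astype(h5py.string_dtype()))
                    else:
                        f.create_dataset(m, data=col)
    if csv_path is not None:
        # 17 significant digits guarantee a lossless float64 round-trip
        table.to_csv(csv_path, index=False, float_format="%.17g")


def read_feature_table(h5_path=None, csv_path=None) -> pd.DataFrame:
    if h5_path is not None:
        import h5py
        with h5py.File(h5_path, "r") as f:
            cols = [c.decode() for c in f["columns"][...]]
            df = pd.DataFrame(f["features"][...], columns=cols)
            for m in META_COLUMNS:
                if m in f:
                    v = f[m][...]
                    if v.dtype.kind in "SO":
                        v = np.array([x.decode() for x in v], dtype=object)
                    df[m] = v
        return df
    return pd.read_csv(csv_path, float_precision="round_trip")


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    feats = [c for c in table.columns if c not in META_COLUMNS]
    return table[feats].to_numpy(float), table["label"].to_numpy()


# ------------------------------------------------------------------ metrics

@dataclass
class ClassifierReport:
    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    roc_auc: float
    confusion: np.ndarray          # row-normalized, rows = true classes

    def min_f1(self) -> float:
        return min(self.f1.values())


def classifier_metrics(y_true, y_pred, scores=None,
                       classes: list[str] | None = None) -> ClassifierReport:
    """Per-class precision/recall/F1, accuracy, ROC AUC, and the
    row-normalized confusion matrix, from their defining count ratios."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true))
    unseen = set(y_pred) - set(classes)
    if unseen:
        raise ValueError(f"prediction contains unseen labels: {unseen}")
    cm = confusion_matrix(y_true, y_pred, labels=classes).astype(float)
    prec, rec, f1 = {}, {}, {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        prec[c], rec[c] = float(p), float(r)
        f1[c] = float(2 * p * r / (p + r)) if p + r > 0 else 0.0
    acc = float((y_true == y_pred).mean())
    auc = float("nan")
    if scores is not None:
        scores = np.asarray(scores)
        try:
            if len(classes) == 2:
                s = scores[:, 1] if scores.ndim == 2 else scores
                auc = float(roc_auc_score(y_true == classes[1], s))
            else:
                auc = float(roc_auc_score(y_true, scores,
                                          multi_class="ovr",
                                          labels=classes, average="macro"))
        except ValueError:
            pass
    row = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row, out=np.zeros_like(cm), where=row > 0)
    return ClassifierReport(list(classes), prec, rec, f1, acc, auc, cm_norm)


def mean_report(reports: list[ClassifierReport]) -> ClassifierReport:
    classes = reports[0].classes
    return ClassifierReport(
        classes,
        {c: float(np.mean([r.precision[c] for r in reports])) for c in classes},
        {c: float(np.mean([r.recall[c] for r in reports])) for c in classes},
        {c: float(np.mean([r.f1[c] for r in reports])) for c in classes},
        float(np.mean([r.accuracy for r in reports])),
        float(np.nanmean([r.roc_auc for r in reports])),
        np.mean([r.confusion for r in reports], axis=0),
    )


# -------------------------------------------------------------------- SMOTE

def smote(X: np.ndarray, y: np.ndarray, k: int = 5,
          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling: new minority samples interpolate
    between a sample and one of its k nearest same-class neighbours."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    Xs, ys = [X], [y]
    for c, cnt in zip(classes, counts):
        need = n_max - cnt
        if need == 0:
            continue
        Xc = X[y == c]
        if cnt < k + 1:
            raise ValueError(
                f"class {c!r} has {cnt} samples; SMOTE needs > {k}")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)
        base = rng.integers(0, cnt, size=need)
        nbr = idx[base, rng.integers(1, k + 1, size=need)]
        lam = rng.random(need)[:, None]
        Xs.append(Xc[base] + lam * (Xc[nbr] - Xc[base]))
        ys.append(np.full(need, c, dtype=y.dtype))
    return np.concatenate(Xs), np.concatenate(ys)


def downsample_balance(X: np.ndarray, y: np.ndarray,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep]


# ------------------------------------------------------------ SVM stagers

@dataclass
class StagingModel:
    pipelines: list[tuple[StandardScaler, object]]   # (scaler, calibrated SVM)
    classes: list[str]
    seed: int

    def probability(self, X: np.ndarray, of_class: str) -> np.ndarray:
        """Class probability averaged over the five split iterations."""
        probs = []
        for scaler, clf in self.pipelines:
            p = clf.predict_proba(scaler.transform(X))
            j = list(clf.classes_).index(of_class)
            probs.append(p[:, j])
        return np.mean(probs, axis=0)


def _svm_iterations(X, y, seed, n_iterations=5, test_size=0.2):
    pipes, reports = [], []
    for it in range(n_iterations):
        s = seed + it
        Xb, yb = downsample_balance(X, y, seed=s)
        Xtr, Xte, ytr, yte = train_test_split(
            Xb, yb, test_size=test_size, stratify=yb, random_state=s)
        scaler = StandardScaler().fit(Xtr)
        # linear-kernel maximum-margin classifier; Platt-style sigmoid
        # calibration via internal cross-validation gives class probabilities
        clf = CalibratedClassifierCV(SVC(kernel="linear", random_state=s),
                                     method="sigmoid", ensemble=False, cv=5)
        clf.fit(scaler.transform(Xtr), ytr)
        Xte_s = scaler.transform(Xte)
        rep = classifier_metrics(yte, clf.predict(Xte_s),
                                 clf.predict_proba(Xte_s),
                                 classes=sorted(set(yb)))
        pipes.append((scaler, clf))
        reports.append(rep)
    return pipes, reports


def train_probability_stager(table: pd.DataFrame,
                             train_classes=("awake", "midsleep"),
                             seed: int = 0, n_iterations: int = 5
                             ) -> tuple[StagingModel, ClassifierReport]:
    """Linear-kernel SVM with calibrated probabilities on two stages.

    Classes are balanced by random downsampling; features are standardized
    with statistics fit on the training rows only; the recipe repeats over
    ``n_iterations`` stratified 80/20 splits.
    """
    sub = table[table.label.isin(train_classes)]
    for c in train_classes:
        if (sub.label == c).sum() < 10:
            raise ValueError(f"class {c!r} has fewer than 10 epochs")
    X, y = _xy(sub)
    pipes, reports = _svm_iterations(X, y, seed, n_iterations)
    return (StagingModel(pipes, sorted(train_classes), seed),
            mean_report(reports))


def probe_unseen_epochs(model: StagingModel, table: pd.DataFrame,
                        of_class: str = "awake") -> pd.DataFrame:
    """Awake-class probability for every epoch, tagged by its
    minute-relative-to-bout label.  Probe stages were never in training."""
    X, _ = _xy(table)
    p = model.probability(X, of_class)
    return pd.DataFrame({
        "label": table["label"].to_numpy(),
        "minute": table["minute"].to_numpy(),
        "fly_id": table["fly_id"].to_numpy(),
        "p": p,
    })


def probability_by_minute(probe: pd.DataFrame) -> pd.Series:
    return probe.groupby("minute")["p"].mean()


def train_midsleep_duration_stager(table: pd.DataFrame,
                                   split_at_min: float = 14.0,
                                   seed: int = 0, n_iterations: int = 5
                                   ) -> tuple[StagingModel, ClassifierReport]:
    """SVM on midsleep epochs labeled short (<14 min) vs long (>=14 min)
    by their episode's midsleep duration."""
    sub = table[(table.label == "midsleep")
                & table.midsleep_min.notna()].copy()
    if sub.empty:
        raise ValueError("no midsleep epochs with duration metadata")
    sub["label"] = np.where(sub.midsleep_min < split_at_min,
                            "short_midsleep", "long_midsleep")
    for c in ("short_midsleep", "long_midsleep"):
        if (sub.label == c).sum() < 10:
            raise ValueError(f"class {c!r} has fewer than 10 epochs")
    X, y = _xy(sub)
    pipes, reports = _svm_iterations(X, y, seed, n_iterations)
    return (StagingModel(pipes, ["long_midsleep", "short_midsleep"], seed),
            mean_report(reports))


# -------------------------------------------------------------- RF stager

@dataclass
class ImportanceMap:
    scores: np.ndarray             # (n_channels, 145)
    channel_ids: tuple[int, ...]
    freq_grid: np.ndarray


@dataclass
class RFResult:
    reports: list[ClassifierReport]
    report: ClassifierReport       # mean over iterations
    importance: ImportanceMap | None
    models: list[RandomForestClassifier] = field(default_factory=list)


def _batched_permutation_importance(clf, X: np.ndarray, y: np.ndarray,
                                    n_repeats: int = 5, seed: int = 0,
                                    block: int = 32) -> np.ndarray:
    """Permutation importance: drop in the model score when one feature is
    shuffled.

    The score is the mean log-probability of the true class, which stays
    sensitive when redundant features keep the predicted labels unchanged.
    Features are shuffled in blocks and scored in one predict call per
    block, amortizing the estimator's per-call overhead; scores are
    identical in distribution to the one-feature-at-a-time procedure.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    classes = list(clf.classes_)
    yi = np.array([classes.index(c) for c in y])

    def score(proba: np.ndarray) -> float:
        return float(np.log(np.maximum(proba[np.arange(n), yi],
                                       1e-12)).mean())

    base = score(clf.predict_proba(X))
    imp = np.zeros(p)
    for start in range(0, p, block):
        feats = np.arange(start, min(start + block, p))
        k = feats.size
        Xb = np.tile(X, (k * n_repeats, 1))
        for bi, f in enumerate(feats):
            for r in range(n_repeats):
                rows = slice((bi * n_repeats + r) * n,
                             (bi * n_repeats + r + 1) * n)
                Xb[rows, f] = X[rng.permutation(n), f]
        proba = clf.predict_proba(Xb)
        for bi, f in enumerate(feats):
            drops = [base - score(
                proba[(bi * n_repeats + r) * n:(bi * n_repeats + r + 1) * n])
                for r in range(n_repeats)]
            imp[f] = float(np.mean(drops))
    return imp


_RF_DEFAULTS = dict(n_estimators=100, max_depth=None, max_features="sqrt")
_RF_GRID = {"n_estimators": [200, 500], "max_depth": [None, 10, 20],
            "max_features": ["sqrt", 0.1]}


def _tune_rf(Xtr, ytr, seed):
    from sklearn.model_selection import GridSearchCV, RandomizedSearchCV
    rs = RandomizedSearchCV(RandomForestClassifier(random_state=seed),
                            _RF_GRID, n_iter=4, cv=2, random_state=seed)
    rs.fit(Xtr, ytr)
    base = rs.best_params_
    small = {k: [v] for k, v in base.items()}
    small["max_depth"] = list({base["max_depth"], None})
    gs = GridSearchCV(RandomForestClassifier(random_state=seed), small, cv=2)
    gs.fit(Xtr, ytr)
    return gs.best_params_


def train_rf_multiclass(table: pd.DataFrame, classes: list[str] | None = None,
                        seed: int = 0, n_iterations: int = 5,
                        smote_before_split: bool = True,
                        compute_importance: bool = True,
                        importance_repeats: int = 5,
                        max_importance_rows: int = 120,
                        tune: bool = False) -> RFResult:
    """Multiclass random forest with SMOTE balancing and permutation
    importance.

    SMOTE is applied before the train/test split by default (the recipe
    this reproduces orders it that way; ``smote_before_split=False`` gives
    the leakage-safe variant).  Importance is the mean decrease in accuracy
    over ``importance_repeats`` shuffles per split, averaged over splits.
    """
    if classes is None:
        classes = sorted(table.label.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    sub = table[table.label.isin(classes)]
    counts = sub.label.value_counts()
    for c in classes:
        if counts.get(c, 0) < 6:
            raise ValueError(f"class {c!r} has fewer than 6 epochs "
                             "(SMOTE neighbourhood)")
    X, y = _xy(sub)
    ch = tuple(sorted({int(c[2:4]) for c in sub.columns
                       if c not in META_COLUMNS}))
    reports, models = [], []
    imp_acc = None
    rng = np.random.default_rng(seed)
    for it in range(n_iterations):
        s = seed + it
        if smote_before_split:
            Xb, yb = smote(X, y, seed=s)
            Xtr, Xte, ytr, yte = train_test_split(
                Xb, yb, test_size=0.2, stratify=yb, random_state=s)
        else:
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, test_size=0.2, stratify=y, random_state=s)
            Xtr, ytr = smote(Xtr, ytr, seed=s)
        scaler = StandardScaler().fit(Xtr)
        Xtr_s, Xte_s = scaler.transform(Xtr), scaler.transform(Xte)
        params = _tune_rf(Xtr_s, ytr, s) if tune else dict(_RF_DEFAULTS)
        clf = RandomForestClassifier(random_state=s, **params)
        clf.fit(Xtr_s, ytr)
        reports.append(classifier_metrics(
            yte, clf.predict(Xte_s), clf.predict_proba(Xte_s),
            classes=sorted(classes)))
        models.append(clf)
        if compute_importance:
            if Xte_s.shape[0] > max_importance_rows:
                sel = rng.choice(Xte_s.shape[0], max_importance_rows,
                                 replace=False)
                Xi, yi = Xte_s[sel], yte[sel]
            else:
                Xi, yi = Xte_s, yte
            pi = _batched_permutation_importance(
                clf, Xi, yi, n_repeats=importance_repeats, seed=s)
            imp_acc = pi if imp_acc is None else imp_acc + pi
    importance = None
    if compute_importance:
        from .spectra import FREQ_GRID
        scores = (imp_acc / n_iterations).reshape(len(ch), N_FREQ_BINS)
        importance = ImportanceMap(scores, ch, FREQ_GRID.copy())
    return RFResult(reports, mean_report(reports), importance, models)
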