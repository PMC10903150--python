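"""Patch-based sparse dictionary-learning prediction of FEV1 decline.

Multi-channel patches (V_Norm, V_fSAD, chi_Norm, chi_fSAD) are drawn at
random in-lung locations.  One overcomplete dictionary per progression
class is learned by alternating orthogonal matching pursuit (OMP) sparse
coding with atom-wise dictionary updates (approximate K-SVD).  A test
patch is labelled by the dictionary that reconstructs it with the smaller
sparse-coding residual; a case is scored by its fraction of
abnormal/fast-associated patches.

Because chi is normalised per masked voxel its numerical range is ~100x
smaller than V's; channels are therefore rescaled to unit variance using
training statistics stored in the model, so every channel can contribute
to the L2 residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import orthogonal_mp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score, roc_curve, auc as _trapezoid_auc

from .topology import TPRMMaps

__all__ = [
    "PatchSet",
    "DictionaryModel",
    "stratified_split",
    "extract_patches",
    "train_dictionaries",
    "classify_patches",
    "classify_case",
    "evaluate",
    "EvalResult",
    "mrmr_rank",
    "logistic_baseline",
    "stability_analysis",
    "patch_dice",
]

DEFAULT_CHANNELS = ("V_Norm", "V_fSAD", "chi_Norm", "chi_fSAD")


def stratified_split(case_labels, train_fraction: float = 0.35, seed: int = 0):
    """Disjoint, exhaustive per-class split into train and test case indices.

    Each class contributes ``round(train_fraction * class_size)`` cases to
    the training partition.
    """
    labels = np.asarray(case_labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes to stratify")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


@dataclass
class PatchSet:
    """Vectorised multi-channel patches with their provenance.

    ``patches`` has shape (n_patches, patch_edge^3 * n_channels); the
    channel order is fixed and recorded in ``channels``.
    """

    patches: np.ndarray
    patch_edge_vox: int
    channels: tuple[str, ...]
    locations: np.ndarray
    case_ids: np.ndarray
    labels: np.ndarray | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.patches)

    def select_channels(self, channels) -> "PatchSet":
        """Restrict the patch vectors to a subset of channels."""
        d = self.patch_edge_vox ** 3
        cols = []
        for ch in channels:
            i = self.channels.index(ch)
            cols.append(np.arange(i * d, (i + 1) * d))
        return PatchSet(
            patches=self.patches[:, np.concatenate(cols)],
            patch_edge_vox=self.patch_edge_vox,
            channels=tuple(channels),
            locations=self.locations,
            case_ids=self.case_ids,
            labels=self.labels,
            seed=self.seed,
        )


def _concat_patchsets(sets: list[PatchSet]) -> PatchSet:
    first = sets[0]
    return PatchSet(
        patches=np.concatenate([s.patches for s in sets]),
        patch_edge_vox=first.patch_edge_vox,
        channels=first.channels,
        locations=np.concatenate([s.locations for s in sets]),
        case_ids=np.concatenate([s.case_ids for s in sets]),
        labels=(np.concatenate([s.labels for s in sets])
                if all(s.labels is not None for s in sets) else None),
        seed=first.seed,
    )


def extract_patches(
    tprm_maps: TPRMMaps,
    lung_mask: np.ndarray | None = None,
    n_patches: int = 500,
    patch_edge_vox: int = 21,
    seed: int = 0,
    case_id: str = "case0",
    channels=DEFAULT_CHANNELS,
    min_lung_fraction: float = 0.5,
) -> PatchSet:
    """Randomly sample in-lung multi-channel patches from interpolated maps.

    Patch centres are drawn uniformly from lung voxels whose patch window
    lies inside the volume and covers at least ``min_lung_fraction`` lung.
    Deterministic under ``seed``.
    """
    mask = tprm_maps.lung_mask if lung_mask is None else np.asarray(lung_mask, bool)
    e = patch_edge_vox
    h = e // 2
    shape = np.array(mask.shape)

    fields = []
    for ch in channels:
        kind, cls = ch.split("_", 1)
        fields.append(tprm_maps.V[cls] if kind == "V" else tprm_maps.chi[cls])

    cand = np.argwhere(mask)
    cand = cand[np.all((cand - h >= 0) & (cand + h + 1 <= shape), axis=1)]
    if len(cand) == 0:
        raise ValueError("lung too small for the requested patch size")

    rng = np.random.default_rng(seed)
    locs = np.empty((n_patches, 3), dtype=int)
    vecs = np.empty((n_patches, e**3 * len(channels)), dtype=np.float32)
    got = 0
    for _ in range(50 * n_patches + 100):
        if got == n_patches:
            break
        c = cand[rng.integers(len(cand))]
        sl = tuple(slice(ci - h, ci + h + 1) for ci in c)
        if mask[sl].mean() < min_lung_fraction:
            continue
        vecs[got] = np.concatenate([f[sl].ravel() for f in fields])
        locs[got] = c
        got += 1
    if got < n_patches:
        raise ValueError("could not draw enough patches meeting the lung-coverage rule")
    return PatchSet(patches=vecs, patch_edge_vox=e, channels=tuple(channels),
                    locations=locs, case_ids=np.array([case_id] * n_patches),
                    seed=seed)


@dataclass
class DictionaryModel:
    """Per-class patch dictionaries and their sparse-coding settings."""

    dict_fast: np.ndarray        # (feature_dim, n_atoms), unit-norm columns
    dict_slow: np.ndarray
    sparsity: int                # atoms per code (T)
    channel_scales: np.ndarray   # per-channel std used to rescale patches
    channels: tuple[str, ...]
    patch_edge_vox: int
    aggregation_threshold: float = 0.5
    seed: int = 0
    n_train_fast: int = 0
    n_train_slow: int = 0
    objective_fast: list = field(default_factory=list)
    objective_slow: list = field(default_factory=list)

    def scale_patches(self, patches: np.ndarray) -> np.ndarray:
        d = self.patch_edge_vox ** 3
        out = np.asarray(patches, dtype=np.float64).copy()
        for i, s in enumerate(self.channel_scales):
            out[:, i * d:(i + 1) * d] /= s
        return out


def _channel_scales(patches: np.ndarray, n_channels: int) -> np.ndarray:
    d = patches.shape[1] // n_channels
    scales = np.empty(n_channels)
    for i in range(n_channels):
        s = patches[:, i * d:(i + 1) * d].std()
        scales[i] = s if s > 0 else 1.0
    return scales


def _init_dictionary(X: np.ndarray, n_atoms: int, rng) -> np.ndarray:
    """Seed atoms: randomly chosen training patches, unit-normalised."""
    n = X.shape[1]
    idx = rng.choice(n, size=n_atoms, replace=n_atoms > n)
    D = X[:, idx].astype(np.float64).copy()
    norms = np.linalg.norm(D, axis=0)
    dead = norms < 1e-12
    if dead.any():
        D[:, dead] = rng.normal(size=(X.shape[0], int(dead.sum())))
        norms = np.linalg.norm(D, axis=0)
    return D / norms


def _sparse_code(D: np.ndarray, X: np.ndarray, T: int) -> np.ndarray:
    """OMP codes (n_atoms, n_signals) with at most T atoms per signal."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        # early stopping on linearly dependent atoms is expected and benign
        _warnings.filterwarnings("ignore", message="Orthogonal matching pursuit")
        A = orthogonal_mp(D, X, n_nonzero_coefs=min(T, D.shape[1]),
                          precompute=True)
    if A.ndim == 1:
        A = A[:, None]
    return A


def _ksvd_class(X: np.ndarray, n_atoms: int, T: int, n_iter: int, rng):
    """Approximate K-SVD on signals X (feature_dim, n): returns (D, errors)."""
    D = _init_dictionary(X, n_atoms, rng)
    errors: list[float] = []
    prev_err = np.inf
    for _ in range(n_iter):
        A = _sparse_code(D, X, T)
        err = float(((X - D @ A) ** 2).sum() / X.shape[1])
        if err > prev_err + 1e-12:
            break  # keep the previous (better) dictionary
        errors.append(err)
        prev_err = err
        D_prev = D.copy()
        R = X - D @ A
        for j in range(n_atoms):
            users = np.flatnonzero(A[j])
            if len(users) == 0:
                # re-seed a dead atom with the worst-reconstructed signal
                worst = int(np.argmax((R ** 2).sum(axis=0)))
                d = X[:, worst].astype(np.float64)
                nrm = np.linalg.norm(d)
                if nrm > 1e-12:
                    D[:, j] = d / nrm
                continue
            Rj = R[:, users] + np.outer(D[:, j], A[j, users])
            d = Rj @ A[j, users]
            nrm = np.linalg.norm(d)
            if nrm < 1e-12:
                continue
            d /= nrm
            a_new = Rj.T @ d
            D[:, j] = d
            A[j, users] = a_new
            R[:, users] = Rj - np.outer(d, a_new)
        # guard: revert if the atom pass somehow worsened the fit
        A2 = _sparse_code(D, X, T)
        err2 = float(((X - D @ A2) ** 2).sum() / X.shape[1])
        if err2 > err + 1e-12:
            D = D_prev
            break
    return D, errors


def train_dictionaries(
    train_patches_fast: PatchSet,
    train_patches_slow: PatchSet,
    n_atoms: int = 128,
    T: int = 5,
    n_iter: int = 30,
    seed: int = 0,
    aggregation_threshold: float = 0.5,
) -> DictionaryModel:
    """Learn one unit-norm patch dictionary per progression class.

    Patches from fast-progressor cases supervise the "abnormal" dictionary
    and patches from slow-progressor cases the "normal" one (weak,
    case-level supervision).  ``n_iter = 0`` returns the seeded initial
    dictionaries unchanged.
    """
    if len(train_patches_fast) == 0 or len(train_patches_slow) == 0:
        raise ValueError("both progression classes need training patches")
    if n_atoms > min(len(train_patches_fast), len(train_patches_slow)):
        raise ValueError("n_atoms exceeds the number of training patches")
    if train_patches_fast.channels != train_patches_slow.channels:
        raise ValueError("channel mismatch between training patch sets")

    nch = len(train_patches_fast.channels)
    allp = np.concatenate([train_patches_fast.patches, train_patches_slow.patches])
    scales = _channel_scales(allp, nch)

    model = DictionaryModel(
        dict_fast=np.empty(0), dict_slow=np.empty(0), sparsity=T,
        channel_scales=scales, channels=train_patches_fast.channels,
        patch_edge_vox=train_patches_fast.patch_edge_vox,
        aggregation_threshold=aggregation_threshold, seed=seed,
        n_train_fast=len(train_patches_fast),
        n_train_slow=len(train_patches_slow),
    )
    Xf = model.scale_patches(train_patches_fast.patches).T
    Xs = model.scale_patches(train_patches_slow.patches).T
    rng = np.random.default_rng(seed)
    if n_iter == 0:
        model.dict_fast = _init_dictionary(Xf, n_atoms, rng)
        model.dict_slow = _init_dictionary(Xs, n_atoms, rng)
        return model
    model.dict_fast, model.objective_fast = _ksvd_class(Xf, n_atoms, T, n_iter, rng)
    model.dict_slow, model.objective_slow = _ksvd_class(Xs, n_atoms, T, n_iter, rng)
    return model


def classify_patches(model: DictionaryModel, patches: PatchSet | np.ndarray):
    """Label each patch by the dictionary with the smaller OMP residual.

    Returns a boolean array (True = abnormal/fast-associated).  Ties break
    toward the normal/slow class.
    """
    X = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    if X.shape[1] != model.dict_fast.shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match model {model.dict_fast.shape[0]}")
    Xs = model.scale_patches(X).T
    rf = Xs - model.dict_fast @ _sparse_code(model.dict_fast, Xs, model.sparsity)
    rs = Xs - model.dict_slow @ _sparse_code(model.dict_slow, Xs, model.sparsity)
    res_fast = (rf ** 2).sum(axis=0)
    res_slow = (rs ** 2).sum(axis=0)
    return res_fast < res_slow


def classify_case(model: DictionaryModel, patch_labels: np.ndarray):
    """Case-level score and label from its patch labels.

    The score is the abnormal-patch fraction; the case is called fast when
    the score reaches the model's aggregation threshold.
    """
    patch_labels = np.asarray(patch_labels, dtype=bool)
    if patch_labels.size == 0:
        raise ValueError("need at least one patch")
    score = float(patch_labels.mean())
    return score, ("fast" if score >= model.aggregation_threshold else "slow")


def patch_probability_map(locations, patch_labels, shape, patch_edge_vox):
    """Render patch labels at their locations as a voxel abnormality map.

    Each voxel gets the mean abnormality of the patches covering it; NaN
    where no patch reaches.
    """
    votes = np.zeros(shape)
    cover = np.zeros(shape)
    h = patch_edge_vox // 2
    for loc, lab in zip(np.asarray(locations), np.asarray(patch_labels)):
        sl = tuple(slice(c - h, c + h + 1) for c in loc)
        votes[sl] += float(lab)
        cover[sl] += 1.0
    out = np.full(shape, np.nan)
    hit = cover > 0
    out[hit] = votes[hit] / cover[hit]
    return out


def patch_dice(locations, patch_labels, truth_mask, patch_edge_vox) -> float:
    """Dice overlap of abnormal-patch coverage with a planted region.

    Both prediction and truth are rasterised at patch resolution: the
    comparison is restricted to voxels covered by at least one patch, and a
    patch counts as truth-positive where the planted region is.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    pred = np.zeros(truth_mask.shape, dtype=bool)
    covered = np.zeros(truth_mask.shape, dtype=bool)
    h = patch_edge_vox // 2
    for loc, lab in zip(np.asarray(locations), np.asarray(patch_labels)):
        sl = tuple(slice(c - h, c + h + 1) for c in loc)
        covered[sl] = True
        if lab:
            pred[sl] = True
    truth_cov = truth_mask & covered
    denom = pred.sum() + truth_cov.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * (pred & truth_cov).sum() / denom)


@dataclass
class EvalResult:
    confusion: np.ndarray       # rows: true (slow, fast); cols: pred (slow, fast)
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def evaluate(labels_true, scores, threshold: float = 0.5) -> EvalResult:
    """ROC/AUC and the confusion matrix at a score threshold.

    ``labels_true`` may be booleans or "fast"/"slow" strings; fast is the
    positive class.  AUC is the trapezoidal area under the ROC curve.
    """
    y = np.asarray(labels_true)
    if y.dtype.kind in "OUS":
        y = y == "fast"
    y = y.astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must be aligned")
    if y.all() or not y.any():
        raise ValueError("AUC undefined: ground truth contains a single class")
    fpr, tpr, _ = roc_curve(y, s)
    area = float(_trapezoid_auc(fpr, tpr))
    pred = s >= threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    return EvalResult(
        confusion=np.array([[tn, fp], [fn, tp]]),
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        fpr=fpr, tpr=tpr, auc=area,
    )


def _binned(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x)


def mrmr_rank(features_by_case, labels, feature_names=None, n_bins: int = 8):
    """Greedy minimum-redundancy maximum-relevance feature ranking.

    Mutual information is estimated on quantile-binned variables
    (``n_bins`` bins).  The first feature maximises relevance MI(f, label);
    each next one maximises relevance minus mean redundancy with the
    already-selected set.  Returns ``[(name, score), ...]`` in rank order.
    """
    X = np.asarray(features_by_case, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2D feature matrix with >= 2 features")
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == "fast").astype(int)
    names = list(feature_names) if feature_names is not None \
        else [f"f{i}" for i in range(X.shape[1])]
    B = np.column_stack([_binned(X[:, j], n_bins) for j in range(X.shape[1])])
    relevance = np.array([mutual_info_score(B[:, j], y) for j in range(X.shape[1])])
    mi_ff = {}

    def _red(i, j):
        key = (min(i, j), max(i, j))
        if key not in mi_ff:
            mi_ff[key] = mutual_info_score(B[:, key[0]], B[:, key[1]])
        return mi_ff[key]

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(X.shape[1]))
    while remaining:
        if not selected:
            crit = [relevance[j] for j in remaining]
        else:
            crit = [relevance[j] - np.mean([_red(j, s) for s in selected])
                    for j in remaining]
        best = int(np.argmax(crit))
        scores.append(float(crit[best]))
        selected.append(remaining.pop(best))
    return [(names[j], sc) for j, sc in zip(selected, scores)]


def logistic_baseline(whole_lung_means_by_case, labels, train_idx, test_idx):
    """Logistic-regression baseline on whole-lung mean tPRM values.

    Fits a near-unregularised model on the training partition; if the fit
    does not converge (e.g. complete separation) it falls back to a
    ridge-regularised fit and flags it.  Returns
    ``(eval_result, scores_test, regularized_flag)``.
    """
    X = np.asarray(whole_lung_means_by_case, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == "fast").astype(int)
    mu, sd = X[train_idx].mean(axis=0), X[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    flagged = False
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning
    with _warnings.catch_warnings():
        _warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=1e6, max_iter=2000).fit(Z[train_idx], y[train_idx])
        except ConvergenceWarning:
            flagged = True
            clf = LogisticRegression(C=1.0, max_iter=2000).fit(Z[train_idx], y[train_idx])
    scores = clf.predict_proba(Z[test_idx])[:, 1]
    return evaluate(y[test_idx].astype(bool), scores), scores, flagged


def stability_analysis(
    train_fast: PatchSet,
    train_slow: PatchSet,
    test_patchsets: list[PatchSet],
    test_labels,
    channels=DEFAULT_CHANNELS,
    n_runs: int = 10,
    subsample: float = 0.7,
    n_atoms: int = 32,
    T: int = 3,
    n_iter: int = 10,
    seed: int = 0,
):
    """Per-input stability of the prediction accuracy.

    For each single input channel, the model is retrained ``n_runs`` times
    on different random subsets of the training patches and its test-set
    accuracy recorded; a Gaussian is fitted to the accuracies.  Returns
    ``{channel: {"accuracies": [...], "mean": m, "sd": s}}``.
    """
    y = np.asarray(test_labels)
    if y.dtype.kind in "OUS":
        y = y == "fast"
    out = {}
    for ch in channels:
        tf = train_fast.select_channels([ch])
        ts = train_slow.select_channels([ch])
        accs = []
        for run in range(n_runs):
            rng = np.random.default_rng(seed + 977 * run)
            sf = np.sort(rng.choice(len(tf), max(n_atoms, int(subsample * len(tf))),
                                    replace=False))
            ss = np.sort(rng.choice(len(ts), max(n_atoms, int(subsample * len(ts))),
                                    replace=False))
            sub_f = PatchSet(tf.patches[sf], tf.patch_edge_vox, tf.channels,
                             tf.locations[sf], tf.case_ids[sf])
            sub_s = PatchSet(ts.patches[ss], ts.patch_edge_vox, ts.channels,
                             ts.locations[ss], ts.case_ids[ss])
            model = train_dictionaries(sub_f, sub_s, n_atoms=n_atoms, T=T,
                                       n_iter=n_iter, seed=seed + run)
            preds = []
            for ps in test_patchsets:
                lab = classify_patches(model, ps.select_channels([ch]))
                score, _ = classify_case(model, lab)
                preds.append(score >= model.aggregation_threshold)
            accs.append(float((np.asarray(preds) == y).mean()))
        m, s = stats.norm.fit(accs)
        out[ch] = {"accuracies": accs, "mean": float(m), "sd": float(s)}
    return out
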