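"""Task-related component analysis (TRCA) decoding of realness level.

For each class (realness level) a spatial filter w maximizes

    w' S w / w' Q w,

where S sums the channel-by-channel cross-covariances of the class's
session-mean responses over all ordered pairs of distinct sessions, and Q
is the covariance of the class template (the session-average response);
maximizing the ratio enhances components reproduced consistently across
sessions.  A test trial is classified by the Pearson correlation between
the filtered template and the filtered test data, taking the class with
the largest correlation.  Evaluation is leave-one-session-out cross-
validation; significance is assessed by a label-permutation test that
reruns the whole train/test pipeline.

Filters operate on a nine-channel parieto-occipital cluster by default.
Component signals are in arbitrary units; classification is invariant to
the scale and sign of each filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CLUSTER9
from .io_preproc import Epochs

__all__ = ["TRCAModel", "ClassificationResult", "PermutationResult",
           "fit_trca", "predict_trca", "cross_validate", "permutation_test"]


@dataclass
class TRCAModel:
    """Per-class spatial filters and templates."""

    classes: list
    filters: np.ndarray     # n_classes x n_channels
    templates: np.ndarray   # n_classes x n_channels x L
    ch_names: list[str]
    srate: float

    @property
    def window_len(self) -> int:
        return self.templates.shape[2]

    def save(self, basepath):
        """Serialize to JSON metadata + .npz weights; returns JSON path."""
        import json
        from pathlib import Path

        base = Path(basepath)
        base.parent.mkdir(parents=True, exist_ok=True)
        np.savez(base.with_suffix(".npz"), filters=self.filters,
                 templates=self.templates)
        meta = dict(classes=[int(c) for c in self.classes],
                    ch_names=list(self.ch_names), srate=self.srate,
                    weights=base.with_suffix(".npz").name)
        path = base.with_suffix(".json")
        path.write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, json_path):
        import json
        from pathlib import Path

        path = Path(json_path)
        meta = json.loads(path.read_text())
        weights = np.load(path.parent / meta["weights"])
        return cls(meta["classes"], weights["filters"], weights["templates"],
                   meta["ch_names"], meta["srate"])


@dataclass
class ClassificationResult:
    """Cross-validated decoding outcome."""

    classes: list
    accuracy: float                  # mean across subjects, in [0, 1]
    accuracy_sd: float               # SD across subjects
    per_subject: dict
    confusion: np.ndarray            # row-normalized (true x predicted)
    n_trials: int
    p_value: float | None = None


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    permuted: np.ndarray = field(repr=False)


def _fit_arrays(data: np.ndarray, sessions: np.ndarray, realness: np.ndarray,
                classes, q_matrix: str, ridge: float):
    """Numpy core of the fit: returns (filters, templates)."""
    from scipy.linalg import eigh

    n_ch, L = data.shape[1], data.shape[2]
    filters = np.zeros((len(classes), n_ch))
    templates = np.zeros((len(classes), n_ch, L))
    for k, cls in enumerate(classes):
        cls_mask = realness == cls
        sess_ids = np.unique(sessions[cls_mask])
        if sess_ids.size < 2:
            raise ValueError(
                f"class {cls} has {sess_ids.size} session(s); TRCA needs at "
                "least two sessions to form cross-session covariances"
            )
        sess = np.stack([data[cls_mask & (sessions == h)].mean(axis=0)
                         for h in sess_ids])
        sess -= sess.mean(axis=2, keepdims=True)
        template = sess.mean(axis=0)
        templates[k] = template
        if n_ch == 1:
            filters[k] = 1.0
            continue

        # S = sum over ordered pairs h1 != h2 of Cov(x^{h1}, x^{h2})
        total = sess.sum(axis=0)
        within = np.einsum("hcl,hdl->cd", sess, sess)
        s_mat = (total @ total.T - within) / L
        s_mat = 0.5 * (s_mat + s_mat.T)

        if q_matrix == "template":
            q_mat = template @ template.T / L
        else:
            q_mat = within / L
        if ridge > 0:
            q_mat = q_mat + ridge * np.trace(q_mat) / n_ch * np.eye(n_ch)
        cond = np.linalg.cond(q_mat)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"Q matrix for class {cls} is singular; pass ridge > 0"
            )
        _, vecs = eigh(s_mat, q_mat)
        filters[k] = vecs[:, -1]
    return filters, templates


def _predict_many(filters: np.ndarray, templates: np.ndarray,
                  tests: np.ndarray, warn_ties: bool = True):
    """Vectorized template-correlation classification.

    ``tests`` is n_trials x n_ch x L; returns (argmax indices, rho matrix
    of shape n_trials x n_classes).
    """
    n_cls = filters.shape[0]
    rho = np.empty((tests.shape[0], n_cls))
    for k in range(n_cls):
        ref = filters[k] @ templates[k]
        ref = ref - ref.mean()
        ref_norm = np.linalg.norm(ref)
        proj = np.einsum("c,ncl->nl", filters[k], tests)
        proj = proj - proj.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(proj, axis=1) * ref_norm
        norms[norms == 0] = np.inf
        rho[:, k] = proj @ ref / norms
    best = np.argmax(rho, axis=1)
    if warn_ties:
        ties = (rho == rho[np.arange(len(best)), best][:, None]).sum(axis=1)
        if np.any(ties > 1):
            warnings.warn("tied correlations; choosing the lowest class index",
                          RuntimeWarning, stacklevel=3)
    return best, rho


def fit_trca(ep: Epochs, classes=None, channels=CLUSTER9,
             window_s: float | None = None, q_matrix: str = "template",
             ridge: float = 0.0) -> TRCAModel:
    """Train one TRCA filter and template per class.

    ``window_s`` restricts training to the first ``window_s`` seconds of
    each epoch (measured from the trimmed-trial start).  ``q_matrix``
    selects the denominator covariance: ``"template"`` uses the covariance
    of the session-averaged template, ``"concatenated"`` the summed
    within-session covariance of the session means; both yield the same
    optimal filter up to scale.  ``ridge`` adds ``ridge * trace(Q)/n_ch``
    to Q's diagonal for ill-conditioned short windows.
    """
    if q_matrix not in ("template", "concatenated"):
        raise ValueError(f"unknown q_matrix: {q_matrix!r}")
    if channels is not None:
        ep = ep.pick_channels(list(channels))
    data = ep.data
    if window_s is not None:
        L = int(round(window_s * ep.srate))
        if L > data.shape[2]:
            raise ValueError(f"window of {window_s} s exceeds epoch length")
        data = data[:, :, :L]
    labels = ep.labels.reset_index(drop=True)
    if classes is None:
        classes = sorted(labels["realness"].unique())
    filters, templates = _fit_arrays(
        data, labels["session"].to_numpy(), labels["realness"].to_numpy(),
        list(classes), q_matrix, ridge)
    return TRCAModel(list(classes), filters, templates, list(ep.ch_names),
                     ep.srate)


def predict_trca(model: TRCAModel, x_test: np.ndarray):
    """Classify a single trial (n_channels x L).

    Returns ``(predicted_class, rho)`` where ``rho[c]`` is the Pearson
    correlation between the filtered class template and the filtered test
    data.  Exact ties resolve to the lowest class index (with a warning).
    """
    x_test = np.asarray(x_test, dtype=float)
    if x_test.shape != (len(model.ch_names), model.window_len):
        raise ValueError(
            f"test data shape {x_test.shape} does not match model "
            f"({len(model.ch_names)} channels x {model.window_len} samples)"
        )
    best, rho = _predict_many(model.filters, model.templates, x_test[None])
    return model.classes[int(best[0])], rho[0]


def _check_balance(sessions: np.ndarray, realness: np.ndarray, classes) -> None:
    mask = np.isin(realness, np.asarray(classes))
    pairs, counts = np.unique(
        np.stack([sessions[mask], realness[mask]]), axis=1,
        return_counts=True)
    n_sessions = np.unique(sessions).size
    if (np.unique(counts).size != 1
            or pairs.shape[1] != n_sessions * len(classes)):
        raise ValueError(
            "unbalanced class counts per session; leave-one-session-out CV "
            "requires every class in every session with equal counts"
        )


def cross_validate(ep: Epochs, classes=None, channels=CLUSTER9,
                   window_s: float | None = None, q_matrix: str = "template",
                   ridge: float = 0.0) -> ClassificationResult:
    """Leave-one-session-out decoding, averaged across folds then subjects.

    Trials whose realness is outside ``classes`` are ignored.  Per subject,
    each session serves once as the test set while the remainder trains the
    model; the confusion matrix aggregates predictions over all subjects
    and folds and is row-normalized.
    """
    if channels is not None:
        ep = ep.pick_channels(list(channels))
    labels = ep.labels.reset_index(drop=True)
    if classes is None:
        classes = sorted(labels["realness"].unique())
    classes = list(classes)
    return _cross_validate_arrays(
        ep.data, labels["subject"].to_numpy(), labels["session"].to_numpy(),
        labels["realness"].to_numpy(), classes, ep.srate, window_s,
        q_matrix, ridge)


def _cross_validate_arrays(data, subjects, sessions, realness, classes,
                           srate, window_s, q_matrix, ridge,
                           warn_ties: bool = True) -> ClassificationResult:
    if window_s is not None:
        L = int(round(window_s * srate))
        if L > data.shape[2]:
            raise ValueError(f"window of {window_s} s exceeds epoch length")
        data = data[:, :, :L]
    cls_arr = np.asarray(classes)
    cls_idx = {c: i for i, c in enumerate(classes)}

    per_subject = {}
    confusion = np.zeros((len(classes), len(classes)))
    n_total = 0
    for subject in np.unique(subjects):
        s_mask = subjects == subject
        _check_balance(sessions[s_mask], realness[s_mask], classes)
        sess_ids = np.unique(sessions[s_mask])
        if sess_ids.size < 2:
            raise ValueError(f"subject {subject} has fewer than two sessions")
        correct = total = 0
        for held_out in sess_ids:
            train = s_mask & (sessions != held_out)
            test = (s_mask & (sessions == held_out)
                    & np.isin(realness, cls_arr))
            filters, templates = _fit_arrays(
                data[train], sessions[train], realness[train], classes,
                q_matrix, ridge)
            best, _ = _predict_many(filters, templates, data[test],
                                    warn_ties=warn_ties)
            true = realness[test]
            pred = cls_arr[best]
            for t, p in zip(true, pred):
                confusion[cls_idx[t], cls_idx[p]] += 1
            correct += int(np.sum(pred == true))
            total += true.size
        per_subject[subject] = correct / total
        n_total += total

    accs = np.array(list(per_subject.values()))
    row_sums = confusion.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return ClassificationResult(classes, float(accs.mean()),
                                float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
                                per_subject, confusion / row_sums, n_total)


def permutation_test(ep: Epochs, classes=None, n_perm: int = 1000,
                     seed: int = 0, add_one: bool = False,
                     **cv_kwargs) -> PermutationResult:
    """Label-permutation significance of the cross-validated accuracy.

    Realness labels are shuffled among the included trials *within* each
    subject x session (preserving the CV fold structure and balance), the
    full fit + cross-validation is rerun, and

        p = #(permuted accuracy > observed) / n_perm.

    ``add_one`` switches to the (1 + #(perm >= obs)) / (n_perm + 1)
    estimator, which cannot return exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    channels = cv_kwargs.pop("channels", CLUSTER9)
    if channels is not None:
        ep = ep.pick_channels(list(channels))
    labels = ep.labels.reset_index(drop=True)
    if classes is None:
        classes = sorted(labels["realness"].unique())
    classes = list(classes)
    subjects = labels["subject"].to_numpy()
    sessions = labels["session"].to_numpy()
    realness = labels["realness"].to_numpy()
    window_s = cv_kwargs.pop("window_s", None)
    q_matrix = cv_kwargs.pop("q_matrix", "template")
    ridge = cv_kwargs.pop("ridge", 0.0)
    if cv_kwargs:
        raise TypeError(f"unknown cross-validation options: {sorted(cv_kwargs)}")

    observed = _cross_validate_arrays(ep.data, subjects, sessions, realness,
                                      classes, ep.srate, window_s, q_matrix,
                                      ridge).accuracy
    rng = np.random.default_rng(seed)
    group_rows = [
        grp[np.isin(realness[grp], np.asarray(classes))]
        for grp in (np.flatnonzero((subjects == su) & (sessions == se))
                    for su in np.unique(subjects)
                    for se in np.unique(sessions[subjects == su]))
    ]
    perms = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = realness.copy()
        for rows in group_rows:
            shuffled[rows] = shuffled[rng.permutation(rows)]
        perms[b] = _cross_validate_arrays(
            ep.data, subjects, sessions, shuffled, classes, ep.srate,
            window_s, q_matrix, ridge, warn_ties=False).accuracy
    if add_one:
        p = (1.0 + np.sum(perms >= observed)) / (n_perm + 1.0)
    else:
        p = float(np.sum(perms > observed)) / n_perm
    return PermutationResult(float(p), float(observed), perms)
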