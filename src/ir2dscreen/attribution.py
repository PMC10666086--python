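"""Interpretation layer: difference spectra, incremental-LV success, latent
variable score summaries and LV-to-class assignment.

PLS-DA is used here not only as a classifier but as an attribution tool:
each latent variable carries a spectral loading, and a class whose scores on
one LV separate cleanly from every other class (non-overlapping 1-sigma
intervals) can be assigned that LV, whose loading is then the model's
estimate of the class-specific spectral signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridmap import SpectrumMap2D
from .pls import PLSModel, loo_crossval, plsda_fit

__all__ = [
    "LVScoreSummary",
    "attribution_model",
    "difference_map",
    "incremental_success",
    "lv_class_scores",
    "lv_assignment",
    "serum_mean_map",
    "loading_map",
    "cosine_similarity",
]


@dataclass
class LVScoreSummary:
    """Per (class, LV) score statistics of a fitted PLS-DA model.

    ``mean`` and ``sd`` are class x LV matrices (sd is the 1-sigma sample
    standard deviation); ``n`` gives the class sizes.
    """

    class_names: list
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray


def attribution_model(X, labels: list, n_lv: int = 9) -> PLSModel:
    """Fit the five-class PLS-DA model used for latent-variable attribution.

    Attribution fits are mean-centered even when the classification model is
    not: the common serum response dwarfs the drug perturbations by more
    than an order of magnitude, and without centering it bleeds into every
    loading, obscuring the drug-specific signatures the scores/loadings
    analysis is meant to expose.  Classification accuracy is unaffected by
    this choice; it applies to interpretation only.
    """
    return plsda_fit(X, labels, n_lv, centered=True)


def difference_map(sample: SpectrumMap2D, serum_mean: SpectrumMap2D) -> SpectrumMap2D:
    """Cellwise sample minus mean neat-serum map: isolates what the drug
    changed in the protein response."""
    return sample - serum_mean


def serum_mean_map(maps: list, labels: list, serum_label: str = "Serum") -> SpectrumMap2D:
    """Mean of all preprocessed neat-serum maps."""
    serum = [m for m, l in zip(maps, labels) if l == serum_label]
    if not serum:
        raise ValueError(f"no maps labelled {serum_label!r}")
    mean = np.mean([m.amplitudes for m in serum], axis=0)
    return serum[0].copy_with(mean, sample_id="serum_mean")


def incremental_success(
    X: np.ndarray, labels: list, max_lv: int, centered: bool = False,
    recall_threshold: float = 2 / 3,
) -> tuple[np.ndarray, dict]:
    """Per-class LOO recall as the LV count grows from 1 to ``max_lv``.

    Returns (table, classifies_at): ``table`` is max_lv x n_classes recall
    values (classes in sorted order); ``classifies_at`` maps each class to
    the smallest LV count at which its recall reaches the threshold
    (default 2/3), or None if it never does.
    """
    if max_lv < 2:
        raise ValueError("max_lv must be >= 2")
    class_names = sorted(set(labels))
    table = np.zeros((max_lv, len(class_names)))
    for k in range(1, max_lv + 1):
        cv = loo_crossval(X, labels, k, centered=centered)
        rec = cv.per_class_recall
        table[k - 1] = [rec[c] for c in class_names]
    classifies_at = {}
    for j, c in enumerate(class_names):
        hits = np.nonzero(table[:, j] >= recall_threshold)[0]
        classifies_at[c] = int(hits[0] + 1) if hits.size else None
    return table, classifies_at


def lv_class_scores(model: PLSModel, labels: list) -> LVScoreSummary:
    """Group the fitted model's x-scores by class: mean and 1-sigma sd per
    (class, LV)."""
    labels = list(labels)
    if model.T.shape[0] != len(labels):
        raise ValueError("label count does not match the model's sample count")
    class_names = sorted(set(labels))
    arr = np.asarray(labels)
    mean = np.zeros((len(class_names), model.n_lv))
    sd = np.zeros_like(mean)
    n = np.zeros(len(class_names), dtype=int)
    for i, c in enumerate(class_names):
        scores = model.T[arr == c]
        n[i] = scores.shape[0]
        mean[i] = scores.mean(axis=0)
        sd[i] = scores.std(axis=0, ddof=1) if scores.shape[0] > 1 else 0.0
    return LVScoreSummary(class_names=class_names, mean=mean, sd=sd, n=n)


def lv_assignment(summary: LVScoreSummary, exclude: list | None = None) -> dict:
    """Assign latent variables to classes by score separation.

    LV l is attributable to class c iff c has the largest absolute mean
    score on l AND its mean +/- 1 sigma interval does not overlap any other
    class's interval on l.  A class may end up unassigned (partial mapping);
    if several LVs qualify for one class the one with the largest absolute
    mean score wins.  Classes in ``exclude`` (e.g. the serum background
    class) are not assigned LVs but still participate in overlap checks.
    """
    exclude = set(exclude or [])
    best: dict = {}
    n_classes, n_lv = summary.mean.shape
    for l in range(n_lv):
        means = summary.mean[:, l]
        sds = summary.sd[:, l]
        c_star = int(np.argmax(np.abs(means)))
        lo, hi = means[c_star] - sds[c_star], means[c_star] + sds[c_star]
        overlap = any(
            (means[c] - sds[c] <= hi) and (means[c] + sds[c] >= lo)
            for c in range(n_classes)
            if c != c_star
        )
        if overlap:
            continue
        name = summary.class_names[c_star]
        if name in exclude:
            continue
        score = abs(means[c_star])
        if name not in best or score > best[name][1]:
            best[name] = (l, score)
    return {c: l for c, (l, _) in best.items()}


def loading_map(model: PLSModel, lv: int, processed) -> SpectrumMap2D:
    """Un-flatten one LV's x-loading back onto the (pump, probe) grid for
    visual comparison with difference spectra."""
    if not 0 <= lv < model.n_lv:
        raise IndexError(f"lv {lv} out of range [0, {model.n_lv})")
    return processed.unflatten(model.P[:, lv])


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))
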